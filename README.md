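# microsolv

Cluster-continuum microhydration analysis for small organic solutes such as
phenylboronic acid (PBA): per-conformer rigid-rotor harmonic-oscillator
(RRHO) thermochemistry over a temperature grid, Boltzmann conformer
populations, hydration free-energy/enthalpy assembly with size-convergence
diagnostics, and non-covalent interaction classification from QTAIM and NBO
tables.

## The problem

In the cluster-continuum approach the hydration of a solute is modelled by
the reaction

    PBA(g) + (H2O)n(s) -> PBA(H2O)n(s)

where *(s)* marks species embedded in an implicit water continuum. Given
ensembles of optimized conformers for the bare solute, the water clusters
(H2O)n and the microhydrated clusters PBA(H2O)n, the absolute hydration
free energy at cluster size *n* is

    ΔG_hyd(n, T) = G_s[PBA(H2O)n] − G_s[(H2O)n] − G_g[PBA]

(enthalpy analogously), with every term the Boltzmann-ensemble value of its
conformer group:

    G(T) = Σ_i G_i(T) P_i(T),   P_i(T) = exp(−G_i/kBT) / Σ_j exp(−G_j/kBT)

Each G_i(T) comes from RRHO statistical mechanics (Sackur–Tetrode
translation, classical rigid rotor with symmetry number, harmonic
vibrations, ground-state electronic multiplicity) applied to the
conformer's electronic energy, harmonic frequencies and rotational
constants. Convergence in *n* is diagnosed by averaging over a size window
(default n = 5–10) at a reference temperature; the hydration entropy is the
negated least-squares slope of ΔG_hyd versus T, and the max−min spread of
ΔH_hyd over the grid flags temperature independence.

The bonding layer classifies QTAIM bond critical points (OH···O, CH···O,
OH···π, O···C) by atom context with reference (ρ, ∇²ρ) envelopes as
validation ranges, detects hydrogen bonds geometrically from XYZ
coordinates, and evaluates NBO second-order stabilization energies
E(2) = q·F²/(ε_j − ε_i).

Electronic-structure inputs (energies, frequencies, BCP and NBO tables) are
expected from quantum-chemistry calculations; the package also ships a
synthetic-data module that generates complete, physically shaped scenarios
with planted ground truth so the entire pipeline is verifiable by parameter
recovery.

## Worked example

```python
from microsolv.ensemble import build_ensembles
from microsolv.hydration import assemble_hydration
from microsolv.synthetic import ScenarioSpec, generate_hydration_scenario

scenario = generate_hydration_scenario(ScenarioSpec(seed=2025))
ensembles = build_ensembles(scenario.thermo)
summary = assemble_hydration(ensembles, sizes=range(1, 11), window=(5, 10))

print(f"dG_hyd(298.15 K) = {summary.window_mean_G:.2f} kcal/mol")
print(f"dH_hyd(298.15 K) = {summary.window_mean_H:.2f} kcal/mol")
print(f"hydration entropy = {summary.entropy * 1000:.2f} cal/mol/K")
print(f"dH spread over 20-400 K = {summary.enthalpy_flatness:.2e} kcal/mol "
      f"(temperature-independent: {summary.temperature_independent})")
```

prints

```
dG_hyd(298.15 K) = -72.10 kcal/mol
dH_hyd(298.15 K) = -85.50 kcal/mol
hydration entropy = -44.94 cal/mol/K
dH spread over 20-400 K = 2.18e-10 kcal/mol (temperature-independent: True)
```

The scenario plants a linear ΔG_hyd(T) and a constant ΔH_hyd at the
ensemble level; the numbers above are the pipeline recovering that plant: a
hydration free energy of −72.1 kcal/mol at room temperature, an enthalpy of
−85.5 kcal/mol that does not move with temperature, and a negative
hydration entropy (≈ −45 cal mol⁻¹ K⁻¹) that accounts for the entire
temperature dependence of ΔG_hyd.

The same pipeline is available from the shell:

```
microsolv simulate --out scenario/ --seed 2025
microsolv populations --thermo scenario/thermo.csv --out-prefix pop
microsolv hydration   --thermo scenario/thermo.csv --out-prefix hyd
microsolv classify-bcp --table scenario/bcp.csv --out bcp_classified.csv
microsolv hbond-geom geometry.xyz --out contacts.csv
```

For measured data, build a YAML manifest referencing one XYZ file per
conformer (see `microsolv.conformer_io`) and start from
`microsolv thermo --manifest manifest.yaml --out thermo.csv`.

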