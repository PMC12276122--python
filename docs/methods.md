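# Methods

## Thermochemical model

Each conformer is treated as an ideal-gas rigid-rotor harmonic oscillator.
At temperature T and pressure p the contributions are:

- **Translation** — Sackur–Tetrode entropy
  S = R[ln((2πmkT/h²)^{3/2} kT/p) + 5/2] and thermal energy 3/2 RT.
- **Rotation** — classical partition functions: q = T/(σΘ) for a linear
  rotor, q = (√π/σ)·T^{3/2}/√(Θ_A Θ_B Θ_C) otherwise, with Θ = hB/k from
  the rotational constants B (GHz) and external symmetry number σ. A single
  atom contributes nothing. Rotational constants are computed from the
  geometry (inertia-tensor eigenvalues) when a manifest omits them; a
  manifest value wins when both exist. A molecule is linear when its
  smallest principal moment is below 10⁻³ amu Å².
- **Vibration** — harmonic, ZPE-separated: ZPE = ½Σhcν_i (scale factor
  default 1.0, configurable), thermal energy RT·Σ x_i/(e^{x_i}−1) and
  entropy R·Σ[x_i/(e^{x_i}−1) − ln(1−e^{−x_i})] with x = hcν/kT. No
  quasi-RRHO damping of low frequencies: populations are meant to follow
  plain harmonic free energies, and a damping scheme would shift them
  silently.
- **Electronic** — q = ground-state multiplicity only (the intended
  systems are closed-shell singlets).

Enthalpy follows the quantum-chemistry convention
H = E_elec + ZPE + thermal corrections + RT and G = H − TS, so the
identity G + TS − H = 0 holds to machine precision by construction. The
default grid is 20–400 K in 10 K steps (39 points); energies are hartree at
the API boundary (1 hartree = 627.509474 kcal/mol) and kcal/mol in every
report, with R = 1.98720425864083×10⁻³ kcal mol⁻¹ K⁻¹.

Standard state is the ideal gas at 1 atm for every phase tag; no
gas→solution correction is applied by default. An opt-in `standard_state="1M"`
subtracts R ln(24.46·T/298.15) from the entropy (the ideal-gas molar volume
scaled linearly with T), for sensitivity analyses only.

The classical rotor/translation formulas make G → E_elec + ZPE only as
T ln T → 0, so the zero-temperature limit is verified numerically at
millikelvin temperatures; below ~10 K the classical entropy itself is
unphysical (it can go negative), which is irrelevant to the supported
20–400 K range.

## Ensembles and populations

Boltzmann weights use P_i = exp(−G_i/RT)/Σ_j exp(−G_j/RT), computed after
shifting by the group minimum so arbitrarily large energy gaps cannot
overflow; the shifted and naive evaluations agree to 10⁻¹⁰ whenever the
naive form is finite. The ensemble free energy (and enthalpy) is the
population-weighted arithmetic mean of the conformer values. The
thermodynamically strict alternative −RT ln Σ exp(−G_i/RT) is available
behind `method="log_sum_exp"` for comparison, never as the default,
because the weighted mean is the definition the assembly is built on.
Since the average is covariant under a common shift of all G_i, absolute
and relative conformer free energies give identical hydration differences.

Reporting filters: conformers are retained when their weight strictly
exceeds 10% at at least one grid temperature (a conformer pinned exactly at
the threshold is dropped), and ensembles can be restricted to conformers
within an inclusive 2.0 kcal/mol ZPE-corrected window of the group minimum
(the window boundary carries a 10⁻⁹ kcal/mol guard against round-off in
the hartree→kcal path). No deduplication of permutational or mirror
isomers is attempted; records are taken as curated.

## Hydration assembly

ΔG_hyd(n, T) = G_s[solute·(H₂O)n] − G_s[(H₂O)n] − G_g[solute], each term a
Boltzmann-ensemble value (a `best_only` analysis can be emulated by
passing single-conformer groups). n = 0 reduces to the continuum-only
estimate G_s[solute] − G_g[solute], for which identical thermal corrections
in the two phases make ΔH = ΔG analytically. The gas-phase solute term uses
whatever records carry the gas phase tag; the bundled scenarios provide
gas-phase geometries and frequencies for it.

Diagnostics: an unweighted mean over cluster sizes n = 5–10 (configurable)
at T_ref = 298.15 K; the hydration entropy as the negated OLS slope of
ΔG_hyd versus T with the residual norm as a linearity check; and the
max−min spread of ΔH_hyd over the grid, flagged temperature-independent
below 1.0 kcal/mol. Summary-level slope and flatness are evaluated on the
size-averaged curves over the window; per-size curves remain in the
profile table. A size-weighted window mean is deliberately not
implemented.

## Bonding analysis

Bond critical points are classified by their atom context (O–H···O,
C–H···O, O–H···π, O···C); the (ρ, ∇²ρ) reference envelopes

| contact | ρ (au) | ∇²ρ (au) |
|---|---|---|
| OH···O | 0.0115–0.0548 | 0.0435–0.1296 |
| CH···O | 0.0049–0.0051 | 0.0195–0.0232 |
| OH···π | 0.0078–0.0088 | 0.0254–0.0279 |
| O···C  | 0.0057–0.0065 | 0.0185–0.0226 |

serve as validation ranges only (out-of-range values warn, never error),
because the ∇²ρ intervals overlap across types and cannot key a
classification. A positive Laplacian is required for the non-covalent
flag; ρ orders contacts by strength, with stable ties reported as equal
strength.

The geometric detector is a stand-in for wavefunction-level bond-path
analysis: O–H···O requires d(H···O) ≤ 2.5 Å and ∠D–H···A ≥ 140°, C–H···O
d ≤ 2.8 Å and ≥ 120°, O–H···π a hydrogen within 3.0 Å of the centroid of a
near-planar (≤ 0.15 Å deviation) six-carbon ring at ≥ 60° elevation.
These are conventional literature cutoffs, all configurable; covalent
connectivity uses Cordero radii scaled by 1.25. Atoms closer than 0.5 Å
are rejected as overlapping.

NBO stabilization energies are evaluated as E(2) = q·F²/(ε_j − ε_i)
(atomic units in, kcal/mol out); a non-positive orbital-energy gap is
rejected as non-stabilizing. E(2) values can only be evaluated from
supplied (q, F, ε) tables, not re-derived from wavefunctions.

## Synthetic scenarios and what they show

The generator emulates the statistical structure of a microhydration
study: cluster sizes n = 0–10, about ten isomers per size with
ZPE-corrected relative energies spanning up to 11.1 kcal/mol (imposed
exactly by back-setting electronic energies against the drawn vibrational
spectra), matched gas/continuum record pairs shifted by a constant
solvation term per group, water-cluster geometries with O–O separations of
2.7–3.0 Å, and vibrational spectra of up to six soft intermolecular modes
drawn U(30, 300) cm⁻¹ plus stiff modes U(600, 3900) cm⁻¹. All draws come
from one seeded generator; outputs are rendered at fixed precision, so a
scenario directory is byte-identical across reruns of the same seed.

The hydration scenario plants its target at the ensemble level. Water
clusters and the gas-phase solute receive honest RRHO thermochemistry from
their generated geometries and spectra. The composite solute–water groups'
per-conformer tables are then back-solved,

    G_PWn,j(T) = G_Wn,j(T) + G[solute, gas](T) + a + sT,
    H_PWn,j(T) = H_Wn,j(T) + H[solute, gas](T) + ΔH,

inheriting the water group's conformer gap structure so the Boltzmann
weights of the two groups coincide and the assembly cancels exactly to the
planted line — independent of n, which makes the window average equal the
plant by construction. This is a deliberate design choice: a bimolecular
association changes translational/rotational degrees of freedom whose free
energy is T ln T-shaped, so no composite built honestly from geometries
could hit an exactly linear plant; planting at the ensemble level is what
makes Boltzmann averaging and the assembly jointly testable by parameter
recovery at 10⁻⁹ kcal/mol. The back-solved tables are synthetic composites
— they are not the RRHO thermochemistry of the composite manifest
geometries, and at low temperature their formal entropies (H−G)/T can be
negative; the entropy ≥ 0 invariant is asserted only for RRHO-computed
records.

Default planted values are ΔH = −85.5 kcal/mol and
ΔG(T) = −85.5 + (13.4/298.15)·T kcal/mol, i.e. ΔG(298.15 K) = −72.1
kcal/mol and a hydration entropy of −44.94 cal mol⁻¹ K⁻¹ — magnitudes
representative of a small aromatic acid with a strongly hydrogen-bonding
head group, and thermodynamically consistent (ΔH equals the intercept, so
ΔG = ΔH − TΔS holds exactly along the plant).

What passing tests do and do not show: exact recovery demonstrates that
the weighting, averaging, assembly, windowing, slope and flatness
machinery is correct, and the honest water/solute legs exercise the full
RRHO path; it does not validate electronic energies, real conformational
sampling, anharmonicity, or continuum-solvation physics, which live in the
upstream quantum-chemistry inputs. Real data enter through the manifest
interface and flow through the identical code path.

## Numerical choices

- Weight computation shifts by the group minimum; frozen vibrational modes
  evaluate x/(e^x−1) → 0 without overflow.
- Ties: equal free energies give equal weights; equal ρ preserves input
  order; equal E(2) keeps the earliest entry.
- OLS slope via `numpy.polyfit` (degree 1); degenerate grids (< 3 points
  or zero temperature spread) are rejected.
- The scenario grid is the default 39-point grid plus the 298.15 K
  reference point inserted in order (40 points), so window averages need
  no interpolation.
- Tables are CSV at 10 significant digits; the scenario thermochemistry
  table uses 16 so the 10⁻⁹ recovery property survives a disk round-trip.
- Problem sizes: the bundled scenario uses 11 sizes × 10 isomers (202
  conformer records, 8080 thermo rows) and builds in well under a second;
  these sizes make every planted property exactly checkable while keeping
  the suite fast.

## Known limitations

- Harmonic only: no hindered rotors, anharmonic corrections or isotope
  effects; no quasi-RRHO low-frequency treatment.
- Classical rotational partition function: invalid below ~10 K, irrelevant
  for the supported 20–400 K grid.
- The geometric hydrogen-bond detector uses fixed cutoffs and knows
  nothing about electron density; borderline contacts can differ from a
  QTAIM bond-path analysis.
- Quantum-chemistry log files are not parsed; inputs arrive as manifests
  and delimited tables.
- Plot rendering is out of scope; the delimited tables are the correctness
  surface.
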