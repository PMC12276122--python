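"""Synthetic microhydration scenarios with planted ground truth.

Everything the pipeline consumes can be generated here: conformer
ensembles over cluster sizes n = 0-10 with planted ZPE-corrected energy
gaps, matched gas/continuum record pairs, water-cluster series, reference
geometries for the hydrogen-bond detector, and BCP/NBO tables drawn inside
the reference envelopes.

The hydration scenario plants its target at the ensemble level: water
clusters and the bare solute are given honest RRHO thermochemistry from
generated geometries and frequencies, and the solute-water composite
groups' per-conformer G(T)/H(T) tables are then back-solved so that the
cluster-continuum assembly returns the planted free-energy line and
constant enthalpy exactly, at every grid point and for every size. The
back-solved tables are synthetic composites (they are not the RRHO
thermochemistry of the composite manifest geometries); this is what makes
the Boltzmann averaging and the assembly jointly verifiable by parameter
recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bonding import TABLE_ENVELOPES, BCPRecord, NBOInteraction
from .constants import HARTREE_TO_KCAL_MOL
from .conformer_io import (ConformerRecord, EnsembleManifest, Phase, Species,
                           ValidationError, write_manifest, write_table)
from .rrho import (TemperatureGrid, rotational_constants_from_geometry,
                   thermo_at, zero_point_energy)

__all__ = [
    "ScenarioSpec",
    "HydrationScenario",
    "generate_ensemble",
    "generate_hydration_scenario",
    "build_reference_geometries",
    "generate_bcp_nbo_tables",
    "write_scenario",
    "pba_geometry",
    "water_geometry",
    "water_dimer_geometry",
    "pba_monohydrate_geometry",
    "water_cube_geometry",
]

_OH = 0.9572          # O-H bond length, angstrom
_HOH = np.radians(104.52)
_E_WATER = -76.43     # per-water electronic baseline, hartree
_E_PBA = -411.57      # bare-solute electronic baseline, hartree


@dataclass
class ScenarioSpec:
    """Study conditions for a synthetic scenario.

    Defaults emulate the microhydrated-arylboronic study design: cluster
    sizes 0-10, about ten isomers per size with ZPE-corrected relative
    energies spanning up to 11.1 kcal/mol, soft intermolecular modes at
    30-300 cm^-1 plus intramolecular modes up to 3900 cm^-1, and a planted
    hydration thermodynamics of dH = -85.5 kcal/mol with a linear dG(T)
    passing through -72.1 kcal/mol at 298.15 K.
    """

    seed: int = 2025
    sizes: tuple = tuple(range(0, 11))
    isomers_per_size: int = 10
    relative_energy_span: float = 11.1  # kcal/mol
    low_freq_range: tuple = (30.0, 300.0)    # cm^-1
    high_freq_range: tuple = (600.0, 3900.0)  # cm^-1
    dg_intercept: float = -85.5              # kcal/mol
    dg_slope: float = 13.4 / 298.15          # kcal/mol/K
    dh_constant: float = -85.5               # kcal/mol
    t_ref: float = 298.15

    def __post_init__(self):
        if self.isomers_per_size < 1:
            raise ValidationError("isomers_per_size must be >= 1")
        if self.relative_energy_span < 0:
            raise ValidationError("relative_energy_span must be >= 0")

    def planted_dg(self, T):
        return self.dg_intercept + self.dg_slope * np.asarray(T, dtype=float)


# ---------------------------------------------------------------------------
# Reference geometries
# ---------------------------------------------------------------------------

def water_geometry():
    """A single water molecule in the xy-plane."""
    elements = ["O", "H", "H"]
    coords = np.array([
        [0.0, 0.0, 0.0],
        [_OH, 0.0, 0.0],
        [_OH * np.cos(_HOH), _OH * np.sin(_HOH), 0.0],
    ])
    return elements, coords


def water_dimer_geometry(o_o: float = 2.98):
    """Linear hydrogen-bonded dimer: one O-H points straight at the
    acceptor oxygen; acceptor hydrogens point away in the xz-plane."""
    half = _HOH / 2.0
    elements = ["O", "H", "H", "O", "H", "H"]
    coords = np.array([
        [0.0, 0.0, 0.0],
        [_OH, 0.0, 0.0],                                   # donor H on the O...O axis
        [_OH * np.cos(_HOH), _OH * np.sin(_HOH), 0.0],
        [o_o, 0.0, 0.0],
        [o_o + _OH * np.cos(half), 0.0, _OH * np.sin(half)],
        [o_o + _OH * np.cos(half), 0.0, -_OH * np.sin(half)],
    ])
    return elements, coords


def pba_geometry():
    """Phenylboronic acid: benzene ring in the xy-plane, B(OH)2 on +x.

    Standard bond lengths: C-C 1.39, C-H 1.08, C-B 1.56, B-O 1.36,
    O-H 0.96 angstrom. The two hydroxyl hydrogens point outward.
    """
    elements, coords = [], []
    ring_r = 1.39
    for k in range(6):
        ang = np.radians(60.0 * k)
        c = np.array([ring_r * np.cos(ang), ring_r * np.sin(ang), 0.0])
        elements.append("C")
        coords.append(c)
        if k != 0:  # ipso carbon carries the boron instead of an H
            elements.append("H")
            coords.append(c * ((ring_r + 1.08) / ring_r))
    b = np.array([ring_r + 1.56, 0.0, 0.0])
    elements.append("B")
    coords.append(b)
    for sgn in (+1.0, -1.0):
        o = b + 1.36 * np.array([np.cos(np.radians(60.0)),
                                 sgn * np.sin(np.radians(60.0)), 0.0])
        elements.append("O")
        coords.append(o)
        h = o + 0.96 * np.array([np.cos(np.radians(sgn * 10.0)),
                                 np.sin(np.radians(sgn * 10.0)), 0.0])
        elements.append("H")
        coords.append(h)
    return elements, np.array(coords)


def pba_monohydrate_geometry():
    """C2v-like motif: both B(OH)2 hydroxyls donate to one water oxygen.

    The water oxygen sits on the C2 axis so the two O-H...O contacts are
    symmetry-equivalent (same H...O distance, hence same strength).
    """
    elements, coords = pba_geometry()
    coords = list(coords)
    b = np.array([1.39 + 1.56, 0.0, 0.0])
    o_idx = [i for i, e in enumerate(elements) if e == "O"]
    oh_idx = [i + 1 for i in o_idx]  # hydroxyl H follows its O
    o_acc_dist = 2.86  # O(hydroxyl)...O(water)
    o1 = coords[o_idx[0]]
    dy2 = o_acc_dist**2 - o1[1] ** 2
    ow = np.array([o1[0] + np.sqrt(dy2), 0.0, 0.0])
    for oi, hi in zip(o_idx, oh_idx):
        u = (ow - coords[oi]) / np.linalg.norm(ow - coords[oi])
        coords[hi] = coords[oi] + 0.96 * u  # re-aim hydroxyl H at the water O
    half = _HOH / 2.0
    elements = elements + ["O", "H", "H"]
    coords += [
        ow,
        ow + _OH * np.array([np.cos(half), 0.0, np.sin(half)]),
        ow + _OH * np.array([np.cos(half), 0.0, -np.sin(half)]),
    ]
    return elements, np.array(coords)


def water_cube_geometry(edge: float = 2.8):
    """Eight waters on cube corners, hydrogens donated along the edges.

    Edge orientations are assigned greedily so every oxygen donates one or
    two hydrogens; leftover hydrogens point radially outward.
    """
    h = edge / 2.0
    corners = np.array(list(itertools.product((-h, h), repeat=3)))
    edges = [(i, j) for i in range(8) for j in range(i + 1, 8)
             if np.isclose(np.linalg.norm(corners[i] - corners[j]), edge)]
    donated = [0] * 8
    oriented = []
    for i, j in edges:
        if donated[i] <= donated[j] and donated[i] < 2:
            d, a = i, j
        elif donated[j] < 2:
            d, a = j, i
        else:
            d, a = i, j  # cannot happen for a cube; keep deterministic anyway
        donated[d] += 1
        oriented.append((d, a))
    if max(donated) > 2:
        raise ValidationError("cube orientation failed: an oxygen donates > 2 H")
    elements = ["O"] * 8
    coords = list(corners)
    for d, a in oriented:
        u = (corners[a] - corners[d]) / edge
        elements.append("H")
        coords.append(corners[d] + _OH * u)
    for i in range(8):
        u = corners[i] / np.linalg.norm(corners[i])
        perp = np.cross(u, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        extras = ([u] if donated[i] == 1 else
                  [u, (u + perp) / np.linalg.norm(u + perp)] if donated[i] == 0
                  else [])
        for v in extras:
            elements.append("H")
            coords.append(corners[i] + _OH * v)
    return elements, np.array(coords)


def build_reference_geometries() -> dict:
    """Named benchmark geometries for the geometric hydrogen-bond detector."""
    return {
        "water_monomer": water_geometry(),
        "water_dimer": water_dimer_geometry(),
        "pba": pba_geometry(),
        "pba_monohydrate": pba_monohydrate_geometry(),
        "water_cube": water_cube_geometry(),
    }


# ---------------------------------------------------------------------------
# Random cluster geometries and spectra
# ---------------------------------------------------------------------------

def _random_water_orientation(rng) -> np.ndarray:
    u1 = rng.normal(size=3)
    u1 /= np.linalg.norm(u1)
    t = rng.normal(size=3)
    t -= (t @ u1) * u1
    t /= np.linalg.norm(t)
    u2 = np.cos(_HOH) * u1 + np.sin(_HOH) * t
    return np.vstack([u1, u2])


def random_water_cluster(rng, n: int):
    """n waters with O-O separations in the hydrogen-bonding range."""
    if n < 1:
        raise ValidationError("water cluster needs n >= 1")
    centers = [np.zeros(3)]
    while len(centers) < n:
        base = centers[int(rng.integers(len(centers)))]
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        cand = base + rng.uniform(2.7, 3.0) * v
        if all(np.linalg.norm(cand - c) >= 2.5 for c in centers):
            centers.append(cand)
    elements, coords = [], []
    for c in centers:
        hh = _random_water_orientation(rng)
        elements += ["O", "H", "H"]
        coords += [c, c + _OH * hh[0], c + _OH * hh[1]]
    return elements, np.array(coords)


def random_pba_water_cluster(rng, n: int):
    """Solute plus n waters clustered near the B(OH)2 end."""
    elements, coords = pba_geometry()
    coords = list(coords)
    anchor = np.array([5.6, 0.0, 0.0])
    centers = []
    while len(centers) < n:
        cand = anchor + rng.normal(scale=1.8, size=3)
        if all(np.linalg.norm(cand - c) >= 2.5 for c in centers) and \
           all(np.linalg.norm(cand - p) >= 2.4 for p in coords):
            centers.append(cand)
    for c in centers:
        hh = _random_water_orientation(rng)
        elements += ["O", "H", "H"]
        coords += [c, c + _OH * hh[0], c + _OH * hh[1]]
    return elements, np.array(coords)


def generate_frequencies(rng, n_atoms: int, low=(30.0, 300.0),
                         high=(600.0, 3900.0)) -> np.ndarray:
    """3N-6 positive wavenumbers: up to 6 soft intermolecular modes plus
    stiff intramolecular modes."""
    n_modes = 3 * n_atoms - 6
    if n_modes <= 0:
        return np.array([])
    n_low = min(6, max(0, n_modes - 3))
    freqs = np.concatenate([
        rng.uniform(low[0], low[1], n_low),
        rng.uniform(high[0], high[1], n_modes - n_low),
    ])
    return np.sort(freqs)


def _make_record(label, species, n_waters, phase, elements, coords,
                 energy_hartree, freqs, point_group=None) -> ConformerRecord:
    return ConformerRecord(
        label=label, species=species, n_waters=n_waters, phase=phase,
        elements=elements, coordinates=coords,
        electronic_energy=energy_hartree, frequencies=freqs,
        rotational_constants=rotational_constants_from_geometry(elements, coords),
        point_group=point_group,
    )


def _planted_gaps(rng, k: int, span: float) -> np.ndarray:
    if k == 1:
        return np.zeros(1)
    return np.concatenate([[0.0], np.sort(rng.uniform(0.0, span, k - 1))])


# ---------------------------------------------------------------------------
# Conformer-ensemble generator
# ---------------------------------------------------------------------------

def generate_ensemble(spec: ScenarioSpec, return_truth: bool = False):
    """Matched gas/continuum conformer ensembles with planted energy gaps.

    For each size n the ZPE-corrected relative energies of the isomers are
    drawn once in [0, span] and imposed exactly by back-setting the
    electronic energies against the drawn vibrational spectra; the same
    gaps hold in both phases (the continuum shifts every isomer of a group
    by one constant). Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    truth = {}
    for n in spec.sizes:
        species = Species.PBA if n == 0 else Species.PBA_WATER
        k = spec.isomers_per_size
        gaps = _planted_gaps(rng, k, spec.relative_energy_span)
        solvation_shift = rng.uniform(0.01, 0.03)  # hartree, per group
        e_base = (_E_PBA + _E_WATER * n) + rng.normal(0.0, 0.005)
        zpes, geoms, freq_sets = [], [], []
        for j in range(k):
            if n == 0:
                el, xyz = pba_geometry()
                xyz = xyz + rng.normal(scale=0.01, size=xyz.shape)
            else:
                el, xyz = random_pba_water_cluster(rng, n)
            freqs = generate_frequencies(rng, len(el), spec.low_freq_range,
                                         spec.high_freq_range)
            geoms.append((el, xyz))
            freq_sets.append(freqs)
            zpes.append(zero_point_energy(freqs))
        for j in range(k):
            # impose (E + ZPE) gap exactly despite per-isomer ZPE scatter
            e_j = e_base + (gaps[j] - (zpes[j] - zpes[0])) / HARTREE_TO_KCAL_MOL
            stem = "PBA" if n == 0 else f"PBA-W{n}"
            for phase, e_val, tag in (
                (Phase.GAS, e_j, "g"),
                (Phase.CONTINUUM_WATER, e_j - solvation_shift, "s"),
            ):
                records.append(_make_record(
                    f"{stem}-{j + 1}-{tag}", species, n, phase,
                    geoms[j][0], geoms[j][1], e_val, freq_sets[j],
                ))
        for phase in (Phase.GAS, Phase.CONTINUUM_WATER):
            truth[(species.value, n, phase.value)] = gaps.copy()
    manifest = EnsembleManifest(
        records=records,
        provenance=f"synthetic ensemble, seed {spec.seed}",
    )
    manifest.validate()
    if return_truth:
        return manifest, truth
    return manifest


# ---------------------------------------------------------------------------
# Hydration scenario with planted dG(T) / dH
# ---------------------------------------------------------------------------

@dataclass
class HydrationScenario:
    """Manifests + per-conformer thermochemistry + planted truth.

    ``thermo`` is the authoritative long thermochemistry table (columns
    species, n_waters, phase, label, T, zpe, enthalpy, entropy, gibbs);
    for the back-solved composite groups it intentionally differs from
    what RRHO on the manifest geometries would give.
    """

    spec: ScenarioSpec
    grid: TemperatureGrid
    manifest: EnsembleManifest
    thermo: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _thermo_rows(df: pd.DataFrame, species, n, phase) -> pd.DataFrame:
    df = df.copy()
    df.insert(0, "species", species.value)
    df.insert(1, "n_waters", n)
    df.insert(2, "phase", phase.value)
    return df


def generate_hydration_scenario(spec: ScenarioSpec | None = None) -> HydrationScenario:
    """Full cluster-continuum scenario with a planted hydration line.

    Water-cluster groups and the gas-phase solute get honest RRHO
    thermochemistry; composite solute-water (and continuum-solute) tables
    are back-solved so the assembly returns dG(T) = intercept + slope*T
    and the constant dH exactly, for every size, independent of n.
    """
    spec = spec or ScenarioSpec()
    rng = np.random.default_rng(spec.seed)
    grid = TemperatureGrid().with_point(spec.t_ref)
    T = grid.values
    dg_t = spec.planted_dg(T)

    records, frames = [], []

    # Bare solute, gas phase (honest RRHO; single conformer).
    el, xyz = pba_geometry()
    pba_freqs = generate_frequencies(rng, len(el), spec.low_freq_range,
                                     spec.high_freq_range)
    pba_rec = _make_record("PBA-1-g", Species.PBA, 0, Phase.GAS, el, xyz,
                           _E_PBA + rng.normal(0.0, 0.005), pba_freqs)
    records.append(pba_rec)
    pba_thermo = thermo_at(pba_rec, grid)
    frames.append(_thermo_rows(pba_thermo, Species.PBA, 0, Phase.GAS))
    g_p = pba_thermo["gibbs"].to_numpy()
    h_p = pba_thermo["enthalpy"].to_numpy()

    # Continuum solute: back-solved so the n = 0 assembly hits the plant.
    pba_s = _make_record("PBA-1-s", Species.PBA, 0, Phase.CONTINUUM_WATER,
                         el, xyz,
                         pba_rec.electronic_energy
                         + spec.dg_intercept / HARTREE_TO_KCAL_MOL,
                         pba_freqs)
    records.append(pba_s)
    g_ps = g_p + dg_t
    h_ps = h_p + spec.dh_constant
    frames.append(_thermo_rows(pd.DataFrame({
        "label": pba_s.label, "T": T, "zpe": pba_thermo["zpe"].to_numpy(),
        "enthalpy": h_ps, "entropy": (h_ps - g_ps) / T * 1000.0, "gibbs": g_ps,
    }), Species.PBA, 0, Phase.CONTINUUM_WATER))

    sizes = [n for n in spec.sizes if n >= 1]
    for n in sizes:
        k = spec.isomers_per_size
        gaps = _planted_gaps(rng, k, spec.relative_energy_span)
        e_base = _E_WATER * n + rng.normal(0.0, 0.005)
        zpes, geoms, freq_sets = [], [], []
        for j in range(k):
            el_w, xyz_w = random_water_cluster(rng, n)
            freqs = generate_frequencies(rng, len(el_w), spec.low_freq_range,
                                         spec.high_freq_range)
            geoms.append((el_w, xyz_w))
            freq_sets.append(freqs)
            zpes.append(zero_point_energy(freqs))
        w_tables, w_energies = [], []
        for j in range(k):
            e_j = e_base + (gaps[j] - (zpes[j] - zpes[0])) / HARTREE_TO_KCAL_MOL
            w_energies.append(e_j)
            w_rec = _make_record(f"W{n}-{j + 1}-s", Species.WATER_CLUSTER, n,
                                 Phase.CONTINUUM_WATER, geoms[j][0], geoms[j][1],
                                 e_j, freq_sets[j])
            records.append(w_rec)
            tab = thermo_at(w_rec, grid)
            w_tables.append(tab)
            frames.append(_thermo_rows(tab, Species.WATER_CLUSTER, n,
                                       Phase.CONTINUUM_WATER))
        # Composite group: manifest geometries are plausible clusters, but
        # the thermochemistry is the back-solved planted composite.
        for j in range(k):
            el_c, xyz_c = random_pba_water_cluster(rng, n)
            freqs_c = generate_frequencies(rng, len(el_c), spec.low_freq_range,
                                           spec.high_freq_range)
            c_rec = _make_record(
                f"PBA-W{n}-{j + 1}-s", Species.PBA_WATER, n,
                Phase.CONTINUUM_WATER, el_c, xyz_c,
                pba_rec.electronic_energy + w_energies[j]
                + spec.dg_intercept / HARTREE_TO_KCAL_MOL,
                freqs_c)
            records.append(c_rec)
            g_c = w_tables[j]["gibbs"].to_numpy() + g_p + dg_t
            h_c = w_tables[j]["enthalpy"].to_numpy() + h_p + spec.dh_constant
            frames.append(_thermo_rows(pd.DataFrame({
                "label": c_rec.label, "T": T,
                "zpe": w_tables[j]["zpe"].to_numpy() + pba_thermo["zpe"].iloc[0],
                "enthalpy": h_c, "entropy": (h_c - g_c) / T * 1000.0,
                "gibbs": g_c,
            }), Species.PBA_WATER, n, Phase.CONTINUUM_WATER))

    manifest = EnsembleManifest(
        records=records,
        provenance=f"synthetic hydration scenario, seed {spec.seed}",
    )
    manifest.validate()
    thermo = pd.concat(frames, ignore_index=True)
    truth = {
        "dg_intercept": spec.dg_intercept,
        "dg_slope": spec.dg_slope,
        "dh_constant": spec.dh_constant,
        "entropy": -spec.dg_slope,
        "t_ref": spec.t_ref,
        "dg_at_t_ref": float(spec.planted_dg(spec.t_ref)),
        "sizes": sizes,
    }
    return HydrationScenario(spec=spec, grid=grid, manifest=manifest,
                             thermo=thermo, truth=truth)


# ---------------------------------------------------------------------------
# BCP / NBO fixture tables
# ---------------------------------------------------------------------------

_BCP_CONTEXTS = {
    "OH_O": ("O1", "H2", "O3"),
    "CH_O": ("C4", "H5", "O6"),
    "OH_PI": ("O7", "H8", "ring"),
    "O_C": ("O9", None, "C12"),
}


@dataclass
class BondingTables:
    bcp: list
    nbo: list
    truth: dict

    def bcp_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "donor": r.donor_atom, "hydrogen": r.hydrogen or "",
            "acceptor": r.acceptor_atom, "rho_au": r.rho,
            "laplacian_au": r.laplacian,
        } for r in self.bcp])

    def nbo_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "donor_label": it.donor_orbital, "acceptor_label": it.acceptor_orbital,
            "q": it.occupancy, "F_au": it.fock_element,
            "eps_donor_au": it.eps_donor, "eps_acceptor_au": it.eps_acceptor,
        } for it in self.nbo])


def generate_bcp_nbo_tables(seed: int, rows_per_label: int = 5,
                            n_nbo: int = 12) -> BondingTables:
    """BCP rows drawn inside each reference envelope plus a random NBO
    donor-acceptor table with a known strongest entry."""
    rng = np.random.default_rng(seed)
    bcp, intended = [], []
    for label, (don, hyd, acc) in _BCP_CONTEXTS.items():
        (rlo, rhi), (llo, lhi) = TABLE_ENVELOPES[label]
        for _ in range(rows_per_label):
            bcp.append(BCPRecord(
                donor_atom=don, hydrogen=hyd, acceptor_atom=acc,
                rho=float(rng.uniform(rlo, rhi)),
                laplacian=float(rng.uniform(llo, lhi)),
            ))
            intended.append(label)
    nbo = []
    for i in range(n_nbo):
        eps_d = float(rng.uniform(-1.0, -0.3))
        nbo.append(NBOInteraction(
            donor_orbital=f"LP(2)O{i + 1}",
            acceptor_orbital=f"BD*(1)O{i + 20}-H{i + 21}",
            occupancy=float(rng.uniform(1.7, 2.0)),
            fock_element=float(rng.uniform(0.01, 0.12)),
            eps_donor=eps_d,
            eps_acceptor=eps_d + float(rng.uniform(0.3, 1.0)),
        ))
    strongest = int(np.argmax([it.e2 for it in nbo]))
    return BondingTables(bcp=bcp, nbo=nbo,
                         truth={"bcp_labels": intended,
                                "strongest_nbo_index": strongest})


# ---------------------------------------------------------------------------
# Scenario directory writer (backs the `simulate` CLI subcommand)
# ---------------------------------------------------------------------------

def write_scenario(scenario: HydrationScenario, outdir) -> None:
    """Write manifest + XYZ files, thermo table, bonding tables and the
    planted-truth file (consumed only by tests) into a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(scenario.manifest, out / "manifest.yaml")
    # near-full float precision: the planted-recovery property must survive
    # a disk round-trip
    write_table(scenario.thermo, out / "thermo.csv", float_format="%.16g")
    tables = generate_bcp_nbo_tables(scenario.spec.seed)
    write_table(tables.bcp_frame(), out / "bcp.csv")
    write_table(tables.nbo_frame(), out / "nbo.csv")
    import json
    truth = dict(scenario.truth)
    truth["bonding"] = tables.truth
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
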