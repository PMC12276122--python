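"""Rigid-rotor harmonic-oscillator thermochemistry on a temperature grid.

Per-conformer ideal-gas statistical mechanics: Sackur-Tetrode translation,
classical rigid-rotor rotation with an external symmetry number, harmonic
vibrations in the ZPE-separated convention, and a ground-state-multiplicity
electronic partition function. Enthalpies follow the quantum-chemistry
convention H(T) = E_elec + ZPE + thermal corrections + RT; G = H - T*S.

Units: temperatures K, pressures atm, energies kcal/mol, entropies
cal mol^-1 K^-1, rotational constants GHz, frequencies cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (AMU_KG, ATM_PA, ATOMIC_MASSES, C_LIGHT,
                        HARTREE_TO_KCAL_MOL, H_PLANCK, K_BOLTZMANN,
                        MOLAR_VOLUME_298_L, R_CAL, R_KCAL,
                        WAVENUMBER_TO_KCAL_MOL)
from .conformer_io import ConformerRecord, ValidationError

__all__ = [
    "TemperatureGrid",
    "ThermoRecord",
    "zero_point_energy",
    "rotational_constants_from_geometry",
    "thermo_at",
    "manifest_thermo",
    "relative_zpe_energies",
    "vibrational_thermal_energy",
    "SYMMETRY_NUMBERS",
]

# Point-group -> external symmetry number, applied when a record names a
# point group but leaves the symmetry number at its default.
SYMMETRY_NUMBERS = {
    "C1": 1, "Ci": 1, "Cs": 1, "Cinfv": 1,
    "Dinfh": 2,
    "C2": 2, "C2v": 2, "C2h": 2,
    "C3": 3, "C3v": 3, "C3h": 3,
    "D2": 4, "D2h": 4, "D2d": 4,
    "D3": 6, "D3h": 6, "D3d": 6,
    "Td": 12, "Oh": 24,
}

# Smallest principal moment below this (amu A^2) counts as zero (linear /
# single atom detection).
LINEAR_MOMENT_TOL = 1e-3


@dataclass
class TemperatureGrid:
    """Strictly increasing positive temperatures, default 20-400 K by 10 K."""

    values: np.ndarray = field(default_factory=lambda: np.arange(20.0, 401.0, 10.0))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValidationError("temperature grid must be a non-empty 1-D array")
        if np.any(self.values <= 0):
            raise ValidationError("temperatures must be strictly positive")
        if np.any(np.diff(self.values) <= 0):
            raise ValidationError("temperature grid must be strictly increasing")

    def with_point(self, t: float) -> "TemperatureGrid":
        """Return a grid containing ``t`` (inserted in order if absent)."""
        vals = self.values
        if np.any(np.isclose(vals, t)):
            return self
        return TemperatureGrid(np.sort(np.append(vals, float(t))))

    def __len__(self):
        return len(self.values)


@dataclass
class ThermoRecord:
    """Thermochemistry of one conformer at one temperature."""

    label: str
    T: float
    zpe: float        # kcal/mol
    enthalpy: float   # kcal/mol, includes E_elec + ZPE + thermal + RT
    entropy: float    # cal mol^-1 K^-1
    gibbs: float      # kcal/mol


def zero_point_energy(frequencies, scale: float = 1.0) -> float:
    """Harmonic ZPE = (1/2) * sum(h c nu_i) * scale, in kcal/mol."""
    if scale <= 0:
        raise ValidationError("frequency scale factor must be > 0")
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        return 0.0
    if np.any(freqs <= 0):
        raise ValidationError("all frequencies must be strictly positive")
    return float(0.5 * np.sum(freqs) * scale * WAVENUMBER_TO_KCAL_MOL)


def _masses(elements) -> np.ndarray:
    return np.array([ATOMIC_MASSES[e] for e in elements], dtype=float)


def principal_moments(elements, coordinates) -> np.ndarray:
    """Principal moments of inertia in amu A^2, ascending."""
    coords = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    m = _masses(elements)
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    r = coords - com
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    ixx = np.sum(m * (y**2 + z**2))
    iyy = np.sum(m * (x**2 + z**2))
    izz = np.sum(m * (x**2 + y**2))
    ixy = -np.sum(m * x * y)
    ixz = -np.sum(m * x * z)
    iyz = -np.sum(m * y * z)
    tensor = np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])
    return np.sort(np.linalg.eigvalsh(tensor))


def rotational_constants_from_geometry(elements, coordinates):
    """Rotational constants in GHz from the inertia tensor.

    Returns three constants sorted descending for a nonlinear top, a single
    constant for a linear molecule, and ``None`` for a single atom.
    """
    coords = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("non-finite coordinates")
    if len(coords) == 1:
        return None
    moments = principal_moments(elements, coords)
    # B [Hz] = h / (8 pi^2 I);  I converted amu A^2 -> kg m^2
    def to_ghz(i_amu_a2):
        i_si = i_amu_a2 * AMU_KG * 1e-20
        return H_PLANCK / (8.0 * np.pi**2 * i_si) / 1e9

    if moments[0] < LINEAR_MOMENT_TOL:
        return np.array([to_ghz(moments[2])])
    return np.array(sorted((to_ghz(i) for i in moments), reverse=True))


def _s_translational(mass_amu: float, T: np.ndarray, pressure_atm: float) -> np.ndarray:
    m = mass_amu * AMU_KG
    p = pressure_atm * ATM_PA
    ln_q = (1.5 * np.log(2.0 * np.pi * m * K_BOLTZMANN * T / H_PLANCK**2)
            + np.log(K_BOLTZMANN * T / p))
    return R_CAL * (ln_q + 2.5)


def _rotation(rot_ghz, sigma: int, T: np.ndarray):
    """Returns (E_rot kcal/mol, S_rot cal/mol/K)."""
    if rot_ghz is None or len(rot_ghz) == 0:
        return np.zeros_like(T), np.zeros_like(T)
    theta = np.asarray(rot_ghz, dtype=float) * 1e9 * H_PLANCK / K_BOLTZMANN  # K
    if len(theta) == 1:  # linear rotor
        ln_q = np.log(T / (sigma * theta[0]))
        return R_KCAL * T, R_CAL * (ln_q + 1.0)
    ln_q = (np.log(np.sqrt(np.pi) / sigma)
            + 1.5 * np.log(T) - 0.5 * np.sum(np.log(theta)))
    return 1.5 * R_KCAL * T, R_CAL * (ln_q + 1.5)


def _vibration(freqs, T: np.ndarray, scale: float):
    """ZPE-separated harmonic terms: (E_thermal kcal/mol, S cal/mol/K)."""
    if freqs is None or len(freqs) == 0:
        return np.zeros_like(T), np.zeros_like(T)
    nu = np.asarray(freqs, dtype=float) * scale
    x = (H_PLANCK * C_LIGHT * 100.0 * nu[:, None]) / (K_BOLTZMANN * T[None, :])
    with np.errstate(over="ignore"):  # frozen modes: x/expm1(x) -> 0 cleanly
        occ = x / np.expm1(x)
    e_th = R_KCAL * T * occ.sum(axis=0)
    s = R_CAL * (occ - np.log1p(-np.exp(-x))).sum(axis=0)
    return e_th, s


def vibrational_thermal_energy(frequencies, T, scale: float = 1.0) -> float:
    """Thermal (above-ZPE) vibrational energy in kcal/mol at temperature T."""
    e, _ = _vibration(np.asarray(frequencies, float), np.atleast_1d(float(T)), scale)
    return float(e[0])


def _resolve_sigma(record: ConformerRecord) -> int:
    if record.symmetry_number != 1 or not record.point_group:
        return record.symmetry_number
    return SYMMETRY_NUMBERS.get(record.point_group, 1)


def thermo_at(
    record: ConformerRecord,
    grid: TemperatureGrid | np.ndarray,
    pressure_atm: float = 1.0,
    freq_scale: float = 1.0,
    standard_state: str = "1atm",
) -> pd.DataFrame:
    """Full RRHO thermochemistry of one conformer over a temperature grid.

    Returns a DataFrame with columns label, T, zpe, enthalpy, entropy,
    gibbs. ``standard_state='1M'`` applies the opt-in gas -> solution
    standard-state shift +RT ln(24.46 T/298.15) to G (via the entropy).
    """
    if not isinstance(grid, TemperatureGrid):
        grid = TemperatureGrid(np.atleast_1d(grid))
    T = grid.values
    if pressure_atm <= 0:
        raise ValidationError("pressure must be > 0")
    record.validate()
    if record.n_atoms > 1 and (record.frequencies is None or len(record.frequencies) == 0):
        raise ValidationError(
            f"record {record.label!r}: frequencies required for a polyatomic"
        )
    rot = record.rotational_constants
    if rot is None and record.n_atoms > 1:
        rot = rotational_constants_from_geometry(record.elements, record.coordinates)
    sigma = _resolve_sigma(record)

    zpe = zero_point_energy(record.frequencies if record.frequencies is not None else [],
                            freq_scale)
    e_elec = record.electronic_energy * HARTREE_TO_KCAL_MOL

    s_trans = _s_translational(record.mass, T, pressure_atm)
    e_rot, s_rot = _rotation(rot, sigma, T)
    e_vib, s_vib = _vibration(record.frequencies, T, freq_scale)
    s_elec = np.full_like(T, R_CAL * np.log(record.multiplicity))

    entropy = s_trans + s_rot + s_vib + s_elec
    if standard_state == "1M":
        entropy = entropy - R_CAL * np.log(MOLAR_VOLUME_298_L * T / 298.15)
    elif standard_state != "1atm":
        raise ValidationError("standard_state must be '1atm' or '1M'")

    enthalpy = e_elec + zpe + 1.5 * R_KCAL * T + e_rot + e_vib + R_KCAL * T
    gibbs = enthalpy - T * entropy / 1000.0

    return pd.DataFrame({
        "label": record.label,
        "T": T,
        "zpe": zpe,
        "enthalpy": enthalpy,
        "entropy": entropy,
        "gibbs": gibbs,
    })


def manifest_thermo(manifest, grid=None, pressure_atm: float = 1.0,
                    freq_scale: float = 1.0, standard_state: str = "1atm") -> pd.DataFrame:
    """Thermochemistry for every record of a manifest, as one long table.

    Adds the grouping columns (species, n_waters, phase) so population and
    hydration analyses can split the table without reloading the manifest.
    """
    grid = grid if grid is not None else TemperatureGrid()
    frames = []
    for rec in manifest.records:
        df = thermo_at(rec, grid, pressure_atm, freq_scale, standard_state)
        df.insert(0, "species", rec.species.value)
        df.insert(1, "n_waters", rec.n_waters)
        df.insert(2, "phase", rec.phase.value)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def relative_zpe_energies(group, freq_scale: float = 1.0) -> np.ndarray:
    """ZPE-corrected relative energies (kcal/mol), minimum mapped to 0.

    All records must belong to one (species, n_waters, phase) group; this is
    the quantity used to rank isomers in stability figures.
    """
    group = list(group)
    if not group:
        raise ValidationError("empty conformer group")
    keys = {r.group_key for r in group}
    if len(keys) > 1:
        raise ValidationError(f"mixed conformer groups: {sorted(map(str, keys))}")
    tot = np.array([
        r.electronic_energy * HARTREE_TO_KCAL_MOL
        + zero_point_energy(r.frequencies if r.frequencies is not None else [], freq_scale)
        for r in group
    ])
    return tot - tot.min()
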