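"""Conformer-ensemble containers and file formats.

An ensemble is described by a YAML manifest of scalar metadata (one record
per optimized cluster isomer) plus one standard XYZ file per geometry.
Records carry everything rigid-rotor harmonic-oscillator thermochemistry
needs: electronic energy (hartree), harmonic wavenumbers (cm^-1), rotational
constants (GHz), mass, spin multiplicity, external symmetry number, and a
phase tag distinguishing gas-phase from continuum-solvated species.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import ATOMIC_MASSES


class Species(str, enum.Enum):
    """Chemical identity of a cluster record."""

    PBA = "PBA"
    WATER_CLUSTER = "WATER_CLUSTER"
    PBA_WATER = "PBA_WATER"


class Phase(str, enum.Enum):
    """Environment tag: bare gas phase or implicit-water continuum."""

    GAS = "gas"
    CONTINUUM_WATER = "continuum_water"


#: (species, n_waters, phase) — the grouping key every downstream module uses.
GroupKey = tuple


class FormatError(ValueError):
    """Malformed input file (bad XYZ header, missing manifest field...)."""


class ValidationError(ValueError):
    """A record violates a physical or bookkeeping invariant."""


def _is_collinear(coords: np.ndarray, tol: float = 1e-6) -> bool:
    if len(coords) < 3:
        return True
    d = coords - coords[0]
    ref = None
    for v in d[1:]:
        if np.linalg.norm(v) > tol:
            ref = v / np.linalg.norm(v)
            break
    if ref is None:
        return True
    for v in d[1:]:
        if np.linalg.norm(np.cross(ref, v)) > tol * max(1.0, np.linalg.norm(v)):
            return False
    return True


@dataclass
class ConformerRecord:
    """One optimized cluster isomer.

    Coordinates are in angstrom, ``electronic_energy`` in hartree,
    ``frequencies`` in cm^-1, ``rotational_constants`` in GHz (three values
    for a nonlinear top, one for a linear molecule, ``None`` for a single
    atom), ``mass`` in amu (derived from the element list when omitted).
    """

    label: str
    species: Species
    n_waters: int
    phase: Phase
    elements: list
    coordinates: np.ndarray
    electronic_energy: float
    frequencies: np.ndarray | None = None
    rotational_constants: np.ndarray | None = None
    mass: float | None = None
    multiplicity: int = 1
    symmetry_number: int = 1
    point_group: str | None = None
    comment: str = ""

    def __post_init__(self):
        self.species = Species(self.species)
        self.phase = Phase(self.phase)
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if self.frequencies is not None:
            self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.rotational_constants is not None:
            self.rotational_constants = np.atleast_1d(
                np.asarray(self.rotational_constants, dtype=float)
            )
        if self.mass is None:
            try:
                self.mass = float(sum(ATOMIC_MASSES[e] for e in self.elements))
            except KeyError as exc:
                raise ValidationError(
                    f"record {self.label!r}: unknown element symbol {exc.args[0]!r}"
                ) from None

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def group_key(self) -> GroupKey:
        return (self.species, self.n_waters, self.phase)

    def expected_mode_count(self) -> int:
        n = self.n_atoms
        if n == 1:
            return 0
        if _is_collinear(self.coordinates):
            return 3 * n - 5
        return 3 * n - 6

    def validate(self) -> None:
        lbl = self.label
        if len(self.elements) != len(self.coordinates):
            raise ValidationError(
                f"record {lbl!r}: {len(self.elements)} elements but "
                f"{len(self.coordinates)} coordinate rows"
            )
        for e in self.elements:
            if e not in ATOMIC_MASSES:
                raise ValidationError(f"record {lbl!r}: unknown element symbol {e!r}")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError(f"record {lbl!r}: non-finite coordinates")
        if self.electronic_energy is None or not math.isfinite(self.electronic_energy):
            raise ValidationError(f"record {lbl!r}: missing or non-finite electronic energy")
        if self.multiplicity < 1:
            raise ValidationError(f"record {lbl!r}: multiplicity must be >= 1")
        if self.symmetry_number < 1:
            raise ValidationError(f"record {lbl!r}: symmetry number must be >= 1")
        if self.n_waters < 0:
            raise ValidationError(f"record {lbl!r}: n_waters must be >= 0")
        if self.species is Species.PBA and self.n_waters != 0:
            raise ValidationError(f"record {lbl!r}: species PBA requires n_waters = 0")
        if self.species is Species.PBA_WATER and self.n_waters < 1:
            raise ValidationError(f"record {lbl!r}: species PBA_WATER requires n_waters >= 1")
        if self.frequencies is not None and len(self.frequencies) > 0:
            if np.any(self.frequencies <= 0):
                bad = float(self.frequencies[self.frequencies <= 0][0])
                raise ValidationError(
                    f"record {lbl!r}: non-positive frequency {bad:g} cm^-1 "
                    "(only minima with all-real modes are accepted)"
                )
            expected = self.expected_mode_count()
            if len(self.frequencies) != expected:
                raise ValidationError(
                    f"record {lbl!r}: {len(self.frequencies)} frequencies, "
                    f"expected {expected} for {self.n_atoms} atoms"
                )


@dataclass
class EnsembleManifest:
    """A validated collection of conformer records plus free-text provenance."""

    records: list = field(default_factory=list)
    provenance: str = ""

    def validate(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.label in seen:
                raise ValidationError(f"duplicate label {rec.label!r} in manifest")
            seen.add(rec.label)
            rec.validate()
        for key, group in self.groups().items():
            n_atoms = {r.n_atoms for r in group}
            masses = {round(r.mass, 9) for r in group}
            if len(n_atoms) > 1 or len(masses) > 1:
                labels = [r.label for r in group]
                raise ValidationError(
                    f"group {tuple(getattr(k, 'value', k) for k in key)}: records "
                    f"{labels} disagree on atom count or mass"
                )

    def groups(self) -> dict:
        out: dict = {}
        for rec in self.records:
            out.setdefault(rec.group_key, []).append(rec)
        return out


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path) -> tuple:
    """Read a standard XYZ file; returns (elements, coordinates, comment)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise FormatError(f"{path}: first line is not an atom count") from None
    comment = lines[1] if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < n:
        raise FormatError(f"{path}: declared {n} atoms but found {len(body)} atom lines")
    elements, coords = [], []
    for ln in body[:n]:
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed atom line {ln!r}")
        sym = parts[0].capitalize() if len(parts[0]) > 1 else parts[0].upper()
        if sym not in ATOMIC_MASSES:
            raise ValidationError(f"{path}: unknown element symbol {parts[0]!r}")
        elements.append(sym)
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError:
            raise FormatError(f"{path}: non-numeric coordinate in line {ln!r}") from None
    return elements, np.asarray(coords, dtype=float), comment


def write_xyz(path, elements: Sequence[str], coordinates, comment: str = "") -> None:
    coords = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    if len(elements) != len(coords):
        raise ValidationError("element count does not match coordinate rows")
    lines = [str(len(elements)), comment.replace("\n", " ")]
    for e, (x, y, z) in zip(elements, coords):
        lines.append(f"{e:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Manifest (YAML + per-conformer XYZ files)
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("label", "species", "n_waters", "phase", "xyz",
                    "electronic_energy_hartree")


def read_manifest(path) -> EnsembleManifest:
    """Load and fully validate an ensemble manifest.

    The manifest is a YAML document with a ``records`` list; each record
    references its geometry through a path relative to the manifest file.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "records" not in doc:
        raise FormatError(f"{path}: manifest must be a mapping with a 'records' list")
    records = []
    for raw in doc["records"]:
        missing = [f for f in _REQUIRED_FIELDS if f not in raw]
        if missing:
            raise FormatError(
                f"{path}: record {raw.get('label', '<unlabelled>')!r} missing "
                f"required field(s) {missing}"
            )
        elements, coords, comment = read_xyz(path.parent / raw["xyz"])
        rec = ConformerRecord(
            label=str(raw["label"]),
            species=raw["species"],
            n_waters=int(raw["n_waters"]),
            phase=raw["phase"],
            elements=elements,
            coordinates=coords,
            electronic_energy=float(raw["electronic_energy_hartree"]),
            frequencies=raw.get("frequencies_cm1"),
            rotational_constants=raw.get("rotational_constants_ghz"),
            mass=raw.get("mass_amu"),
            multiplicity=int(raw.get("multiplicity", 1)),
            symmetry_number=int(raw.get("symmetry_number", 1)),
            point_group=raw.get("point_group"),
            comment=comment,
        )
        records.append(rec)
    manifest = EnsembleManifest(records=records, provenance=str(doc.get("provenance", "")))
    manifest.validate()
    return manifest


def write_manifest(manifest: EnsembleManifest, path, xyz_dir: str = "xyz") -> None:
    """Write a manifest plus one XYZ file per record (fixed precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    xyz_root = path.parent / xyz_dir
    xyz_root.mkdir(parents=True, exist_ok=True)
    raws = []
    for rec in manifest.records:
        rel = f"{xyz_dir}/{rec.label}.xyz"
        write_xyz(path.parent / rel, rec.elements, rec.coordinates, rec.comment)
        raw = {
            "label": rec.label,
            "species": rec.species.value,
            "n_waters": int(rec.n_waters),
            "phase": rec.phase.value,
            "xyz": rel,
            "electronic_energy_hartree": float(rec.electronic_energy),
            "mass_amu": float(rec.mass),
            "multiplicity": int(rec.multiplicity),
            "symmetry_number": int(rec.symmetry_number),
        }
        if rec.frequencies is not None:
            raw["frequencies_cm1"] = [round(float(f), 6) for f in rec.frequencies]
        if rec.rotational_constants is not None:
            raw["rotational_constants_ghz"] = [
                round(float(b), 9) for b in rec.rotational_constants
            ]
        if rec.point_group:
            raw["point_group"] = rec.point_group
        raws.append(raw)
    doc = {"provenance": manifest.provenance, "records": raws}
    path.write_text(yaml.safe_dump(doc, sort_keys=False, default_flow_style=None))


# ---------------------------------------------------------------------------
# Generic delimited result tables
# ---------------------------------------------------------------------------

def write_table(rows, path, float_format: str = "%.10g") -> None:
    """Write result records as a CSV with deterministic column order.

    ``rows`` is a DataFrame or an iterable of dataclasses / mappings with a
    homogeneous schema; an empty iterable produces a header-only file when a
    DataFrame (which carries its schema) is given, otherwise an empty file
    with no rows cannot infer columns and raises.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        dicts = []
        for r in rows:
            if hasattr(r, "__dataclass_fields__"):
                dicts.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                dicts.append(dict(r))
        keys = list(dicts[0]) if dicts else []
        if dicts and any(list(d) != keys for d in dicts):
            raise ValidationError("write_table requires a homogeneous row schema")
        df = pd.DataFrame(dicts, columns=keys)
    df.to_csv(path, index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
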