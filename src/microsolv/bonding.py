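"""Non-covalent interaction analysis: QTAIM classification, geometric
hydrogen-bond detection, and NBO second-order stabilization energies.

A bond critical point (BCP) is classified by its atom context (O-H...O,
C-H...O, O-H...pi, O...C); the sign of the density Laplacian decides
covalency (positive = closed-shell, i.e. non-covalent), and the electron
density rho orders interactions by strength. Reference min/max envelopes of
(rho, laplacian) per contact type, taken from microhydrated-arylboronic
cluster data, serve as validation ranges only — the overlapping laplacian
intervals make them unsuitable as a classification key.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .constants import COVALENT_RADII, HARTREE_TO_KCAL_MOL
from .conformer_io import ValidationError

__all__ = [
    "TABLE_ENVELOPES",
    "BCPRecord",
    "Classification",
    "classify_bcp",
    "rank_by_density",
    "HBondCriteria",
    "Contact",
    "detect_hbonds_geometric",
    "NBOInteraction",
    "e2",
    "strongest_interaction",
    "read_bcp_table",
    "read_nbo_table",
]

# (rho_min, rho_max), (lap_min, lap_max) in atomic units per contact type.
TABLE_ENVELOPES = {
    "OH_O": ((0.0115, 0.0548), (0.0435, 0.1296)),
    "CH_O": ((0.0049, 0.0051), (0.0195, 0.0232)),
    "OH_PI": ((0.0078, 0.0088), (0.0254, 0.0279)),
    "O_C": ((0.0057, 0.0065), (0.0185, 0.0226)),
}

_ATOM_RE = re.compile(r"^([A-Za-z]{1,2})\s*(\d*)$")
_PI_TAGS = {"pi", "ring", "PI", "RING"}


def _element_of(atom_tag: str) -> str:
    """'O18' -> 'O'; ring/pi tags pass through as 'pi'."""
    tag = str(atom_tag).strip()
    if tag in _PI_TAGS or tag.lower().startswith(("ring", "pi")):
        return "pi"
    m = _ATOM_RE.match(tag)
    if not m:
        raise ValidationError(f"cannot parse atom tag {atom_tag!r}")
    sym = m.group(1)
    return sym.capitalize() if len(sym) > 1 else sym.upper()


@dataclass
class BCPRecord:
    """One bond path: donor (and optional bridging hydrogen) to acceptor."""

    donor_atom: str
    acceptor_atom: str
    rho: float
    laplacian: float
    hydrogen: str | None = None
    label: str | None = None  # assigned by classify_bcp


@dataclass
class Classification:
    label: str
    non_covalent: bool
    in_envelope: bool


class EnvelopeWarning(UserWarning):
    """(rho, laplacian) falls outside the reference range for its label."""


def classify_bcp(record: BCPRecord) -> Classification:
    """Assign a contact-type label and covalency flag to a bond path.

    The atom-context triplet is the classification key; a positive
    Laplacian is required for the non-covalent flag; (rho, laplacian)
    outside the reference envelope for the assigned label raises an
    ``EnvelopeWarning`` but never an error.
    """
    if record.rho <= 0:
        raise ValidationError("electron density at a BCP must be > 0")
    don = _element_of(record.donor_atom)
    acc = _element_of(record.acceptor_atom)
    if record.hydrogen is not None:
        if don == "O" and acc == "O":
            label = "OH_O"
        elif don == "C" and acc == "O":
            label = "CH_O"
        elif don == "O" and acc == "pi":
            label = "OH_PI"
        else:
            label = "other"
    else:
        if {don, acc} == {"O", "C"}:
            label = "O_C"
        else:
            label = "other"
    non_covalent = record.laplacian > 0
    in_envelope = True
    if label in TABLE_ENVELOPES:
        (rlo, rhi), (llo, lhi) = TABLE_ENVELOPES[label]
        in_envelope = (rlo <= record.rho <= rhi) and (llo <= record.laplacian <= lhi)
        if not in_envelope:
            warnings.warn(
                f"{label} BCP (rho={record.rho:g}, lap={record.laplacian:g}) "
                "outside the reference envelope",
                EnvelopeWarning, stacklevel=2,
            )
    record.label = label
    return Classification(label=label, non_covalent=non_covalent,
                          in_envelope=in_envelope)


def rank_by_density(records) -> list:
    """Bond paths ordered strongest first (descending rho, stable ties)."""
    records = list(records)
    order = sorted(range(len(records)), key=lambda i: -records[i].rho)
    return [records[i] for i in order]


# ---------------------------------------------------------------------------
# Geometric hydrogen-bond detection
# ---------------------------------------------------------------------------

@dataclass
class HBondCriteria:
    """Distance/angle cutoffs (conventional literature values, configurable)."""

    oh_o_dist: float = 2.5    # H...O, angstrom
    oh_o_angle: float = 140.0  # D-H...A, degrees
    ch_o_dist: float = 2.8
    ch_o_angle: float = 120.0
    pi_dist: float = 3.0      # H to ring centroid
    pi_elevation: float = 60.0  # degrees above the ring plane
    covalent_scale: float = 1.25
    ring_planarity: float = 0.15  # max deviation from best-fit plane, angstrom


@dataclass
class Contact:
    kind: str        # OH_O, CH_O or OH_PI
    donor: int       # atom index of the donor heavy atom
    hydrogen: int
    acceptor: object  # atom index, or tuple of ring atom indices
    distance: float
    angle: float


def _covalent_graph(elements, coords, scale: float) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(elements)))
    for i in range(len(elements)):
        for j in range(i + 1, len(elements)):
            r = np.linalg.norm(coords[i] - coords[j])
            cutoff = scale * (COVALENT_RADII.get(elements[i], 0.8)
                              + COVALENT_RADII.get(elements[j], 0.8))
            if r < 0.5:
                raise ValidationError(
                    f"atoms {i} and {j} overlap (distance {r:.3f} A)"
                )
            if r <= cutoff:
                g.add_edge(i, j)
    return g


def _aromatic_rings(elements, coords, graph: nx.Graph, planarity: float) -> list:
    """Six-membered all-carbon near-planar cycles."""
    rings = []
    seen = set()
    for cyc in nx.simple_cycles(graph, length_bound=6):
        if len(cyc) != 6 or not all(elements[i] == "C" for i in cyc):
            continue
        key = frozenset(cyc)
        if key in seen:
            continue
        seen.add(key)
        pts = coords[list(cyc)]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        normal = vt[2]
        dev = np.abs((pts - centroid) @ normal)
        if dev.max() <= planarity:
            rings.append((tuple(sorted(cyc)), centroid, normal))
    return rings


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cosv = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def detect_hbonds_geometric(elements, coordinates,
                            criteria: HBondCriteria | None = None) -> list:
    """Hydrogen-bond contacts from coordinates alone.

    O-H...O and C-H...O contacts by H...acceptor distance plus donor-H-
    acceptor angle; O-H...pi contacts by hydrogen-to-aromatic-centroid
    distance plus elevation angle above the ring plane. This is a geometric
    stand-in for wavefunction-level bond-path analysis and reports no
    electron densities.
    """
    crit = criteria or HBondCriteria()
    coords = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    elements = list(elements)
    graph = _covalent_graph(elements, coords, crit.covalent_scale)
    rings = _aromatic_rings(elements, coords, graph, crit.ring_planarity)
    ring_atoms = set().union(*(set(r[0]) for r in rings)) if rings else set()

    contacts = []
    for h in range(len(elements)):
        if elements[h] != "H":
            continue
        donors = [i for i in graph.neighbors(h) if elements[i] in ("O", "C")]
        if not donors:
            continue
        donor = donors[0]
        if elements[donor] == "O":
            dist_cut, ang_cut, kind = crit.oh_o_dist, crit.oh_o_angle, "OH_O"
        else:
            dist_cut, ang_cut, kind = crit.ch_o_dist, crit.ch_o_angle, "CH_O"
        # Oxygen acceptors.
        for a in range(len(elements)):
            if elements[a] != "O" or a == donor or graph.has_edge(h, a):
                continue
            d = float(np.linalg.norm(coords[h] - coords[a]))
            if d > dist_cut:
                continue
            ang = _angle_deg(coords[donor] - coords[h], coords[a] - coords[h])
            if ang >= ang_cut:
                contacts.append(Contact(kind, donor, h, a, d, ang))
        # Aromatic pi acceptors (hydroxyl donors only).
        if elements[donor] == "O":
            for ring, centroid, normal in rings:
                if donor in ring:
                    continue
                v = coords[h] - centroid
                d = float(np.linalg.norm(v))
                if d > crit.pi_dist or d < 1e-6:
                    continue
                # elevation above the plane, independent of which side the
                # normal points to
                elev = abs(90.0 - _angle_deg(v, normal))
                if elev >= crit.pi_elevation:
                    contacts.append(Contact("OH_PI", donor, h, ring, d, elev))
    return contacts


# ---------------------------------------------------------------------------
# NBO second-order perturbation energies
# ---------------------------------------------------------------------------

@dataclass
class NBOInteraction:
    """One donor -> acceptor orbital delocalization entry."""

    donor_orbital: str
    acceptor_orbital: str
    occupancy: float      # donor occupancy q, electrons
    fock_element: float   # F(i,j), hartree
    eps_donor: float      # hartree
    eps_acceptor: float   # hartree
    e2: float = field(default=None)  # kcal/mol, filled on construction

    def __post_init__(self):
        if self.e2 is None:
            self.e2 = e2(self.occupancy, self.fock_element,
                         self.eps_donor, self.eps_acceptor)


def e2(q: float, F: float, eps_donor: float, eps_acceptor: float) -> float:
    """Second-order stabilization q F^2 / (eps_j - eps_i), in kcal/mol.

    Inputs are in atomic units; a non-positive orbital-energy gap denotes a
    non-stabilizing ordering and is rejected.
    """
    if q < 0:
        raise ValidationError("donor occupancy must be >= 0")
    gap = eps_acceptor - eps_donor
    if gap <= 0:
        raise ValidationError(
            "eps_acceptor must exceed eps_donor for a stabilizing interaction"
        )
    return float(q * F * F / gap) * HARTREE_TO_KCAL_MOL


def strongest_interaction(interactions) -> NBOInteraction:
    """Entry with the largest E(2); ties keep the earliest entry."""
    interactions = list(interactions)
    if not interactions:
        raise ValidationError("empty interaction list")
    best = interactions[0]
    for it in interactions[1:]:
        if it.e2 > best.e2:
            best = it
    return best


# ---------------------------------------------------------------------------
# Delimited-table adapters
# ---------------------------------------------------------------------------

def read_bcp_table(path) -> list:
    """CSV columns: donor, hydrogen (may be empty), acceptor, rho_au,
    laplacian_au."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        hyd = row.get("hydrogen")
        if pd.isna(hyd) or str(hyd).strip() == "":
            hyd = None
        out.append(BCPRecord(
            donor_atom=str(row["donor"]), hydrogen=hyd,
            acceptor_atom=str(row["acceptor"]),
            rho=float(row["rho_au"]), laplacian=float(row["laplacian_au"]),
        ))
    return out


def read_nbo_table(path) -> list:
    """CSV columns: donor_label, acceptor_label, q, F_au, eps_donor_au,
    eps_acceptor_au."""
    df = pd.read_csv(path)
    return [
        NBOInteraction(
            donor_orbital=str(r["donor_label"]),
            acceptor_orbital=str(r["acceptor_label"]),
            occupancy=float(r["q"]), fock_element=float(r["F_au"]),
            eps_donor=float(r["eps_donor_au"]),
            eps_acceptor=float(r["eps_acceptor_au"]),
        )
        for _, r in df.iterrows()
    ]
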