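"""Boltzmann conformer populations and ensemble-averaged thermodynamics.

Weights follow P_i(T) = exp(-G_i/RT) / sum_j exp(-G_j/RT), evaluated
stably by shifting all free energies by the group minimum before
exponentiation. The ensemble free energy (and enthalpy) is the
population-weighted arithmetic mean of the per-conformer values; the
thermodynamically strict alternative -RT ln(sum exp(-G_i/RT)) is available
behind an explicit option for sensitivity checks, never as the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import R_KCAL
from .conformer_io import ValidationError
from .rrho import relative_zpe_energies

__all__ = [
    "boltzmann_weights",
    "ensemble_average",
    "log_sum_exp_free_energy",
    "population_curves",
    "dominant_conformers",
    "filter_significant",
    "energy_window_filter",
    "ensemble_thermo",
    "build_ensembles",
    "EnsembleResult",
]


def boltzmann_weights(gibbs_by_conformer, T: float) -> np.ndarray:
    """Conformer probabilities at temperature T (kcal/mol free energies)."""
    g = np.asarray(gibbs_by_conformer, dtype=float)
    if g.size == 0:
        raise ValidationError("boltzmann_weights: empty free-energy list")
    if not np.all(np.isfinite(g)):
        raise ValidationError("boltzmann_weights: non-finite free energy")
    if T <= 0:
        raise ValidationError("boltzmann_weights: temperature must be > 0")
    x = -(g - g.min()) / (R_KCAL * T)
    w = np.exp(x)
    return w / w.sum()


def ensemble_average(values, weights) -> float:
    """Population-weighted mean of per-conformer values (kcal/mol in, out)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValidationError("ensemble_average: length mismatch")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("ensemble_average: weights must sum to 1")
    return float(v @ w)


def log_sum_exp_free_energy(gibbs_by_conformer, T: float) -> float:
    """-RT ln sum_i exp(-G_i/RT): the strict partition-function ensemble G."""
    g = np.asarray(gibbs_by_conformer, dtype=float)
    if g.size == 0:
        raise ValidationError("empty free-energy list")
    if T <= 0:
        raise ValidationError("temperature must be > 0")
    rt = R_KCAL * T
    gmin = g.min()
    return float(gmin - rt * np.log(np.sum(np.exp(-(g - gmin) / rt))))


def _pivot(thermo: pd.DataFrame, column: str) -> pd.DataFrame:
    pivot = thermo.pivot_table(index="label", columns="T", values=column, sort=False)
    if pivot.isna().any().any():
        raise ValidationError(
            "inconsistent temperature grids across conformers in one group"
        )
    return pivot


def population_curves(thermo: pd.DataFrame) -> pd.DataFrame:
    """Per-conformer Boltzmann weight at every grid temperature.

    ``thermo`` is a long per-conformer table for ONE group with columns
    label, T, gibbs. Returns a DataFrame indexed by conformer label with one
    column per temperature.
    """
    gpiv = _pivot(thermo, "gibbs")
    weights = np.column_stack([
        boltzmann_weights(gpiv[t].to_numpy(), float(t)) for t in gpiv.columns
    ])
    return pd.DataFrame(weights, index=gpiv.index, columns=gpiv.columns)


def dominant_conformers(curves: pd.DataFrame) -> pd.Series:
    """Label of the highest-weight conformer at each temperature."""
    return curves.idxmax(axis=0)


def filter_significant(curves: pd.DataFrame, threshold: float = 0.10) -> list:
    """Conformers whose weight strictly exceeds ``threshold`` somewhere.

    The reporting filter is strict ("more than 10%"): a conformer pinned at
    exactly the threshold is dropped.
    """
    if not 0 <= threshold < 1:
        raise ValidationError("threshold must lie in [0, 1)")
    keep = (curves > threshold).any(axis=1)
    return list(curves.index[keep])


def energy_window_filter(group, window: float = 2.0, freq_scale: float = 1.0) -> list:
    """Records whose ZPE-corrected relative energy is <= window (inclusive).

    The completeness window restricts a Boltzmann analysis to the structures
    that can contribute appreciably; 2.0 kcal/mol retains everything above
    ~3% population at room temperature.
    """
    group = list(group)
    rel = relative_zpe_energies(group, freq_scale)
    # inclusive boundary, robust to round-off in the hartree -> kcal path
    return [rec for rec, e in zip(group, rel) if e <= window + 1e-9]


@dataclass
class EnsembleResult:
    """Boltzmann-averaged thermodynamics of one conformer group."""

    group_key: tuple
    table: pd.DataFrame     # index T; columns gibbs, enthalpy, n_conformers
    weights: pd.DataFrame   # labels x temperatures


def ensemble_thermo(thermo: pd.DataFrame, method: str = "weighted_mean") -> pd.DataFrame:
    """Ensemble G(T) and H(T) for one group's per-conformer table.

    ``method='weighted_mean'`` (default) averages conformer free energies
    and enthalpies with their Boltzmann weights; ``method='log_sum_exp'``
    replaces the free energy by -RT ln sum exp(-G_i/RT) (enthalpy remains a
    weighted mean).
    """
    if method not in ("weighted_mean", "log_sum_exp"):
        raise ValidationError("method must be 'weighted_mean' or 'log_sum_exp'")
    gpiv = _pivot(thermo, "gibbs")
    hpiv = _pivot(thermo, "enthalpy")
    temps = [float(t) for t in gpiv.columns]
    g_out, h_out = [], []
    for t in gpiv.columns:
        g = gpiv[t].to_numpy()
        w = boltzmann_weights(g, float(t))
        if method == "log_sum_exp":
            g_out.append(log_sum_exp_free_energy(g, float(t)))
        else:
            g_out.append(ensemble_average(g, w))
        h_out.append(ensemble_average(hpiv[t].to_numpy(), w))
    return pd.DataFrame(
        {"gibbs": g_out, "enthalpy": h_out, "n_conformers": len(gpiv)},
        index=pd.Index(temps, name="T"),
    )


def build_ensembles(thermo_long: pd.DataFrame, method: str = "weighted_mean") -> dict:
    """Split a long thermo table by group and Boltzmann-average each group.

    Input columns: species, n_waters, phase, label, T, gibbs, enthalpy.
    Returns {(species, n_waters, phase): DataFrame indexed by T}.
    """
    out = {}
    for (species, n, phase), sub in thermo_long.groupby(
            ["species", "n_waters", "phase"], sort=False):
        out[(species, int(n), phase)] = ensemble_thermo(sub, method=method)
    return out
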