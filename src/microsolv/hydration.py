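"""Cluster-continuum hydration free energy and enthalpy assembly.

The solvation reaction PBA(g) + (H2O)_n(s) -> PBA(H2O)_n(s) gives

    dG_hyd(n, T) = G_s[PBA(H2O)_n] - G_s[(H2O)_n] - G_g[PBA]

(enthalpy analogously), with every term the Boltzmann-ensemble value of its
conformer group. Convergence in n is diagnosed by averaging over a size
window (default n = 5-10) at a reference temperature; the hydration entropy
is the negated least-squares slope of dG versus T, and the enthalpy curve's
max-min spread over the grid flags temperature independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conformer_io import Phase, Species, ValidationError

__all__ = [
    "hydration_free_energy",
    "hydration_enthalpy",
    "hydration_profile",
    "window_average",
    "entropy_from_slope",
    "enthalpy_flatness",
    "assemble_hydration",
    "SlopeFit",
    "HydrationSummary",
]


def _group(ensembles: dict, key: tuple):
    # Enum members compare equal to their string values, so normalise.
    species, n, phase = key
    for cand in (key, (getattr(species, "value", species), n,
                       getattr(phase, "value", phase))):
        if cand in ensembles:
            return ensembles[cand]
    raise ValidationError(
        f"missing ensemble group ({getattr(species, 'value', species)}, {n}, "
        f"{getattr(phase, 'value', phase)})"
    )


def _value(table: pd.DataFrame, T: float, column: str) -> float:
    idx = np.asarray(table.index, dtype=float)
    hit = np.isclose(idx, T, rtol=0, atol=1e-9)
    if not hit.any():
        raise ValidationError(f"temperature {T} K not on the ensemble grid")
    return float(table[column].to_numpy()[hit.argmax()])


def _assembly(n: int, T: float, ensembles: dict, column: str) -> float:
    if n < 0:
        raise ValidationError("cluster size n must be >= 0")
    pba_g = _group(ensembles, (Species.PBA, 0, Phase.GAS))
    if n == 0:
        # No explicit solvent: the continuum-only estimate G_s[PBA] - G_g[PBA].
        pba_s = _group(ensembles, (Species.PBA, 0, Phase.CONTINUUM_WATER))
        return _value(pba_s, T, column) - _value(pba_g, T, column)
    clus = _group(ensembles, (Species.PBA_WATER, n, Phase.CONTINUUM_WATER))
    wat = _group(ensembles, (Species.WATER_CLUSTER, n, Phase.CONTINUUM_WATER))
    return (_value(clus, T, column) - _value(wat, T, column)
            - _value(pba_g, T, column))


def hydration_free_energy(n: int, T: float, ensembles: dict) -> float:
    """dG_hyd for cluster size n at temperature T, in kcal/mol."""
    return _assembly(n, T, ensembles, "gibbs")


def hydration_enthalpy(n: int, T: float, ensembles: dict) -> float:
    """dH_hyd for cluster size n at temperature T, in kcal/mol."""
    return _assembly(n, T, ensembles, "enthalpy")


def hydration_profile(ensembles: dict, sizes, temperatures=None) -> pd.DataFrame:
    """dG_hyd and dH_hyd for every requested (n, T), as a long table."""
    rows = []
    for n in sizes:
        if temperatures is None:
            key = (Species.PBA_WATER, n, Phase.CONTINUUM_WATER) if n > 0 else \
                  (Species.PBA, 0, Phase.CONTINUUM_WATER)
            temps = [float(t) for t in _group(ensembles, key).index]
        else:
            temps = [float(t) for t in temperatures]
        for t in temps:
            rows.append({
                "n": int(n),
                "T": t,
                "dG_hyd": hydration_free_energy(n, t, ensembles),
                "dH_hyd": hydration_enthalpy(n, t, ensembles),
            })
    return pd.DataFrame(rows)


def window_average(profile: pd.DataFrame, window=(5, 10), t_ref: float = 298.15):
    """Unweighted mean of dG and dH over sizes in ``window`` at ``t_ref``.

    Returns (mean_dG, mean_dH). Sizes absent from the profile are simply
    not averaged; an empty window is an error.
    """
    lo, hi = window
    sel = profile[(profile["n"] >= lo) & (profile["n"] <= hi)
                  & np.isclose(profile["T"], t_ref, rtol=0, atol=1e-9)]
    if sel.empty:
        raise ValidationError(
            f"no cluster sizes in window {lo}-{hi} at T = {t_ref} K"
        )
    return float(sel["dG_hyd"].mean()), float(sel["dH_hyd"].mean())


@dataclass
class SlopeFit:
    """OLS line through dG(T); hydration entropy is the negated slope."""

    entropy: float        # kcal mol^-1 K^-1, = -slope
    slope: float          # kcal mol^-1 K^-1
    intercept: float      # kcal/mol
    residual_norm: float  # L2 norm of fit residuals, linearity diagnostic


def entropy_from_slope(temperatures, dg_values) -> SlopeFit:
    """Hydration entropy from the temperature dependence of dG_hyd."""
    T = np.asarray(temperatures, dtype=float)
    g = np.asarray(dg_values, dtype=float)
    if T.size != g.size:
        raise ValidationError("temperature and dG arrays differ in length")
    if T.size < 3:
        raise ValidationError("need at least 3 grid points for the slope")
    if np.ptp(T) == 0:
        raise ValidationError("degenerate temperature grid")
    slope, intercept = np.polyfit(T, g, 1)
    resid = g - (slope * T + intercept)
    return SlopeFit(entropy=-float(slope), slope=float(slope),
                    intercept=float(intercept),
                    residual_norm=float(np.linalg.norm(resid)))


def enthalpy_flatness(dh_values, tolerance: float = 1.0):
    """(max - min) of dH over the grid and a temperature-independence flag.

    The default 1.0 kcal/mol tolerance is the conventional bound below which
    an enthalpy curve is treated as temperature-independent.
    """
    h = np.asarray(dh_values, dtype=float)
    if h.size < 2:
        raise ValidationError("need at least 2 grid points for flatness")
    spread = float(h.max() - h.min())
    return spread, spread < tolerance


@dataclass
class HydrationSummary:
    """Windowed hydration estimate with its convergence diagnostics."""

    profile: pd.DataFrame        # long (n, T, dG_hyd, dH_hyd)
    window: tuple
    t_ref: float
    window_mean_G: float         # kcal/mol
    window_mean_H: float         # kcal/mol
    entropy: float               # kcal mol^-1 K^-1
    slope_residual_norm: float
    enthalpy_flatness: float     # kcal/mol
    temperature_independent: bool


def assemble_hydration(ensembles: dict, sizes=range(1, 11), window=(5, 10),
                       t_ref: float = 298.15, flat_tolerance: float = 1.0,
                       temperatures=None) -> HydrationSummary:
    """Full hydration analysis: profile, window means, slope, flatness.

    The entropy slope and flatness are evaluated on the size-averaged
    dG(T) / dH(T) curves over the window (per-size curves remain available
    in ``profile``).
    """
    profile = hydration_profile(ensembles, sizes, temperatures)
    mean_g, mean_h = window_average(profile, window, t_ref)
    lo, hi = window
    win = profile[(profile["n"] >= lo) & (profile["n"] <= hi)]
    if win.empty:
        raise ValidationError(f"no cluster sizes in window {lo}-{hi}")
    curve = win.groupby("T", sort=True)[["dG_hyd", "dH_hyd"]].mean()
    fit = entropy_from_slope(curve.index.to_numpy(), curve["dG_hyd"].to_numpy())
    spread, flat = enthalpy_flatness(curve["dH_hyd"].to_numpy(), flat_tolerance)
    return HydrationSummary(
        profile=profile, window=tuple(window), t_ref=t_ref,
        window_mean_G=mean_g, window_mean_H=mean_h,
        entropy=fit.entropy, slope_residual_norm=fit.residual_norm,
        enthalpy_flatness=spread, temperature_independent=flat,
    )
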