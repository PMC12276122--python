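import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microsolv.constants import R_KCAL
from microsolv.conformer_io import ValidationError
from microsolv.ensemble import (boltzmann_weights, dominant_conformers,
                                energy_window_filter, ensemble_average,
                                ensemble_thermo, filter_significant,
                                log_sum_exp_free_energy, population_curves)
from microsolv.synthetic import ScenarioSpec, generate_ensemble

finite_g = st.lists(st.floats(-20.0, 20.0, allow_nan=False), min_size=1,
                    max_size=8)
temps = st.floats(20.0, 400.0)


def _curves(weights_by_label, temps=(20.0, 100.0, 300.0)):
    return pd.DataFrame(weights_by_label, index=list(temps)).T


class TestBoltzmannWeights:
    def test_degenerate_pair_splits_evenly(self):
        assert np.allclose(boltzmann_weights([0.0, 0.0], 150.0), [0.5, 0.5])

    def test_rt_ln2_gap_gives_two_thirds(self):
        T = 298.15
        w = boltzmann_weights([0.0, R_KCAL * T * np.log(2.0)], T)
        assert np.allclose(w, [2.0 / 3.0, 1.0 / 3.0], atol=1e-12)

    def test_matches_direct_unshifted_evaluation(self):
        g = np.array([0.0, 1.0, 2.5])
        T = 298.15
        naive = np.exp(-g / (R_KCAL * T))
        naive /= naive.sum()
        assert np.allclose(boltzmann_weights(g, T), naive, atol=1e-12)

    def test_empty_and_bad_temperature_rejected(self):
        with pytest.raises(ValidationError):
            boltzmann_weights([], 300.0)
        with pytest.raises(ValidationError):
            boltzmann_weights([0.0], 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(g=finite_g, T=temps)
    def test_normalization_range_and_ordering(self, g, T):
        w = boltzmann_weights(g, T)
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all((w >= 0) & (w <= 1))
        for i in range(len(g)):
            for j in range(len(g)):
                if g[i] < g[j]:
                    assert w[i] >= w[j] - 1e-12

    @settings(max_examples=200, derandomize=True)
    @given(g=finite_g, T=temps, shift=st.floats(-50.0, 50.0))
    def test_shift_invariance_and_naive_agreement(self, g, T, shift):
        g = np.asarray(g)
        w = boltzmann_weights(g, T)
        assert np.allclose(w, boltzmann_weights(g + shift, T), atol=1e-10)
        naive = np.exp(-g / (R_KCAL * T))
        if np.isfinite(naive).all() and naive.sum() > 0:
            assert np.allclose(w, naive / naive.sum(), atol=1e-10)


class TestEnsembleAverage:
    def test_single_conformer_is_identity(self):
        assert ensemble_average([-42.0], [1.0]) == -42.0

    def test_even_weights_give_midpoint(self):
        assert ensemble_average([-70.0, -74.0], [0.5, 0.5]) == -72.0

    def test_matches_dot_product_oracle(self, rng):
        v = rng.normal(size=5)
        w = rng.dirichlet(np.ones(5))
        assert ensemble_average(v, w) == pytest.approx(float(v @ w), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ensemble_average([1.0, 2.0], [1.0])

    @settings(max_examples=100, derandomize=True)
    @given(g=finite_g, T=temps, shift=st.floats(-30.0, 30.0))
    def test_average_covariant_under_common_shift(self, g, T, shift):
        g = np.asarray(g)
        w = boltzmann_weights(g, T)
        a0 = ensemble_average(g, w)
        a1 = ensemble_average(g + shift, boltzmann_weights(g + shift, T))
        assert a1 - a0 == pytest.approx(shift, abs=1e-9)


class TestLogSumExp:
    def test_never_above_minimum(self, rng):
        for _ in range(20):
            g = rng.normal(scale=3.0, size=6)
            T = rng.uniform(20, 400)
            assert log_sum_exp_free_energy(g, T) <= g.min() + 1e-12

    def test_single_conformer_is_identity(self):
        assert log_sum_exp_free_energy([-5.0], 300.0) == pytest.approx(-5.0)


class TestPopulationCurves:
    def _thermo(self, gibbs_by_label, temps=(20.0, 100.0, 300.0)):
        rows = []
        for label, gs in gibbs_by_label.items():
            for t, g in zip(temps, gs):
                rows.append({"label": label, "T": t, "gibbs": g,
                             "enthalpy": g})
        return pd.DataFrame(rows)

    def test_degenerate_conformers_uniform(self):
        df = self._thermo({"a": [0, 0, 0], "b": [0, 0, 0], "c": [0, 0, 0]})
        curves = population_curves(df)
        assert np.allclose(curves.to_numpy(), 1.0 / 3.0)

    def test_two_kcal_gap_dominates_at_20k(self):
        df = self._thermo({"lo": [0.0] * 3, "hi": [2.0] * 3})
        curves = population_curves(df)
        assert curves.loc["lo", 20.0] > 1.0 - 1e-10
        assert (dominant_conformers(curves) == "lo").all()

    def test_global_minimum_weight_monotone_in_t(self, default_scenario):
        sub = default_scenario.thermo.query(
            "species == 'WATER_CLUSTER' and n_waters == 5")
        curves = population_curves(sub[["label", "T", "gibbs"]])
        gmin = curves.iloc[:, 0].idxmax()  # dominant at the coldest point
        w = curves.loc[gmin].to_numpy()
        assert np.all(np.diff(w) <= 1e-12)

    def test_inconsistent_grids_rejected(self):
        df = self._thermo({"a": [0, 0, 0]})
        df = pd.concat([df, pd.DataFrame([{"label": "b", "T": 50.0,
                                           "gibbs": 0.0, "enthalpy": 0.0}])])
        with pytest.raises(ValidationError, match="grid"):
            population_curves(df)


class TestFilters:
    def test_single_conformer_always_retained(self):
        curves = _curves({"only": [1.0, 1.0, 1.0]})
        assert filter_significant(curves) == ["only"]

    def test_exactly_at_threshold_is_dropped(self):
        curves = _curves({"big": [0.9, 0.9, 0.9], "edge": [0.10, 0.10, 0.10]})
        assert filter_significant(curves, 0.10) == ["big"]

    def test_planted_count_above_threshold(self):
        curves = _curves({
            "a": [0.50, 0.40, 0.30], "b": [0.30, 0.35, 0.35],
            "c": [0.15, 0.20, 0.25], "d": [0.05, 0.05, 0.10],
        })
        assert filter_significant(curves, 0.10) == ["a", "b", "c"]

    def test_window_boundary_inclusive(self, water_record):
        from dataclasses import replace
        h2k = 627.509474
        recs = [replace(water_record, label=f"w{i}",
                        electronic_energy=water_record.electronic_energy
                        + e / h2k)
                for i, e in enumerate([0.0, 1.9, 2.0, 2.1])]
        kept = energy_window_filter(recs, window=2.0)
        assert [r.label for r in kept] == ["w0", "w1", "w2"]

    def test_window_matches_brute_force(self, rng, water_record):
        from dataclasses import replace
        h2k = 627.509474
        energies = rng.uniform(0, 5, size=100)
        recs = [replace(water_record, label=f"w{i}",
                        electronic_energy=water_record.electronic_energy
                        + e / h2k)
                for i, e in enumerate(energies)]
        kept = energy_window_filter(recs, window=2.0)
        assert len(kept) == int(np.sum(energies - energies.min() <= 2.0))


class TestEnsembleThermo:
    def test_bounded_by_conformer_extremes(self, default_scenario):
        sub = default_scenario.thermo.query(
            "species == 'WATER_CLUSTER' and n_waters == 3")
        ens = ensemble_thermo(sub)
        for t, row in ens.iterrows():
            g = sub[np.isclose(sub["T"], t)]["gibbs"]
            assert g.min() - 1e-9 <= row["gibbs"] <= g.max() + 1e-9

    def test_log_sum_exp_variant_lies_below_mean(self, default_scenario):
        sub = default_scenario.thermo.query(
            "species == 'WATER_CLUSTER' and n_waters == 2")
        mean = ensemble_thermo(sub, method="weighted_mean")
        lse = ensemble_thermo(sub, method="log_sum_exp")
        assert (lse["gibbs"] <= mean["gibbs"] + 1e-9).all()
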