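import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deha_pbk.gsa import (MEASURE_NAMES, elementary_effects, lhs_design,
                          morris_design, morris_screen, pbk_measures,
                          run_ensemble, screen_filter)
from deha_pbk.priors import (PriorSpec, morris_parameter_names, prior_table,
                             screening_table)


def unit_priors(k):
    return [PriorSpec(f"x{i}", "uniform", {"lower": 0.0, "upper": 1.0})
            for i in range(k)]


class TestLHS:
    def test_one_point_per_quartile(self):
        d = lhs_design(unit_priors(1), 4, seed=0)
        strata = np.floor(d.frame["x0"].to_numpy() * 4).astype(int)
        assert sorted(strata) == [0, 1, 2, 3]

    def test_marginal_stratification_of_full_table(self):
        d = lhs_design(screening_table(), 200, seed=1)
        assert d.n_runs == 200
        for i in range(d.unit.shape[1]):
            strata = np.floor(d.unit[:, i] * 200).astype(int)
            assert sorted(strata) == list(range(200))

    def test_marginals_match_prior_cdf(self):
        spec = PriorSpec("u", "uniform", {"lower": 2.0, "upper": 5.0})
        d = lhs_design([spec], 200, seed=2)
        p = stats.kstest(d.frame["u"], stats.uniform(2.0, 3.0).cdf).pvalue
        assert p > 0.01

    def test_rejects_degenerate_design(self):
        with pytest.raises(ValueError):
            lhs_design(unit_priors(2), 1, seed=0)


class TestMorrisDesign:
    @pytest.mark.parametrize("k, r, expected", [(1, 1, 2), (3, 4, 16),
                                                (5, 7, 42)])
    def test_run_count_formula(self, k, r, expected):
        ranges = {f"x{i}": (0.0, 1.0) for i in range(k)}
        assert morris_design(ranges, r=r, seed=0).n_runs == expected

    def test_one_parameter_changes_per_step(self):
        ranges = {f"x{i}": (0.0, 1.0) for i in range(6)}
        d = morris_design(ranges, r=3, seed=1)
        for t in range(3):
            rows = d.unit[d.trajectories == t]
            changed = set()
            for a, b in zip(rows, rows[1:]):
                diff = np.flatnonzero(np.abs(b - a) > 1e-12)
                assert diff.size == 1
                assert abs(b[diff[0]] - a[diff[0]]) == pytest.approx(d.delta)
                changed.add(diff[0])
            assert changed == set(range(6))   # every parameter moved once

    def test_values_respect_ranges(self):
        ranges = {"a": (2.0, 4.0), "b": (-1.0, 1.0)}
        d = morris_design(ranges, r=5, seed=2)
        assert d.frame["a"].between(2.0, 4.0).all()
        assert d.frame["b"].between(-1.0, 1.0).all()

    def test_invalid_range_names_parameter(self):
        with pytest.raises(ValueError, match="bad"):
            morris_design({"bad": (1.0, 1.0)}, r=1)


class TestElementaryEffects:
    def toy(self, x):   # smooth nonlinear 3-parameter test function
        return 2.0 * x[0] + x[1] ** 2 + 0.5 * x[0] * x[2]

    def test_matches_finite_difference_oracle(self):
        ranges = {f"x{i}": (0.0, 1.0) for i in range(3)}
        d = morris_design(ranges, r=4, seed=3)
        y = np.array([self.toy(row) for row in d.frame.to_numpy()])
        eff = elementary_effects(d, y)
        # brute-force oracle: recompute each effect directly from the
        # consecutive design rows
        for t in range(4):
            sel = np.flatnonzero(d.trajectories == t)
            got = eff[eff["trajectory"] == t].reset_index(drop=True)
            for step, (a, b) in enumerate(zip(sel, sel[1:])):
                du = d.unit[b] - d.unit[a]
                i = int(np.argmax(np.abs(du)))
                expect = (self.toy(d.frame.to_numpy()[b])
                          - self.toy(d.frame.to_numpy()[a])) / du[i]
                assert got.loc[step, "effect"] == pytest.approx(
                    expect, abs=1e-10)
                assert got.loc[step, "parameter"] == f"x{i}"

    def test_linear_function_has_zero_sigma(self):
        a = np.array([3.0, -1.5, 0.5])
        ranges = {f"x{i}": (0.0, 1.0) for i in range(3)}
        d = morris_design(ranges, r=6, seed=4)
        y = d.frame.to_numpy() @ a
        res = morris_screen(d, y)
        tab = res.table.set_index("parameter")
        assert np.all(tab["sigma"].abs() < 1e-10)
        mu = tab["mu_star"]
        np.testing.assert_allclose(
            [mu[f"x{i}"] for i in range(3)], np.abs(a), rtol=1e-10)

    def test_inert_parameter_scores_zero(self):
        ranges = {"active": (0.0, 1.0), "inert": (0.0, 1.0)}
        d = morris_design(ranges, r=5, seed=5)
        y = d.frame["active"].to_numpy() ** 2
        res = morris_screen(d, y)
        mx = res.max_norm_distance()
        assert mx["inert"] == 0.0
        assert mx["active"] == 1.0

    def test_normalisation_attains_one_per_measure(self):
        ranges = {f"x{i}": (0.0, 1.0) for i in range(3)}
        d = morris_design(ranges, r=4, seed=6)
        y = np.column_stack([d.frame["x0"], 2 * d.frame["x1"]])
        res = morris_screen(d, y)
        for m, grp in res.table.groupby("measure"):
            assert grp["norm_distance"].max() == pytest.approx(1.0)


class TestScreenFilter:
    def test_threshold_filtering(self):
        table = pd.DataFrame({
            "parameter": ["a", "a", "b", "b"], "measure": [0, 1, 0, 1],
            "mu_star": 0.0, "sigma": 0.0, "distance": 0.0,
            "norm_distance": [0.05, 0.4, 0.02, 0.01]})
        from deha_pbk.gsa import MorrisResult
        res = MorrisResult(table=table, measure_names=[0, 1])
        assert screen_filter(res, 0.1) == ["a"]
        assert screen_filter(res, 0.5) == []


class TestEnsemble:
    def small_design(self, rows):
        frame = pd.DataFrame(rows)
        from deha_pbk.gsa import Design
        return Design(frame=frame, provenance="lhs", seed=0)

    def test_single_row_envelope_is_the_curve(self):
        d = self.small_design([{"FracAbsorbed": 0.6}])
        ens = run_ensemble(d, grid_step=1.0, duration=12.0)
        np.testing.assert_array_equal(ens["RUrine_cx"]["lo"],
                                      ens["RUrine_cx"]["hi"])

    def test_identical_rows_zero_width_envelope(self):
        d = self.small_design([{"FracAbsorbed": 0.6}] * 3)
        ens = run_ensemble(d, grid_step=1.0, duration=12.0)
        assert np.all(ens["CV_DEHA"]["hi"] - ens["CV_DEHA"]["lo"] == 0.0)


class TestPBKScreening:
    """Screening behaviour on the actual PBK model."""

    def test_urinary_curves_rise_and_decay_over_lhs_ensemble(self):
        """Over a 200-point Latin hypercube of the parameter
        distributions, the urinary deposition rate starts at zero, shows
        a rapid peak, and decays toward zero by 48 h: at least 90% of
        draws peak within 12 h and end below half their peak, and the
        median terminal-to-peak ratio is below 10%."""
        d = lhs_design(screening_table(), 200, seed=7)
        ens = run_ensemble(d, grid_step=0.25)
        curves = ens["RUrine_cx"]["curves"]
        t = ens["time"]
        assert curves.shape[0] >= 0.95 * 200
        assert np.all(curves[:, 0] == 0.0)
        peak = curves.max(axis=1)
        peak_time = t[curves.argmax(axis=1)]
        ratio = curves[:, -1] / peak
        assert np.mean(peak_time < 12.0) >= 0.90
        assert np.mean(ratio < 0.5) >= 0.90
        assert np.median(ratio) < 0.10

    def test_screen_recovers_calibrated_parameter_set(self):
        """A high-precision elementary-effects screen flags most of the
        parameters that the calibration stage treats as uncertain."""
        ranges = {s.name: s.range_95() for s in screening_table()}
        d = morris_design(ranges, r=20, levels=4, seed=3)
        y = np.vstack([pbk_measures(row.to_dict())
                       for _, row in d.frame.iterrows()])
        res = morris_screen(d, y, MEASURE_NAMES)
        sens = set(screen_filter(res, threshold=0.1))
        calibrated = {s.name for s in prior_table()
                      if s.calibrated and not s.name.startswith("sigma")}
        overlap = len(sens & calibrated) / len(calibrated)
        assert overlap >= 0.7
        # reference predictions that do not enter the operative model
        # must screen inert
        mx = res.max_norm_distance()
        assert mx["fu_DEHA"] == 0.0
        assert mx["fu_MEHA"] == 0.0
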