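"""Trend fitting, model selection, parallelism and residual comparisons."""

import numpy as np
import pytest
from scipy import stats

import dendrotramp as dt
from dendrotramp.trend_models import FitError, N_PARAMS, fit_all


def _years(n, start=1900):
    return np.arange(start, start + n, dtype=float)


class TestFitTrend:
    def test_exact_line_recovered(self):
        x = _years(30)
        y = 2.0 * x + 1.0
        fit = dt.fit_trend(x, y, "linear")
        assert fit.r_squared == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-8)
        np.testing.assert_allclose(fit.params, [1.0, 2.0], rtol=1e-8)

    def test_negexp_parameter_recovery(self):
        # truth: a=3, b=0.02, k=0.5 plus sigma=0.05 noise at n=150
        rng = np.random.default_rng(101)
        x = _years(150)
        truth = 3.0 * np.exp(-0.02 * (x - x[0])) + 0.5
        y = truth + rng.normal(0, 0.05, x.size)
        fit = dt.fit_trend(x, y, "negexp", seed=1)
        a, b, k = fit.params
        assert a == pytest.approx(3.0, rel=0.10)
        assert b == pytest.approx(0.02, rel=0.10)
        assert k == pytest.approx(0.5, rel=0.10)

    def test_weibull_recovers_hump_shape(self):
        rng = np.random.default_rng(7)
        x = _years(120)
        u = x - x[0] + 1.0
        truth = 2.5 * (u / 40.0) ** 1.8 * np.exp(-((u / 40.0) ** 2.8))
        y = truth + rng.normal(0, 0.02, x.size)
        fit = dt.fit_trend(x, y, "weibull", seed=3)
        assert fit.r_squared > 0.95

    def test_residuals_sum_zero_for_intercept_families(self):
        rng = np.random.default_rng(2)
        x = _years(60)
        y = 0.5 - 0.01 * x + rng.normal(0, 0.2, x.size)
        for fam in ("linear", "log", "poly3"):
            fit = dt.fit_trend(x, y, fam)
            assert abs(fit.residuals.sum()) < 1e-6

    def test_f_and_p_match_r2_formula(self):
        rng = np.random.default_rng(4)
        x = _years(80)
        y = -0.01 * x + rng.normal(0, 0.3, x.size)
        fit = dt.fit_trend(x, y, "linear")
        df1, df2 = fit.n_params - 1, fit.n_points - fit.n_params
        f = (fit.r_squared / df1) / ((1 - fit.r_squared) / df2)
        assert fit.f_stat == pytest.approx(f)
        assert fit.p_value == pytest.approx(float(stats.f.sf(f, df1, df2)))

    def test_constant_data_negexp_level_at_mean(self):
        x = _years(40)
        y = np.full(x.size, 1.3) + np.random.default_rng(0).normal(0, 1e-6, x.size)
        fit = dt.fit_trend(x, y, "negexp", seed=0)
        assert fit.predict(x).mean() == pytest.approx(1.3, abs=1e-3)
        assert abs(fit.r_squared) < 0.5

    def test_unsorted_x_rejected(self):
        with pytest.raises(FitError, match="sorted"):
            dt.fit_trend(np.array([1.0, 3.0, 2.0, 4.0, 5.0, 6.0]), np.zeros(6), "linear")

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            dt.fit_trend(_years(4), np.ones(4), "poly3")


class TestBestFit:
    def test_noiseless_cubic_selects_poly3(self):
        x = _years(50)
        xc = x - x.mean()
        y = 0.2 + 0.01 * xc - 2e-4 * xc**2 + 1e-5 * xc**3
        fit = dt.best_fit(x, y)
        assert fit.family == "poly3"
        assert fit.r_squared == pytest.approx(1.0)

    def test_noiseless_line_tie_breaks_to_linear(self):
        x = _years(50)
        y = 1.0 - 0.02 * x
        fit = dt.best_fit(x, y)
        assert fit.family == "linear"

    def test_hump_shape_beats_monotone_families(self):
        rng = np.random.default_rng(21)
        x = _years(100)
        u = x - x[0] + 1.0
        y = 2.0 * (u / 30.0) ** 2 * np.exp(-((u / 30.0) ** 2.5)) + rng.normal(0, 0.03, x.size)
        fit = dt.best_fit(x, y, seed=5)
        fits = fit_all(x, y, seed=5)
        assert fit.family in ("weibull", "poly3")
        assert fit.r_squared > fits["linear"].r_squared
        assert fit.r_squared > fits["negexp"].r_squared

    def test_poly3_nests_linear(self):
        rng = np.random.default_rng(33)
        for trial in range(5):
            x = _years(60)
            y = rng.normal(0, 1, x.size)
            f1 = dt.fit_trend(x, y, "linear")
            f3 = dt.fit_trend(x, y, "poly3")
            assert f3.r_squared >= f1.r_squared - 1e-12


class TestCompareFits:
    def test_self_comparison_p_one(self):
        x = _years(40)
        y = 1.0 - 0.01 * x + np.random.default_rng(1).normal(0, 0.1, 40)
        fit = dt.fit_trend(x, y, "linear")
        cmp = dt.compare_fits(fit, fit)
        assert cmp.p_value == 1.0
        assert cmp.t_stat == 0.0

    def test_strongly_cubic_data_linear_loses(self):
        rng = np.random.default_rng(8)
        x = _years(100)
        xc = x - x.mean()
        y = 1e-5 * xc**3 - 3e-4 * xc**2 + rng.normal(0, 0.05, x.size)
        f1 = dt.fit_trend(x, y, "linear")
        f3 = dt.fit_trend(x, y, "poly3")
        cmp = dt.compare_fits(f1, f3)
        assert cmp.p_value < 0.01
        assert cmp.mean_abs_resid_b < cmp.mean_abs_resid_a

    def test_symmetry_of_p(self):
        rng = np.random.default_rng(9)
        x = _years(50)
        y = -0.01 * x + rng.normal(0, 0.2, x.size)
        fa = dt.fit_trend(x, y, "linear")
        fb = dt.fit_trend(x, y, "poly3")
        assert dt.compare_fits(fa, fb).p_value == pytest.approx(
            dt.compare_fits(fb, fa).p_value
        )

    def test_different_data_rejected(self):
        x = _years(30)
        fa = dt.fit_trend(x, np.sin(x / 10), "linear")
        fb = dt.fit_trend(x, np.cos(x / 10), "linear")
        with pytest.raises(FitError, match="identical"):
            dt.compare_fits(fa, fb)


class TestConservativeSelect:
    def test_linear_data_keeps_line(self):
        rng = np.random.default_rng(12)
        x = _years(80)
        y = 0.5 - 0.01 * x + rng.normal(0, 0.1, x.size)
        fit = dt.conservative_select(x, y, seed=2)
        assert fit.family == "linear"

    def test_cubic_data_switches_with_justification(self):
        rng = np.random.default_rng(13)
        x = _years(100)
        xc = x - x.mean()
        y = 2e-5 * xc**3 + rng.normal(0, 0.05, x.size)
        fit = dt.conservative_select(x, y, seed=2)
        assert fit.family == "poly3"
        assert fit.selection["p_vs_linear"]["poly3"] < 0.05

    def test_alpha_zero_always_linear(self):
        rng = np.random.default_rng(14)
        x = _years(100)
        y = 2e-5 * (x - x.mean()) ** 3 + rng.normal(0, 0.05, x.size)
        fit = dt.conservative_select(x, y, alpha=0.0, seed=2)
        assert fit.family == "linear"


class TestParallelism:
    def test_offset_copies_are_parallel(self):
        rng = np.random.default_rng(15)
        x = _years(80)
        y_a = 1.0 - 0.01 * x + rng.normal(0, 0.2, x.size)
        y_b = y_a + 0.7
        res = dt.parallelism_test(x, y_a, y_b, "linear")
        assert res.f_stat == pytest.approx(0.0, abs=1e-8)
        assert res.p_value > 0.99

    def test_identical_groups_f_zero(self):
        rng = np.random.default_rng(16)
        x = _years(60)
        y = -0.02 * x + rng.normal(0, 0.1, x.size)
        res = dt.parallelism_test(x, y, y.copy(), "linear")
        assert res.f_stat == pytest.approx(0.0, abs=1e-10)

    def test_different_curvature_detected(self):
        rng = np.random.default_rng(17)
        x = _years(100)
        xc = x - x.mean()
        y_a = 1e-5 * xc**3 + rng.normal(0, 0.05, x.size)
        y_b = 3e-5 * xc**3 + rng.normal(0, 0.05, x.size)
        res = dt.parallelism_test(x, y_a, y_b, "poly3")
        assert res.p_value < 0.05

    def test_negexp_parallel_shift(self):
        rng = np.random.default_rng(18)
        x = _years(120)
        curve = 2.0 * np.exp(-0.03 * (x - x[0])) + 0.4
        y_a = curve + rng.normal(0, 0.05, x.size)
        y_b = curve + 0.5 + rng.normal(0, 0.05, x.size)
        res = dt.parallelism_test(x, y_a, y_b, "negexp")
        assert res.p_value > 0.05

    def test_type_one_error_near_alpha(self):
        # same true curve in both groups: rejections should track alpha
        rng = np.random.default_rng(19)
        x = _years(60)
        rejections = 0
        reps = 500
        for _ in range(reps):
            base = 0.5 - 0.01 * (x - x.mean())
            y_a = base + rng.normal(0, 0.2, x.size)
            y_b = base + rng.normal(0, 0.2, x.size)
            res = dt.parallelism_test(x, y_a, y_b, "linear")
            rejections += res.p_value < 0.05
        rate = rejections / reps
        # binomial 99.9% band around 0.05 at 500 reps
        assert 0.02 <= rate <= 0.09


class TestBetweenGroupResiduals:
    def _pooled_fit(self, y_a, y_b, x):
        # both groups observed in the same years (tied x in the pooled fit)
        order = np.argsort(np.concatenate([x, x]), kind="stable")
        xs = np.concatenate([x, x])[order]
        ys = np.concatenate([y_a, y_b])[order]
        labels = np.concatenate([np.zeros_like(x), np.ones_like(x)])[order]
        return dt.fit_trend(xs, ys, "linear"), labels

    def test_identical_groups_t_zero(self):
        rng = np.random.default_rng(20)
        x = _years(50)
        y = -0.01 * x + rng.normal(0, 0.1, x.size)
        fit, labels = self._pooled_fit(y, y.copy(), x)
        t, p = dt.between_group_residuals(fit, labels)
        assert t == pytest.approx(0.0, abs=1e-8)

    def test_offset_groups_detected(self):
        rng = np.random.default_rng(22)
        x = _years(100)
        y_a = -0.01 * x + rng.normal(0, 0.2, x.size)
        y_b = y_a + 1.0 + rng.normal(0, 0.001, x.size)
        fit, labels = self._pooled_fit(y_a, y_b, x)
        t, p = dt.between_group_residuals(fit, labels)
        assert abs(t) > 10
        assert p < 1e-6

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(23)
        x = _years(40)
        rejections = 0
        reps = 200
        for _ in range(reps):
            y_a = -0.01 * x + rng.normal(0, 0.2, x.size)
            y_b = -0.01 * x + rng.normal(0, 0.2, x.size)
            fit, labels = self._pooled_fit(y_a, y_b, x)
            _, p = dt.between_group_residuals(fit, labels)
            rejections += p < 0.05
        assert 0.01 <= rejections / reps <= 0.11

    def test_small_group_rejected(self):
        x = _years(6)
        fit = dt.fit_trend(x, np.sin(x), "linear")
        with pytest.raises(FitError):
            dt.between_group_residuals(fit, [0, 0, 0, 0, 0, 1])
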