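"""Population-inference tests: mixed models (cross-checked against lme4),
Tukey contrasts, logistic threshold curves with inverse prediction, KDE
overlays, the dN statistic, and the penalized-spline decline breakpoint."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cardiothermal import (
    PopulationConfig,
    ReachedCurve,
    delta_n_curve,
    fit_random_intercept_lmm,
    fit_reached_curve,
    generate_dataset,
    inverse_predict,
    kde_tab,
    pairwise_contrasts,
    reached_indicators,
    smooth_decline_breakpoint,
)
from cardiothermal.population import DensityCurve


def _simulated_metric(rng, n=300, n_clutches=5, beta=(10.0, 0.6), clutch_sd=1.0, resid_sd=2.0):
    inc = rng.choice([9.0, 12.0, 15.0], n)
    clutch = rng.integers(0, n_clutches, n)
    effects = rng.normal(0, clutch_sd, n_clutches)
    y = beta[0] + beta[1] * inc + effects[clutch] + rng.normal(0, resid_sd, n)
    return pd.DataFrame({"y": y, "inc": inc, "clutch": clutch.astype(str)})


class TestMixedModel:
    def test_zero_clutch_variance_matches_pooled_ols(self, rng):
        df = _simulated_metric(rng, clutch_sd=0.0)
        fit = fit_random_intercept_lmm(df["y"], df["inc"], df["clutch"])
        ols = sm.OLS(df["y"], sm.add_constant(df["inc"])).fit()
        assert fit.sigma2_clutch == pytest.approx(0.0, abs=0.05)
        assert fit.beta == pytest.approx(np.asarray(ols.params), abs=0.02)

    def test_r2_conditional_at_least_marginal(self, rng):
        for seed in range(5):
            df = _simulated_metric(np.random.default_rng(seed))
            fit = fit_random_intercept_lmm(df["y"], df["inc"], df["clutch"])
            assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0

    def test_single_clutch_falls_back_to_ols(self, rng):
        df = _simulated_metric(rng, n_clutches=1)
        fit = fit_random_intercept_lmm(df["y"], df["inc"], df["clutch"])
        assert fit.fallback_ols

    def test_random_effect_lrt_detects_clutch_variance(self, rng):
        strong = _simulated_metric(rng, clutch_sd=3.0)
        fit = fit_random_intercept_lmm(strong["y"], strong["inc"], strong["clutch"])
        assert fit.lrt_p_random < 0.001
        assert fit.sigma2_clutch > 1.0

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_agrees_with_lme4_reference(self, rng, tmp_path):
        df = _simulated_metric(rng, n=200)
        csv = tmp_path / "metric.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(y ~ inc + (1 | clutch), data = d, REML = TRUE)
            vc <- as.data.frame(VarCorr(m))
            cat(fixef(m), vc$vcov, sep = "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = [float(v) for v in out.stdout.split()]
        fit = fit_random_intercept_lmm(df["y"], df["inc"], df["clutch"])
        assert fit.beta[0] == pytest.approx(ref[0], abs=1e-3)
        assert fit.beta[1] == pytest.approx(ref[1], abs=1e-4)
        assert fit.sigma2_clutch == pytest.approx(ref[2], rel=1e-2, abs=1e-3)
        assert fit.sigma2_resid == pytest.approx(ref[3], rel=1e-3)


class TestPairwiseContrasts:
    def test_identical_groups_not_significant(self, rng):
        y = np.tile(rng.normal(0, 1, 40), 3)
        g = np.repeat(["a", "b", "c"], 40)
        tab = pairwise_contrasts(y, g)
        assert (tab["p_tukey"] > 0.99).all()

    def test_shifted_group_detected(self, rng):
        y = np.concatenate([rng.normal(0, 1, 40), rng.normal(0, 1, 40), rng.normal(10, 1, 40)])
        g = np.repeat(["a", "b", "c"], 40)
        tab = pairwise_contrasts(y, g).set_index(["group_a", "group_b"])
        assert tab.loc[("a", "c"), "p_tukey"] < 1e-6
        assert tab.loc[("b", "c"), "p_tukey"] < 1e-6
        assert tab.loc[("a", "b"), "p_tukey"] > 0.05

    def test_adjustment_never_decreases_p(self, rng):
        y = rng.normal(0, 1, 90) + np.repeat([0.0, 0.3, 0.6], 30)
        tab = pairwise_contrasts(y, np.repeat(["a", "b", "c"], 30))
        assert (tab["p_tukey"] >= tab["p_unadjusted"] - 1e-12).all()

    def test_single_group_raises(self, rng):
        with pytest.raises(ValueError):
            pairwise_contrasts(rng.normal(0, 1, 10), ["a"] * 10)


@pytest.fixture(scope="module")
def small_metrics_and_data():
    cfg = PopulationConfig(
        n_per_group={9.0: 40, 12.0: 40, 15.0: 40}, n_clutches=4, seed=21
    )
    dataset, _ = generate_dataset(cfg)
    from cardiothermal.pipeline import extract_metrics

    return dataset, extract_metrics(dataset)


class TestReachedIndicators:
    def test_indicator_flips_at_endpoint(self, small_metrics_and_data):
        dataset, metrics = small_metrics_and_data
        ind = reached_indicators(dataset, metrics, "t_peak")
        one = metrics.iloc[0]
        rows = ind[ind["individual_id"] == one["individual_id"]].sort_values("step_temp_C")
        expect = (rows["step_temp_C"] >= one["t_peak_C"]).astype(int)
        assert (rows["reached"].to_numpy() == expect.to_numpy()).all()

    def test_censored_individuals_contribute_zeros(self, small_metrics_and_data):
        dataset, metrics = small_metrics_and_data
        censored = metrics[metrics["t_arr_censored"]]
        if len(censored) == 0:
            pytest.skip("no censored individuals in this cohort")
        ind = reached_indicators(dataset, metrics, "t_arr")
        sub = ind[ind["individual_id"].isin(censored["individual_id"])]
        assert (sub["reached"] == 0).all()

    def test_empirical_proportions_equal_hand_cdf(self, small_metrics_and_data):
        dataset, metrics = small_metrics_and_data
        ind = reached_indicators(dataset, metrics, "t_peak")
        props = ind.groupby("step_temp_C")["reached"].mean()
        for temp, p in props.items():
            assert p == pytest.approx((metrics["t_peak_C"] <= temp).mean())


class TestReachedCurve:
    def _logistic_indicators(self, rng, n=400, loc=19.0, scale=1.1):
        steps = np.array([9, 11, 13, 15, 17, 19, 20, 21, 22, 23, 24, 25], float)
        endpoint = rng.logistic(loc, scale, n)
        rows = {
            "individual_id": np.repeat(np.arange(n), len(steps)),
            "clutch_id": np.repeat(rng.integers(0, 5, n).astype(str), len(steps)),
            "incubation_C": 12.0,
            "step_temp_C": np.tile(steps, n),
        }
        df = pd.DataFrame(rows)
        df["reached"] = (df["step_temp_C"] >= np.repeat(endpoint, len(steps))).astype(int)
        return df, endpoint

    def test_recovers_logistic_temperature_coefficient(self, rng):
        # true slope 1/scale ~ 0.91, the realistic scale for this assay
        df, _ = self._logistic_indicators(rng, scale=1.0 / 0.92)
        curve = fit_reached_curve(df, "t_peak", include_incubation=False)
        b = curve.params[1]
        se = np.sqrt(curve.cov[1, 1])
        assert abs(b - 0.92) < 2 * se

    def test_interaction_free_generator_gives_null_interaction(self, rng):
        frames = []
        for inc in (9.0, 12.0, 15.0):
            df, _ = self._logistic_indicators(rng, n=300, loc=19.0)
            df["incubation_C"] = inc
            frames.append(df)
        curve = fit_reached_curve(pd.concat(frames, ignore_index=True), "t_peak")
        i = curve.param_names.index("temp_x_incubation")
        assert abs(curve.params[i]) < 2 * np.sqrt(curve.cov[i, i])

    def test_fitted_curve_monotone_for_positive_slope(self, rng):
        df, _ = self._logistic_indicators(rng)
        curve = fit_reached_curve(df, "t_peak", include_incubation=False)
        grid = np.linspace(5, 30, 200)
        assert np.all(np.diff(curve.predict(grid)) >= 0)

    def test_constant_outcomes_raise(self):
        df = pd.DataFrame(
            {"reached": [1, 1], "step_temp_C": [9.0, 11.0], "incubation_C": 9.0}
        )
        with pytest.raises(ValueError):
            fit_reached_curve(df, "t_peak")

    def test_separated_data_flagged_and_finite(self):
        # perfectly separated at 17 degC
        temps = np.tile(np.array([9.0, 11, 13, 15, 17, 19, 21, 23]), 20)
        df = pd.DataFrame(
            {"step_temp_C": temps, "reached": (temps >= 17).astype(int), "incubation_C": 9.0}
        )
        curve = fit_reached_curve(df, "t_peak", include_incubation=False)
        assert curve.separation
        assert np.all(np.isfinite(curve.params))


class TestInversePredict:
    def _curve(self, b0=-18.0, bt=1.0):
        return ReachedCurve(
            endpoint="t_peak",
            params=np.array([b0, bt]),
            cov=np.diag([0.5, 0.01]),
            param_names=("intercept", "temp"),
            has_incubation=False,
        )

    def test_median_threshold_closed_form(self):
        curve = self._curve()
        est = inverse_predict(curve, 0.5)
        assert est.temperature_c == pytest.approx(18.0)

    def test_round_trip_through_curve(self):
        curve = self._curve(b0=-15.0, bt=0.8)
        for p in (0.10, 0.50, 0.95):
            est = inverse_predict(curve, p)
            assert curve.predict(est.temperature_c) == pytest.approx(p, abs=1e-9)

    def test_thresholds_increase_with_p(self):
        curve = self._curve()
        temps = [inverse_predict(curve, p).temperature_c for p in (0.1, 0.5, 0.95)]
        assert temps[0] < temps[1] < temps[2]

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            inverse_predict(self._curve(bt=-0.5), 0.5)

    def test_quantile_recovery_from_simulated_cohort(self, rng):
        n = 500
        endpoint = rng.logistic(18.5, 1.2, n)
        steps = np.array([9, 11, 13, 15, 17, 19, 20, 21, 22, 23, 24, 25], float)
        df = pd.DataFrame(
            {
                "step_temp_C": np.tile(steps, n),
                "reached": (np.tile(steps, n) >= np.repeat(endpoint, len(steps))).astype(int),
                "incubation_C": 12.0,
            }
        )
        curve = fit_reached_curve(df, "t_peak", include_incubation=False)
        est = inverse_predict(curve, 0.10)
        assert abs(est.temperature_c - np.quantile(endpoint, 0.10)) < 0.5


class TestKde:
    def test_integral_close_to_one(self, rng):
        d = kde_tab(rng.normal(15, 2, 100))
        assert d.integral == pytest.approx(1.0, abs=0.01)

    def test_tight_cluster_unimodal_mode_at_mean(self, rng):
        v = rng.normal(14.0, 0.2, 50)
        d = kde_tab(v)
        maxima = (np.diff(np.sign(np.diff(d.density))) < 0).sum()
        assert maxima == 1
        assert d.mode_c == pytest.approx(v.mean(), abs=0.1)

    def test_separated_mixture_is_bimodal(self, rng):
        v = np.concatenate([rng.normal(12.0, 0.5, 60), rng.normal(18.0, 0.5, 60)])
        d = kde_tab(v)
        interior = d.density[1:-1]
        maxima = np.sum(
            (interior > d.density[:-2]) & (interior >= d.density[2:])
        )
        assert maxima == 2

    def test_identical_values_raise(self):
        with pytest.raises(ValueError):
            kde_tab([15.0] * 10)

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            kde_tab([15.0, 16.0])


class TestDeltaN:
    def _flat_curve(self, level=-50.0):
        # effectively zero reached proportion over the assay range
        return ReachedCurve(
            endpoint="t_peak",
            params=np.array([level, 0.1]),
            cov=np.eye(2) * 1e-4,
            param_names=("intercept", "temp"),
            has_incubation=False,
        )

    def test_zero_reached_curve_leaves_density(self, rng):
        d = kde_tab(rng.normal(14, 1.5, 120))
        dn = delta_n_curve(d, self._flat_curve())
        assert np.allclose(dn.delta_n, d.density, atol=1e-8)
        assert dn.argmax_c == pytest.approx(d.mode_c)

    def test_density_equal_to_curve_gives_zero(self):
        curve = ReachedCurve(
            endpoint="t_peak",
            params=np.array([-18.0, 1.0]),
            cov=np.eye(2) * 1e-4,
            param_names=("intercept", "temp"),
            has_incubation=False,
        )
        grid = np.arange(9.0, 25.0, 0.05)
        density = DensityCurve(
            grid=grid, density=np.asarray(curve.predict(grid)), bandwidth=1.0, n=100
        )
        dn = delta_n_curve(density, curve)
        assert np.allclose(dn.delta_n, 0.0, atol=1e-12)

    def test_max_against_dense_grid_oracle(self, rng):
        # cohort built so the density peaks near 14 degC where the logistic
        # curve is still low; independent dense evaluation must agree
        v = rng.normal(14.0, 1.0, 200)
        d = kde_tab(v, grid_spacing=0.05)
        curve = ReachedCurve(
            endpoint="t_peak",
            params=np.array([-20.0, 1.0]),
            cov=np.eye(2) * 1e-4,
            param_names=("intercept", "temp"),
            has_incubation=False,
        )
        dn = delta_n_curve(d, curve)
        oracle = d.density - 1.0 / (1.0 + np.exp(-(-20.0 + 1.0 * d.grid)))
        i = int(np.argmax(oracle))
        assert dn.max_value == pytest.approx(float(oracle[i]), abs=1e-12)
        assert dn.argmax_c == pytest.approx(float(d.grid[i]))
        assert float(curve.predict(dn.argmax_c)) < 0.05

    def test_max_range_contains_argmax(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            d = kde_tab(r.normal(15, 2, 80))
            dn = delta_n_curve(d, self._flat_curve(level=-20.0 + 5 * seed))
            assert dn.max_range[0] <= dn.argmax_c <= dn.max_range[1]
            assert any(lo <= dn.argmax_c <= hi for lo, hi in dn.max_intervals)


class TestSmoothDeclineBreakpoint:
    def test_parabola_vertex_recovered(self):
        t = np.linspace(9, 25, 12)
        for k in (4, 9):
            _, bp = smooth_decline_breakpoint(t, -((t - 16.0) ** 2), k=k)
            assert bp == pytest.approx(16.0, abs=0.5)

    def test_monotone_increasing_has_no_breakpoint(self):
        t = np.linspace(9, 25, 12)
        _, bp = smooth_decline_breakpoint(t, 2.0 * t, k=4)
        assert bp is None

    def test_constant_data_has_no_breakpoint(self):
        t = np.linspace(9, 25, 12)
        smooth, bp = smooth_decline_breakpoint(t, np.ones_like(t), k=4)
        assert bp is None
        assert np.allclose(smooth.fitted, 1.0, atol=1e-6)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            smooth_decline_breakpoint([1, 2, 3], [1, 2, 3], k=4)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_breakpoint_compatible_with_mgcv_smooth(self, tmp_path):
        # mgcv's GCV thin-plate smooth of the same samples must place the
        # start of its decline near ours
        t = np.linspace(9, 25, 12)
        y = np.array([0.0, 0.01, 0.03, 0.08, 0.05, -0.3, -0.6, -0.8, -0.9, -0.95, -0.98, -1.0])
        pd.DataFrame({"t": t, "y": y}).to_csv(tmp_path / "dn.csv", index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(mgcv))
            d <- read.csv("{tmp_path / 'dn.csv'}")
            m <- gam(y ~ s(t, k = 4), data = d, method = "GCV.Cp")
            grid <- seq(min(d$t), max(d$t), by = 0.05)
            f <- predict(m, newdata = data.frame(t = grid))
            i <- which.max(f)
            dneg <- which(diff(f) < 0 & seq_along(diff(f)) >= i)
            cat(grid[dneg[1]])
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = float(out.stdout.strip())
        _, bp = smooth_decline_breakpoint(t, y, k=4)
        assert bp == pytest.approx(ref, abs=1.0)
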