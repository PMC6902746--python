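"""Rate-curve model, group tests, and trajectory integration."""

import numpy as np
import pandas as pd
import pytest

from amytraj import (
    accumulation_rate,
    RateCurveModel,
    RateCurveResults,
    annualize,
    integrate_rate,
    linearity_test,
    logistic_level,
    shape_difference_test,
    vertical_shift_test,
)


def rate_frame(x, y, group=None):
    df = pd.DataFrame({"baseline_suvr": x, "dsuvr_per_year": y})
    if group is not None:
        df["group"] = group
    return df


class TestAnnualize:
    def test_zero_and_simple_changes(self):
        visits = pd.DataFrame(
            {
                "participant_id": ["a", "a", "b", "b"],
                "group": "case",
                "time_years": [0.0, 1.2, 0.0, 0.5],
                "suvr": [1.20, 1.20, 1.20, 1.30],
                **{m: 1.0 for m in
                   ("cdr_sob", "mmse", "drs", "updrs3", "avlt", "bnt",
                    "tmt_a", "rcf")},
            }
        )
        out = annualize(visits).set_index("participant_id")
        assert out.loc["a", "dsuvr_per_year"] == pytest.approx(0.0)
        assert out.loc["b", "dsuvr_per_year"] == pytest.approx(0.20 / 1.0, abs=1e-12)
        assert out.loc["b", "dsuvr_per_year"] == pytest.approx(0.2)

    def test_batch_equals_per_participant_loop(self, two_group_annualized):
        from amytraj import GeneratorConfig, generate_cohort

        _, visits = generate_cohort(GeneratorConfig(seed=7, n_cases=30,
                                                    control_pool_size=30))
        out = annualize(visits).set_index("participant_id")
        for pid, sub in visits.groupby("participant_id"):
            b = sub[sub.time_years == 0].iloc[0]
            f = sub[sub.time_years > 0].iloc[0]
            expected = (f["suvr"] - b["suvr"]) / f["time_years"]
            assert out.loc[pid, "dsuvr_per_year"] == pytest.approx(expected)
            assert out.loc[pid, "dsuvr_per_year"] * out.loc[
                pid, "interval_years"
            ] == pytest.approx(f["suvr"] - b["suvr"], abs=1e-12)

    def test_missing_measure_yields_missing_change(self):
        visits = pd.DataFrame(
            {
                "participant_id": ["a", "a"],
                "group": "case",
                "time_years": [0.0, 1.0],
                "suvr": [1.2, 1.3],
                "cdr_sob": [np.nan, 2.0],
                **{m: 1.0 for m in
                   ("mmse", "drs", "updrs3", "avlt", "bnt", "tmt_a", "rcf")},
            }
        )
        out = annualize(visits)
        assert np.isnan(out.loc[0, "dcdr_sob_per_year"])
        assert out.loc[0, "dmmse_per_year"] == pytest.approx(0.0)

    def test_short_interval_rejected_and_missing_visit_skipped(self, caplog):
        visits = pd.DataFrame(
            {
                "participant_id": ["a", "a", "b"],
                "group": "case",
                "time_years": [0.0, 0.1, 0.0],
                "suvr": [1.2, 1.25, 1.3],
                **{m: 1.0 for m in
                   ("cdr_sob", "mmse", "drs", "updrs3", "avlt", "bnt",
                    "tmt_a", "rcf")},
            }
        )
        with pytest.raises(ValueError, match="interval"):
            annualize(visits)
        import logging

        with caplog.at_level(logging.WARNING):
            out = annualize(visits[visits.participant_id == "b"])
        assert out.empty and "skipped" in caplog.text


class TestRateCurveFit:
    def test_effective_df_hits_target(self, pooled_annualized):
        fit = RateCurveModel(pooled_annualized).fit(target_edf=4.0)
        assert fit.edf == pytest.approx(4.0, abs=0.01)

    def test_peak_location_recovered(self, pooled_annualized):
        fit = RateCurveModel(pooled_annualized).fit(target_edf=4.0)
        assert 1.7 <= fit.argmax() <= 1.9

    def test_ci_halfwidth_positive_over_data_range(self, pooled_annualized):
        fit = RateCurveModel(pooled_annualized).fit(target_edf=4.0)
        grid = np.linspace(*fit.x_range, 50)
        lo, hi = fit.conf_int(grid)
        assert np.all(hi - lo > 0)

    def test_prediction_refuses_extrapolation(self, pooled_annualized):
        fit = RateCurveModel(pooled_annualized).fit(target_edf=4.0)
        with pytest.raises(ValueError, match="extrapolation"):
            fit.predict(fit.x_range[1] + 0.05)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="10 observations"):
            RateCurveModel(rate_frame(np.arange(5.0), np.arange(5.0)))

    def test_json_round_trip(self, pooled_annualized, tmp_path):
        fit = RateCurveModel(pooled_annualized).fit(target_edf=4.0)
        p = tmp_path / "fit.json"
        fit.to_json(p)
        back = RateCurveResults.from_json(p)
        grid = np.linspace(*fit.x_range, 20)
        np.testing.assert_allclose(back.predict(grid), fit.predict(grid))
        np.testing.assert_allclose(back.se(grid), fit.se(grid))

    def test_coverage_of_pointwise_bands(self, rng):
        # null-simulated data from a known smooth truth; average pointwise
        # coverage of the 95% band over interior grid points stays >= 0.90
        grid = np.linspace(1.25, 2.35, 41)
        truth = accumulation_rate(grid)
        cover = np.zeros(len(grid))
        reps = 200
        for _ in range(reps):
            x = rng.uniform(1.1, 2.5, 300)
            y = accumulation_rate(x) + rng.normal(0, 0.02, 300)
            fit = RateCurveModel(rate_frame(x, y)).fit(4.0)
            lo, hi = fit.conf_int(grid)
            cover += (lo <= truth) & (truth <= hi)
        assert (cover / reps).mean() >= 0.90


class TestGroupTests:
    def test_identical_groups_give_f_zero_p_one(self):
        x = np.linspace(1.2, 2.4, 50)
        y = accumulation_rate(x)
        df = rate_frame(np.r_[x, x], np.r_[y, y],
                        group=["case"] * 50 + ["control"] * 50)
        res = shape_difference_test(df)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.pvalue == pytest.approx(1.0, abs=1e-6)

    def test_shape_test_detects_vertical_offset(self, rng):
        hits = 0
        for _ in range(50):
            x = rng.uniform(1.1, 2.5, 400)
            g = np.r_[np.ones(200), np.zeros(200)]
            y = accumulation_rate(x) + 3 * 0.02 * g + rng.normal(0, 0.02, 400)
            df = rate_frame(x, y, group=np.where(g == 1, "case", "control"))
            hits += shape_difference_test(df).pvalue < 0.01
        assert hits >= 0.95 * 50

    def test_vertical_shift_sign_and_recovery(self, rng):
        hits = 0
        for _ in range(60):
            x = rng.uniform(1.1, 2.5, 1000)
            g = np.r_[np.ones(500), np.zeros(500)]
            y = accumulation_rate(x) + 0.01 * g + rng.normal(0, 0.02, 1000)
            df = rate_frame(x, y, group=np.where(g == 1, "case", "control"))
            res = vertical_shift_test(df)
            assert res.coefficient > 0  # cases accumulate faster
            hits += abs(res.coefficient - 0.01) <= 0.003
        assert hits >= 0.90 * 60

    def test_vertical_shift_null_t_statistics(self, rng):
        big_t = 0
        reps = 150
        for _ in range(reps):
            x = rng.uniform(1.1, 2.5, 400)
            y = accumulation_rate(x) + rng.normal(0, 0.02, 400)
            df = rate_frame(x, y,
                            group=["case"] * 200 + ["control"] * 200)
            res = vertical_shift_test(df)
            big_t += abs(res.coefficient / res.se) >= 2
        assert big_t <= 0.10 * reps

    def test_linearity_power_on_quadratic(self, rng):
        hits = 0
        for _ in range(40):
            x = rng.uniform(1.1, 2.5, 500)
            y = accumulation_rate(x) + rng.normal(0, 0.02, 500)
            hits += linearity_test(rate_frame(x, y)).pvalue < 0.001
        assert hits >= 0.95 * 40

    def test_linearity_refuses_degenerate_nesting(self, rng):
        x = rng.uniform(0, 1, 50)
        with pytest.raises(ValueError, match="degenerate|exceed"):
            linearity_test(rate_frame(x, x), spline_df=1)


class TestTrajectoryIntegration:
    def test_zero_rate_gives_flat_curve(self):
        x = np.linspace(1.2, 2.0, 20)
        fit = RateCurveModel(rate_frame(x, np.zeros(20))).fit(lam=1.0)
        traj = fit.integrate(start_level=1.5, t_max=10.0)
        assert traj.stop_reason == "rate_below_epsilon"
        np.testing.assert_allclose(traj.levels, traj.start_level, atol=1e-10)

    def test_accumulation_rate_matches_closed_form_logistic(self):
        traj = integrate_rate(
            lambda a: accumulation_rate(a), start_level=1.2,
            t_max=30.0, step=0.05,
        )
        exact = logistic_level(1.2, 0.112, 1.1, 2.5, traj.times)
        np.testing.assert_allclose(traj.levels, exact, atol=1e-4)

    def test_step_halving_convergence(self):
        t1 = integrate_rate(lambda a: accumulation_rate(a), 1.2, 30.0, 0.05)
        t2 = integrate_rate(lambda a: accumulation_rate(a), 1.2, 30.0, 0.025)
        assert abs(t1.levels[-1] - t2.levels[-1]) < 1e-6

    def test_fitted_curve_integrates_to_monotone_sigmoid(self, pooled_annualized):
        fit = RateCurveModel(pooled_annualized).fit(target_edf=4.0)
        traj = fit.integrate(t_max=40.0, step=0.05)
        assert np.all(np.diff(traj.levels) >= -1e-12)
        assert traj.levels.max() <= fit.x_range[1] + 1e-9
        # one inflection: numerical second derivative changes sign once,
        # near the peak-rate level ~1.8
        d2 = np.diff(traj.levels, n=2)
        d2 = d2[np.abs(d2) > 1e-10]
        changes = np.flatnonzero(np.diff(np.sign(d2)) != 0)
        assert len(changes) == 1
        level_at_inflection = traj.levels[changes[0] + 1]
        assert 1.6 <= level_at_inflection <= 2.0

    def test_start_outside_range_rejected(self, pooled_annualized):
        fit = RateCurveModel(pooled_annualized).fit(target_edf=4.0)
        with pytest.raises(ValueError, match="start_level"):
            fit.integrate(start_level=fit.x_range[0] - 0.1)
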