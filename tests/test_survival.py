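"""Weibull evaluation, per-cycle event probabilities, RMST and KM fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsclc_cea import (KMPointSeries, WeibullParams, cycle_event_prob,
                       fit_weibull, rmst, weibull_mean, weibull_survival)
from nsclc_cea.survival import FitError, read_km, scale_to_cycles, write_km
from nsclc_cea.synthetic import SimConfig, simulate_km

EXPONENTIAL = WeibullParams(shape=1.0, scale=0.1)
CHEMO_OS_GE50 = WeibullParams(shape=0.868245, scale=0.093252)
NIVO_OS_GE50 = WeibullParams(shape=0.658678, scale=0.112585)

# ranges chosen to keep scale * t**shape well inside double precision so
# S(t) neither underflows to 0 nor rounds the event probability up to 1
params_st = st.builds(
    WeibullParams,
    shape=st.floats(0.3, 1.5),
    scale=st.floats(0.01, 0.3),
)


class TestWeibullSurvival:
    def test_survival_starts_at_one(self):
        assert weibull_survival(NIVO_OS_GE50, 0.0) == 1.0

    def test_exponential_special_case(self):
        assert weibull_survival(EXPONENTIAL, 5.0) == pytest.approx(
            np.exp(-0.5), abs=1e-12)

    def test_median_overall_survival_near_cycle_ten(self):
        # chemo OS in the >=50% stratum crosses 50% close to cycle 10
        assert weibull_survival(CHEMO_OS_GE50, 10.0) == pytest.approx(
            0.5023296, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_survival(EXPONENTIAL, -1.0)

    @settings(deadline=None)
    @given(params=params_st, t=st.floats(0.1, 60), dt=st.floats(0.1, 10))
    def test_strictly_decreasing(self, params, t, dt):
        assert weibull_survival(params, t + dt) < weibull_survival(params, t)


class TestCycleEventProb:
    def test_constant_hazard_when_shape_is_one(self):
        expected = 1 - np.exp(-0.1)
        for t in (0, 3, 17, 100):
            assert cycle_event_prob(EXPONENTIAL, t) == pytest.approx(
                expected, abs=1e-12)

    def test_first_cycle_death_probability(self):
        assert cycle_event_prob(NIVO_OS_GE50, 0) == pytest.approx(
            0.1064786, abs=1e-6)

    def test_matches_conditional_survival_ratio(self):
        # oracle: M(t) = (S(t) - S(t+1)) / S(t) from two survival evaluations
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = WeibullParams(shape=rng.uniform(0.3, 1.5),
                              scale=rng.uniform(0.01, 0.3))
            t = rng.uniform(0, 60)
            s0, s1 = weibull_survival(p, t), weibull_survival(p, t + 1)
            assert cycle_event_prob(p, t) == pytest.approx(
                (s0 - s1) / s0, abs=1e-12)

    @settings(deadline=None)
    @given(params=params_st, t=st.integers(0, 173))
    def test_is_a_probability(self, params, t):
        assert 0 <= cycle_event_prob(params, t) < 1


class TestRMST:
    def test_exponential_mean(self):
        assert rmst(EXPONENTIAL, 1e4) == pytest.approx(10.0, rel=1e-6)

    def test_exponential_restricted(self):
        assert rmst(EXPONENTIAL, 10.0) == pytest.approx(6.3212056, abs=1e-6)

    def test_monotone_in_horizon(self):
        assert rmst(CHEMO_OS_GE50, 50) < rmst(CHEMO_OS_GE50, 100)

    def test_closed_form_mean_agrees(self):
        assert rmst(CHEMO_OS_GE50, 5e3) == pytest.approx(
            weibull_mean(CHEMO_OS_GE50), rel=1e-6)


class TestFit:
    def test_noiseless_exact_recovery(self):
        true = WeibullParams(shape=0.8, scale=0.09)
        t = np.arange(1.0, 41.0)
        series = KMPointSeries(times=t, survival=weibull_survival(true, t))
        fit = fit_weibull(series)
        assert fit.params.shape == pytest.approx(0.8, abs=1e-6)
        assert fit.params.scale == pytest.approx(0.09, abs=1e-6)
        assert fit.rss < 1e-12
        assert fit.n_points_used == 40

    def test_parameter_recovery_from_simulated_cohort(self):
        true = WeibullParams(shape=0.97, scale=0.072)
        series = simulate_km(SimConfig(
            true_params=true, n_patients=500, admin_censor_cycle=30,
            grid=np.arange(1.0, 30.0), seed=7, digitization_noise_sd=0.0))
        fit = fit_weibull(series)
        assert fit.params.shape == pytest.approx(0.97, rel=0.10)
        assert fit.params.scale == pytest.approx(0.072, rel=0.10)

    def test_recovery_bias_shrinks_with_cohort_size(self):
        # mean combined relative error over 10 replicates per cohort size
        true = WeibullParams(shape=0.97, scale=0.072)

        def mean_err(n):
            errs = []
            for seed in range(10):
                series = simulate_km(SimConfig(
                    true_params=true, n_patients=n, admin_censor_cycle=30,
                    grid=np.arange(1.0, 30.0), seed=seed,
                    digitization_noise_sd=0.0))
                fit = fit_weibull(series)
                errs.append(abs(fit.params.shape - true.shape) / true.shape
                            + abs(fit.params.scale - true.scale) / true.scale)
            return float(np.mean(errs))

        errs = {n: mean_err(n) for n in (100, 500, 2000)}
        assert errs[2000] < errs[500] < errs[100]
        assert errs[2000] < 0.10

    def test_mle_cross_check(self):
        # independent oracle: lifelines Weibull MLE on the raw times
        from lifelines import WeibullFitter

        from nsclc_cea.synthetic import weibull_times

        true = WeibullParams(shape=1.2, scale=0.05)
        rng = np.random.default_rng(3)
        times = weibull_times(true, 4000, rng)
        wf = WeibullFitter().fit(times, event_observed=np.ones_like(times))
        # lifelines: S(t) = exp(-(t/lambda_)**rho_)
        mle = WeibullParams(shape=wf.rho_, scale=wf.lambda_ ** (-wf.rho_))
        series = simulate_km(SimConfig(
            true_params=true, n_patients=4000, admin_censor_cycle=200,
            grid=np.linspace(1, 120, 60), seed=3, digitization_noise_sd=0.0))
        fit = fit_weibull(series)
        assert fit.params.shape == pytest.approx(mle.shape, rel=0.05)
        assert fit.params.scale == pytest.approx(mle.scale, rel=0.10)

    def test_interval_weighting_uses_at_risk_counts(self):
        true = WeibullParams(shape=0.9, scale=0.08)
        series = simulate_km(SimConfig(
            true_params=true, n_patients=800, admin_censor_cycle=40,
            grid=np.arange(1.0, 40.0), seed=5, digitization_noise_sd=0.0))
        fit = fit_weibull(series, method="interval_weighted")
        assert fit.method == "interval_weighted"
        assert fit.params.shape == pytest.approx(0.9, rel=0.15)

    def test_too_few_points_rejected(self):
        series = KMPointSeries(times=np.array([1.0, 2.0]),
                               survival=np.array([0.9, 0.8]))
        with pytest.raises(FitError, match="3 usable points"):
            fit_weibull(series)

    def test_saturated_points_excluded(self):
        true = WeibullParams(shape=0.8, scale=0.09)
        t = np.arange(0.0, 21.0)
        s = np.concatenate([[1.0], weibull_survival(true, t[1:])])
        fit = fit_weibull(KMPointSeries(times=t, survival=s))
        assert fit.n_points_used == 20  # t=0 / S=1 dropped

    def test_unknown_method(self):
        series = KMPointSeries(times=np.arange(1.0, 10.0),
                               survival=np.exp(-0.1 * np.arange(1.0, 10.0)))
        with pytest.raises(ValueError, match="unknown fit method"):
            fit_weibull(series, method="mle")


class TestKMSeriesValidation:
    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            KMPointSeries(times=np.array([1.0, 2.0, 3.0]),
                          survival=np.array([0.9, 0.95, 0.8]))

    def test_tied_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            KMPointSeries(times=np.array([1.0, 1.0, 2.0]),
                          survival=np.array([0.9, 0.85, 0.8]))

    def test_io_roundtrip(self, tmp_path):
        series = KMPointSeries(times=np.array([1.0, 2.0, 4.0]),
                               survival=np.array([0.9, 0.7, 0.5]),
                               n_at_risk=np.array([100.0, 80.0, 50.0]))
        path = write_km(series, tmp_path / "km.tsv")
        back = read_km(path)
        np.testing.assert_allclose(back.times, series.times)
        np.testing.assert_allclose(back.survival, series.survival)
        np.testing.assert_allclose(back.n_at_risk, series.n_at_risk)


def test_unit_conversion_preserves_survival():
    # fitted on weeks, re-expressed in 6-week cycles: same S at equal time
    weekly = WeibullParams(shape=0.9, scale=0.02)
    cycles = scale_to_cycles(0.9, 0.02, time_unit_days=7.0)
    s_weekly = weibull_survival(weekly, 12.0)       # 12 weeks
    s_cycles = weibull_survival(cycles, 2.0)        # 2 six-week cycles
    assert s_cycles == pytest.approx(s_weekly, rel=1e-12)
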