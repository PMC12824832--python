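import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate

from mjm.simulate import (
    CalibrationError,
    ScenarioConfig,
    TrueParams,
    calibrate_scale,
    generate_dataset,
    icc_longitudinal,
    simulate_event_time,
    weibull_cum_hazard,
)


class TestIcc:
    @pytest.mark.parametrize(
        "var_v,expected_group",
        [(5.0, 5.0 / 48.0), (18.0, 18.0 / 61.0), (0.0, 0.0)],
    )
    def test_group_level_ratio(self, var_v, expected_group):
        icc_subject, icc_group = icc_longitudinal(10.0, 33.0, var_v)
        assert icc_group == pytest.approx(expected_group)
        assert icc_subject == pytest.approx(10.0 / (43.0 + var_v))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            icc_longitudinal(0.0, 0.0, 0.0)


class TestWeibullCumHazard:
    def test_closed_form(self):
        assert weibull_cum_hazard(0.1, 1.5, 4.0) == pytest.approx(0.8)

    def test_exponential_limit(self):
        assert weibull_cum_hazard(0.37, 1.0, 2.5) == pytest.approx(0.37 * 2.5)

    @pytest.mark.parametrize("scale,shape", [(0.1, 1.5), (2.0, 0.7), (0.5, 3.0)])
    def test_matches_quadrature_of_hazard(self, scale, shape):
        t = 4.2
        oracle, _ = integrate.quad(
            lambda s: scale * shape * s ** (shape - 1.0), 0.0, t
        )
        assert weibull_cum_hazard(scale, shape, t) == pytest.approx(
            oracle, rel=1e-8
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_cum_hazard(0.1, 1.5, -1.0)


class TestSimulateEventTime:
    def test_flat_trajectory_closed_form(self):
        # scale * e^(alpha a + g) = 0.5, shape = 1, u = e^-1 -> T = 2
        T = simulate_event_time(
            a=0.0, b=0.0, alpha=0.3, g=math.log(0.5), scale=1.0, shape=1.0,
            u=math.exp(-1.0),
        )
        assert T == pytest.approx(2.0, abs=1e-6)

    @pytest.mark.parametrize("shape", [0.8, 1.0, 1.5, 2.5])
    @pytest.mark.parametrize("u", [0.2, 0.5, 0.9])
    def test_flat_trajectory_general_shape(self, shape, u):
        a, g, alpha, scale = 14.0, 0.2, -0.2, 0.9
        amp = scale * math.exp(alpha * a + g)
        expected = (-math.log(u) / amp) ** (1.0 / shape)
        T = simulate_event_time(a, 0.0, alpha, g, scale, shape, u, horizon=1e3)
        assert T == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("alpha,b,u", [
        (-0.2, -0.8, 0.3), (-0.2, 1.1, 0.6), (0.15, -2.0, 0.1), (0.1, 0.5, 0.8),
    ])
    def test_exponential_baseline_closed_form(self, alpha, b, u):
        # shape = 1: Lambda(t) = scale e^(alpha a + g) (e^(alpha b t)-1)/(alpha b)
        a, g, scale = 10.0, -0.1, 0.05
        amp = scale * math.exp(alpha * a + g)
        R = -math.log(u)
        arg = 1.0 + R * alpha * b / amp
        if arg <= 0:
            expected = math.inf
        else:
            expected = math.log(arg) / (alpha * b)
        got = simulate_event_time(a, b, alpha, g, scale, 1.0, u, horizon=500.0)
        if math.isinf(expected):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_uniform_draw(self):
        Ts = [
            simulate_event_time(14.0, -0.5, -0.2, 0.0, 0.5, 1.5, u, horizon=1e3)
            for u in (0.1, 0.4, 0.7, 0.95)
        ]
        assert all(a > b for a, b in zip(Ts, Ts[1:]))

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.5, 1.5])
    def test_invalid_uniform_rejected(self, u):
        with pytest.raises(ValueError):
            simulate_event_time(0.0, 0.0, 0.0, 0.0, 1.0, 1.0, u)

    def test_beyond_horizon_is_inf(self):
        assert math.isinf(
            simulate_event_time(0.0, 0.0, 0.0, 0.0, 1e-9, 1.5, 0.5, horizon=9.0)
        )


class TestCalibrateScale:
    def test_higher_censoring_needs_smaller_scale(self):
        sc = ScenarioConfig()
        s20 = calibrate_scale(0.2, 1.5, sc, mc_size=20_000, seed=1)
        s60 = calibrate_scale(0.6, 1.5, sc, mc_size=20_000, seed=1)
        assert s60 < s20

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_scale(1.2, 1.5, ScenarioConfig())

    def test_small_mc_size_rejected(self):
        with pytest.raises(ValueError):
            calibrate_scale(0.2, 1.5, ScenarioConfig(), mc_size=100)


class TestGenerateDataset:
    def test_counts_and_schedule(self, small_sim, small_scenario):
        data, eff = small_sim
        n = small_scenario.L * small_scenario.group_size
        assert data.n_subjects == n
        assert len(data.survival) == n
        sched = np.arange(0.0, 5.01, 0.5)
        counts = data.longitudinal.groupby("subject_id").size()
        for j, sid in enumerate(data.subject_ids):
            expected = int(np.sum(sched < eff.true_event_time[j]))
            assert counts[sid] == expected

    def test_censored_subject_has_full_schedule(self, small_sim):
        data, eff = small_sim
        censored = data.survival[data.survival["event"] == 0]
        assert (censored["observed_time"] == 9.0).all()
        counts = data.longitudinal.groupby("subject_id").size()
        for sid in censored["subject_id"]:
            assert counts[sid] == 11  # baseline + 10 repeated measurements

    def test_treatment_assigned_to_half_the_groups(self, small_sim, small_scenario):
        data, eff = small_sim
        assert int(eff.treatment.sum()) == small_scenario.L // 2

    def test_event_times_invariant_to_measurement_noise(self, small_scenario):
        noisier = replace(
            small_scenario,
            truths=replace(small_scenario.truths, var_eps=5.0),
        )
        d1, e1 = generate_dataset(small_scenario)
        d2, e2 = generate_dataset(noisier)
        np.testing.assert_array_equal(e1.true_event_time, e2.true_event_time)
        assert d1.survival.equals(d2.survival)
        assert not np.allclose(
            d1.longitudinal["y"].to_numpy(), d2.longitudinal["y"].to_numpy()
        )

    def test_oracle_regression_recovers_fixed_effects(self):
        """Regressing y minus the known random effects on the fixed design
        recovers beta within 3 standard errors (sanity of the assembly)."""
        sc = ScenarioConfig(
            L=20, group_size=20, truths=TrueParams(scale=1.6786), seed=77,
        )
        data, eff = generate_dataset(sc)
        sub = np.array([data.subject_index[s] for s in data.longitudinal["subject_id"]])
        grp = eff.subject_group[sub]
        t = data.longitudinal["time"].to_numpy()
        y = data.longitudinal["y"].to_numpy()
        resid = y - eff.u[sub, 0] - eff.u[sub, 1] * t - eff.v[grp]
        trt = eff.treatment[grp]
        X = np.column_stack([np.ones_like(t), t, trt, trt * t])
        beta_hat, *_ = np.linalg.lstsq(X, resid, rcond=None)
        sigma2 = float(
            np.sum((resid - X @ beta_hat) ** 2) / (len(resid) - 4)
        )
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        truth = np.array([16.0, -0.8, 1.6, -2.0])
        assert np.all(np.abs(beta_hat - truth) < 3 * se)

    def test_group_mean_variance_matches_components(self):
        """Variance of group means of baseline y approaches
        var_v + (var_u0 + var_eps) / group size."""
        sc = ScenarioConfig(
            L=200, group_size=30,
            truths=TrueParams(scale=1e-8, beta001=0.0),  # no events: fast
            seed=5,
        )
        data, eff = generate_dataset(sc)
        base = data.longitudinal[data.longitudinal["time"] == 0.0]
        gmeans = base.groupby("group_id")["y"].mean().to_numpy()
        expected = 5.0 + (10.0 + 33.0) / 30.0
        se = expected * math.sqrt(2.0 / (len(gmeans) - 1))
        assert abs(float(np.var(gmeans, ddof=1)) - expected) < 3 * se

    def test_survival_curve_in_degenerate_limit(self):
        """With alpha = 0 and all variances 0 the model is a pure Weibull:
        the empirical survival curve matches exp(-scale t^shape) pointwise."""
        truths = TrueParams(
            var_u0=0.0, var_u1=0.0, var_eps=0.0, var_v=0.0, var_g=0.0,
            alpha=0.0, scale=0.05, shape=1.5, beta001=0.0, beta101=0.0,
        )
        sc = ScenarioConfig(
            L=100, group_size=30, var_v=0.0, var_g=0.0, truths=truths, seed=9,
        )
        data, eff = generate_dataset(sc)
        times = data.survival["observed_time"].to_numpy()
        events = data.survival["event"].to_numpy()
        for t0 in (1.0, 3.0, 5.0, 8.0):
            surv_emp = float(np.mean((times > t0) | ((times == t0) & (events == 0))))
            surv_true = math.exp(-0.05 * t0**1.5)
            assert abs(surv_emp - surv_true) < 0.01 + 3 * math.sqrt(
                surv_true * (1 - surv_true) / len(times)
            )
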