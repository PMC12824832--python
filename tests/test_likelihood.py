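import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mjm.data import TrialDataset
from mjm.design import build_arrays
from mjm.intervals import IntervalGrid, equal_length_grid
from mjm.likelihood import (
    UnconstrainedMap,
    log_density_longitudinal,
    log_density_random_effects,
    log_density_survival,
    log_mu,
    log_posterior,
    log_prior,
    longitudinal_mean,
)
from mjm.params import ModelSpec, ParamState, PriorSpec, SpecError
from mjm.simulate import ScenarioConfig, TrueParams, generate_dataset

SCHEDULE_CUTS = IntervalGrid((0.0, 0.5, 4.5, 12.5))
TABLE_BETA = np.array([16.0, -0.8, 1.6, -2.0])  # intercept, time, trt, trt:time


def sim_spec(Q=3, **kw):
    return ModelSpec.simulation_mjm(Q=Q) if not kw else ModelSpec(
        trajectory="linear",
        subject_random="intercept_slope",
        fixed_covariates_long=("treatment", "treatment:time"),
        Q=Q,
        **kw,
    )


def zero_state(arrays, beta=None, sigma_eps=1.0, lam=None, alpha=-0.2):
    return ParamState(
        beta=TABLE_BETA.copy() if beta is None else np.asarray(beta, float),
        sigma_eps=sigma_eps,
        lam=np.full(arrays.Q, 0.1) if lam is None else np.asarray(lam, float),
        gamma=np.zeros(arrays.p_gamma),
        alpha=alpha if arrays.has_alpha else None,
        Sigma_u=np.eye(arrays.p_u) if arrays.has_u else None,
        sigma_v=1.0 if arrays.has_v else None,
        sigma_g=1.0 if arrays.has_g else None,
        u=np.zeros((arrays.n, arrays.p_u)) if arrays.has_u else None,
        v=np.zeros(arrays.L) if arrays.has_v else None,
        g=np.zeros(arrays.L) if arrays.has_g else None,
    )


@pytest.fixture
def tiny_arrays(tiny_dataset):
    return build_arrays(tiny_dataset, sim_spec(Q=3), SCHEDULE_CUTS)


def one_subject_dataset(times, y, T=0.4, event=1):
    longitudinal = pd.DataFrame(
        {
            "subject_id": "A",
            "group_id": "g1",
            "time": times,
            "y": y,
        }
    )
    survival = pd.DataFrame(
        {
            "subject_id": ["A"],
            "group_id": ["g1"],
            "observed_time": [T],
            "event": [event],
        }
    )
    groups = pd.DataFrame({"group_id": ["g1"], "treatment": [0]})
    return TrialDataset(longitudinal, survival, groups)


class TestLongitudinalMean:
    def test_treated_subject_arithmetic(self, tiny_arrays):
        st = zero_state(tiny_arrays)
        # subject A: group g1, treatment 1: 16 + 1.6 + (-0.8 - 2)*1
        assert longitudinal_mean(st, tiny_arrays, 0, 1.0) == pytest.approx(14.8)

    def test_control_intercept_identity(self, tiny_arrays):
        st = zero_state(tiny_arrays)
        # subject B: group g2, treatment 0, t = 0
        assert longitudinal_mean(st, tiny_arrays, 1, 0.0) == pytest.approx(16.0)

    def test_random_effects_add_linearly(self, tiny_arrays):
        st = zero_state(tiny_arrays)
        st.u[1] = [1.0, 0.5]
        st.v[1] = -0.25
        # control subject at t=2: 16 + 1 - 0.8*2 + 0.5*2 - 0.25
        assert longitudinal_mean(st, tiny_arrays, 1, 2.0) == pytest.approx(16.15)

    def test_unknown_covariate_is_spec_error(self, tiny_dataset):
        spec = sim_spec(Q=3)
        bad = ModelSpec(
            fixed_covariates_long=("nonexistent",), Q=3,
        )
        with pytest.raises(SpecError, match="unknown covariate"):
            build_arrays(tiny_dataset, bad, SCHEDULE_CUTS)


class TestLogDensityLongitudinal:
    def test_single_measurement_at_mean(self):
        data = one_subject_dataset([0.0], [16.0])
        arrays = build_arrays(data, sim_spec(Q=1), equal_length_grid(1.0, 1))
        st = zero_state(arrays)  # control subject: m(0) = 16 = y
        assert log_density_longitudinal(st, arrays) == pytest.approx(
            -0.5 * math.log(2 * math.pi)
        )

    def test_doubling_sigma_costs_log2_per_observation(self):
        times = [0.0, 0.5, 1.0]
        means = [16.0, 15.6, 15.2]  # exactly m(t) for the control subject
        data = one_subject_dataset(times, means, T=2.0)
        arrays = build_arrays(data, sim_spec(Q=1), equal_length_grid(2.0, 1))
        lo = log_density_longitudinal(zero_state(arrays, sigma_eps=1.0), arrays)
        hi = log_density_longitudinal(zero_state(arrays, sigma_eps=2.0), arrays)
        assert lo - hi == pytest.approx(3 * math.log(2.0))

    def test_matches_pointwise_oracle(self, tiny_arrays, tiny_dataset):
        st = zero_state(tiny_arrays, sigma_eps=2.5)
        rng = np.random.default_rng(1)
        st.u = rng.normal(0, 1, st.u.shape)
        st.v = rng.normal(0, 1, st.v.shape)
        total = 0.0
        for _, row in tiny_dataset.longitudinal.iterrows():
            j = tiny_dataset.subject_index[row["subject_id"]]
            m = longitudinal_mean(st, tiny_arrays, j, row["time"])
            total += stats.norm.logpdf(row["y"], loc=m, scale=st.sigma_eps)
        assert log_density_longitudinal(st, tiny_arrays) == pytest.approx(total)

    def test_nonpositive_sigma_rejected(self, tiny_arrays):
        st = zero_state(tiny_arrays)
        st.sigma_eps = -1.0
        with pytest.raises(ValueError):
            log_density_longitudinal(st, tiny_arrays)


class TestLogMu:
    def test_arithmetic(self, tiny_arrays):
        st = zero_state(tiny_arrays, lam=[0.1, 0.1, 0.1])
        out = log_mu(st, tiny_arrays, exposure=0.5, q=1, m_value=14.8, group=0)
        assert out == pytest.approx(math.log(0.5) + math.log(0.1) - 2.96)

    def test_null_association_limit(self, tiny_arrays):
        st = zero_state(tiny_arrays, lam=[0.2, 0.2, 0.2], alpha=0.0)
        out = log_mu(st, tiny_arrays, exposure=0.7, q=2, m_value=99.0, group=1)
        assert out == pytest.approx(math.log(0.7 * 0.2))

    def test_frailty_additivity(self, tiny_arrays):
        st = zero_state(tiny_arrays)
        base = log_mu(st, tiny_arrays, exposure=0.5, q=1, m_value=10.0, group=0)
        st.g[0] = 0.3
        assert log_mu(
            st, tiny_arrays, exposure=0.5, q=1, m_value=10.0, group=0
        ) == pytest.approx(base + 0.3)

    def test_zero_exposure_rejected(self, tiny_arrays):
        st = zero_state(tiny_arrays)
        with pytest.raises(ValueError):
            log_mu(st, tiny_arrays, exposure=0.0, q=1, m_value=10.0, group=0)


class TestLogDensitySurvival:
    @pytest.mark.parametrize("event,expected", [(0, -0.5), (1, math.log(0.5) - 0.5)])
    def test_single_record(self, event, expected):
        data = one_subject_dataset([0.0], [16.0], T=1.0, event=event)
        arrays = build_arrays(data, sim_spec(Q=1), equal_length_grid(1.0, 1))
        # control subject, alpha = 0, g = 0: mu = exposure * lambda = 0.5
        st = zero_state(arrays, lam=[0.5], alpha=0.0)
        assert log_density_survival(st, arrays) == pytest.approx(expected)

    def test_matches_piecewise_exponential_up_to_offset(self, tiny_arrays):
        """Cross-module oracle: survival log-density == direct piecewise-
        exponential log-likelihood + sum_{d=1} log(exposure)."""
        st = zero_state(tiny_arrays, lam=[0.2, 0.08, 0.05])
        rng = np.random.default_rng(3)
        st.u = rng.normal(0, 0.5, st.u.shape)
        st.v = rng.normal(0, 0.5, st.v.shape)
        st.g = rng.normal(0, 0.5, st.g.shape)

        direct = 0.0
        offset = 0.0
        for k in range(len(tiny_arrays.d)):
            m_k = (
                tiny_arrays.Xe[k] @ st.beta
                + tiny_arrays.Ze[k] @ st.u[tiny_arrays.ps_sub[k]]
                + st.v[tiny_arrays.ps_grp[k]]
            )
            rate = st.lam[tiny_arrays.qidx[k]] * math.exp(
                st.alpha * m_k + st.g[tiny_arrays.ps_grp[k]]
            )
            direct += -tiny_arrays.expo[k] * rate
            if tiny_arrays.d[k] == 1:
                direct += math.log(rate)
                offset += math.log(tiny_arrays.expo[k])
        assert log_density_survival(st, tiny_arrays) == pytest.approx(
            direct + offset, abs=1e-10
        )


class TestLogPrior:
    def test_beta_sign_symmetry(self, tiny_arrays):
        priors = PriorSpec()
        st = zero_state(tiny_arrays)
        lp_plus = log_prior(st, tiny_arrays, priors)
        st.beta = -st.beta
        assert log_prior(st, tiny_arrays, priors) == pytest.approx(lp_plus)

    def test_lambda_gamma_term(self, tiny_arrays):
        priors = PriorSpec()
        st = zero_state(tiny_arrays, lam=[1.0, 1.0, 1.0])
        st2 = zero_state(tiny_arrays, lam=[1.0, 1.0, 2.0])
        diff = log_prior(st2, tiny_arrays, priors) - log_prior(st, tiny_arrays, priors)
        a, b = priors.lambda_gamma
        assert diff == pytest.approx(
            stats.gamma.logpdf(2.0, a, scale=1 / b)
            - stats.gamma.logpdf(1.0, a, scale=1 / b)
        )

    def test_inverse_wishart_against_scipy(self, tiny_arrays):
        priors = PriorSpec()
        st = zero_state(tiny_arrays)
        base = log_prior(st, tiny_arrays, priors)
        S = np.array([[2.0, 0.3], [0.3, 1.4]])
        st2 = zero_state(tiny_arrays)
        st2.Sigma_u = S
        diff = log_prior(st2, tiny_arrays, priors) - base
        oracle = stats.invwishart.logpdf(S, df=2, scale=np.eye(2)) - (
            stats.invwishart.logpdf(np.eye(2), df=2, scale=np.eye(2))
        )
        assert diff == pytest.approx(oracle, abs=1e-10)

    def test_outside_support_is_minus_inf(self, tiny_arrays):
        st = zero_state(tiny_arrays)
        st.lam[0] = -0.1
        assert log_prior(st, tiny_arrays, PriorSpec()) == -math.inf


class TestLogPosterior:
    def test_is_sum_of_components(self, tiny_arrays):
        priors = PriorSpec()
        st = zero_state(tiny_arrays, sigma_eps=3.0)
        rng = np.random.default_rng(5)
        st.u = rng.normal(0, 1, st.u.shape)
        st.v = rng.normal(0, 1, st.v.shape)
        st.g = rng.normal(0, 0.3, st.g.shape)
        total = log_posterior(st, tiny_arrays, priors)
        parts = (
            log_prior(st, tiny_arrays, priors)
            + log_density_longitudinal(st, tiny_arrays)
            + log_density_survival(st, tiny_arrays)
            + log_density_random_effects(st, tiny_arrays)
        )
        assert total == pytest.approx(parts)

    def test_two_level_nesting_identity(self, tiny_dataset):
        """With v = g = 0 and their density/prior terms removed, the MJM
        log-posterior equals the two-level JM log-posterior exactly."""
        priors = PriorSpec()
        arrays3 = build_arrays(tiny_dataset, sim_spec(Q=3), SCHEDULE_CUTS)
        arrays2 = build_arrays(
            tiny_dataset, ModelSpec.simulation_jm(Q=3), SCHEDULE_CUTS
        )
        st3 = zero_state(arrays3, sigma_eps=2.0)
        rng = np.random.default_rng(8)
        st3.u = rng.normal(0, 1, st3.u.shape)
        st3.v[:] = 0.0
        st3.g[:] = 0.0
        st2 = zero_state(arrays2, sigma_eps=2.0)
        st2.u = st3.u.copy()

        lp3 = log_posterior(st3, arrays3, priors)
        lp2 = log_posterior(st2, arrays2, priors)
        L = arrays3.L
        # group-level terms present only in the MJM posterior
        from mjm.likelihood import _log_invgamma

        extra = (
            L * stats.norm.logpdf(0.0, scale=st3.sigma_v)
            + L * stats.norm.logpdf(0.0, scale=st3.sigma_g)
            + _log_invgamma(st3.sigma_v**2, 0.5, 0.5)
            + _log_invgamma(st3.sigma_g**2, 0.5, 0.5)
        )
        assert lp3 == pytest.approx(lp2 + extra, abs=1e-9)

    def test_invariant_under_subject_relabeling(self, tiny_tables):
        priors = PriorSpec()
        long, surv, groups = tiny_tables
        relabel = {"A": "Z9", "B": "Q1", "C": "M5"}
        long2 = long.assign(subject_id=long["subject_id"].map(relabel))
        surv2 = surv.assign(subject_id=surv["subject_id"].map(relabel))
        d1 = TrialDataset(long, surv, groups)
        d2 = TrialDataset(long2, surv2, groups)
        a1 = build_arrays(d1, sim_spec(Q=3), SCHEDULE_CUTS)
        a2 = build_arrays(d2, sim_spec(Q=3), SCHEDULE_CUTS)
        st1 = zero_state(a1, sigma_eps=2.0)
        rng = np.random.default_rng(9)
        st1.u = rng.normal(0, 1, st1.u.shape)
        # map each old subject's random effects to its new dense index
        st2 = zero_state(a2, sigma_eps=2.0)
        for old, new in relabel.items():
            st2.u[d2.subject_index[new]] = st1.u[d1.subject_index[old]]
        assert log_posterior(st1, a1, priors) == pytest.approx(
            log_posterior(st2, a2, priors)
        )


class TestGradient:
    @pytest.mark.parametrize(
        "spec",
        [
            ModelSpec.simulation_mjm(Q=3),
            ModelSpec.simulation_jm(Q=3),
            ModelSpec.mjm(1, Q=3),
        ],
        ids=["mjm", "jm", "mjm1_with_survival_covariate"],
    )
    def test_matches_finite_differences(self, spec):
        sc = ScenarioConfig(
            L=4, group_size=5, Q=3, truths=TrueParams(scale=1.68), seed=2
        )
        data, _ = generate_dataset(sc)
        arrays = build_arrays(data, spec, equal_length_grid(9.0, 3))
        umap = UnconstrainedMap(arrays, PriorSpec())
        rng = np.random.default_rng(0)
        st = ParamState(
            beta=rng.normal(0, 1, arrays.p_beta),
            sigma_eps=2.3,
            lam=rng.uniform(0.1, 0.5, 3),
            gamma=rng.normal(0, 0.3, arrays.p_gamma),
            alpha=-0.15 if arrays.has_alpha else None,
            Sigma_u=np.array([[2.0, 0.4], [0.4, 1.5]]),
            sigma_v=1.2 if arrays.has_v else None,
            sigma_g=0.7 if arrays.has_g else None,
            u=rng.normal(0, 1, (arrays.n, arrays.p_u)),
            v=rng.normal(0, 1, arrays.L) if arrays.has_v else None,
            g=rng.normal(0, 0.5, arrays.L) if arrays.has_g else None,
        )
        vec = umap.pack(st)
        # pack/unpack round trip preserves the density
        assert umap.log_posterior(vec) == pytest.approx(
            log_posterior(st, arrays, PriorSpec())
            + umap._log_jacobian(vec)
        )
        grad = umap.grad_log_posterior(vec)
        h = 1e-6
        fd = np.empty_like(vec)
        for k in range(len(vec)):
            vp, vm = vec.copy(), vec.copy()
            vp[k] += h
            vm[k] -= h
            fd[k] = (umap.log_posterior(vp) - umap.log_posterior(vm)) / (2 * h)
        rel = np.abs(grad - fd) / (1.0 + np.abs(fd))
        assert np.max(rel) < 1e-5

    def test_cholesky_jacobian_determinant(self):
        """The stated log-Jacobian of the (log-diag Cholesky) -> Sigma map
        matches a numerical Jacobian determinant for p = 2."""
        def to_sigma(vec):
            C = np.array(
                [[math.exp(vec[0]), 0.0], [vec[1], math.exp(vec[2])]]
            )
            S = C @ C.T
            return np.array([S[0, 0], S[1, 0], S[1, 1]])

        vec = np.array([0.3, -0.4, 0.1])
        h = 1e-6
        J = np.empty((3, 3))
        for k in range(3):
            vp, vm = vec.copy(), vec.copy()
            vp[k] += h
            vm[k] -= h
            J[:, k] = (to_sigma(vp) - to_sigma(vm)) / (2 * h)
        num = math.log(abs(np.linalg.det(J)))
        # p log 2 + sum_i (p - i + 1) eta_i  (0-based i)
        stated = 2 * math.log(2.0) + (2 + 1) * vec[0] + (2 - 1 + 1) * vec[2]
        assert num == pytest.approx(stated, abs=1e-6)
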