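import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mjm.data import TrialDataset
from mjm.design import build_arrays
from mjm.diagnostics import dic, ess, posterior_mean_state, summarize
from mjm.intervals import equal_length_grid
from mjm.params import ModelSpec, ParamState, PriorSpec
from mjm.sampler import InitializationError, McmcConfig, run_mcmc


def flat_dataset(n=40, mu=2.0, sigma=1.0, seed=0):
    """n subjects with a single baseline measurement each, one group."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    longitudinal = pd.DataFrame(
        {
            "subject_id": ids,
            "group_id": "g1",
            "time": 0.0,
            "y": mu + sigma * rng.standard_normal(n),
        }
    )
    survival = pd.DataFrame(
        {
            "subject_id": ids,
            "group_id": "g1",
            "observed_time": rng.uniform(0.5, 4.0, n).round(3),
            "event": rng.integers(0, 2, n),
        }
    )
    groups = pd.DataFrame({"group_id": ["g1"], "treatment": [0]})
    return TrialDataset(longitudinal, survival, groups)


def bare_spec(**kw):
    """No random effects, no association: conjugate diagnostic submodels."""
    base = dict(
        trajectory="linear",
        subject_random="none",
        fixed_covariates_long=(),
        fixed_covariates_surv=(),
        association="none",
        multilevel=False,
        Q=1,
    )
    base.update(kw)
    return ModelSpec(**base)


class TestConjugateOracles:
    def test_normal_normal_posterior(self):
        """Intercept-only longitudinal model with (effectively) known
        noise SD: the beta posterior must match the analytic conjugate
        normal posterior within 3 Monte-Carlo SEs."""
        sigma0 = 1.0
        data = flat_dataset(n=40, mu=2.0, sigma=sigma0, seed=10)
        spec = bare_spec(include_survival=False)
        # pin the residual variance at sigma0^2 via a very tight prior
        priors = PriorSpec(sigma_eps_ig=(1e8, 1e8 * sigma0**2))
        arrays = build_arrays(data, spec, equal_length_grid(4.0, 1))
        draws = run_mcmc(
            arrays, priors, McmcConfig(chains=2, adapt=50, burn_in=200,
                                       thin=1, draws_per_chain=500, seed=3)
        )
        y = data.longitudinal["y"].to_numpy()
        prec = len(y) / sigma0**2 + 1.0 / priors.beta_variance
        post_mean = (y.sum() / sigma0**2) / prec
        post_sd = math.sqrt(1.0 / prec)

        chain = draws.params["beta:Intercept"]
        est_mean = float(np.mean(chain))
        n_eff = ess(chain)
        mcse_mean = float(np.std(chain, ddof=1)) / math.sqrt(n_eff)
        assert abs(est_mean - post_mean) < 3 * mcse_mean
        est_sd = float(np.std(chain, ddof=1))
        mcse_sd = est_sd / math.sqrt(2 * (n_eff - 1))
        assert abs(est_sd - post_sd) < 3 * mcse_sd

    def test_poisson_gamma_posterior(self):
        """Single-interval hazard with no association and no random
        effects: lambda posterior is Gamma(a + sum d, b + sum exposure)."""
        data = flat_dataset(n=40, seed=11)
        spec = bare_spec(include_survival=True)
        priors = PriorSpec()
        arrays = build_arrays(data, spec, equal_length_grid(4.0, 1))
        draws = run_mcmc(
            arrays, priors, McmcConfig(chains=2, adapt=50, burn_in=100,
                                       thin=1, draws_per_chain=500, seed=4)
        )
        a, b = priors.lambda_gamma
        shape = a + data.survival["event"].sum()
        rate = b + data.survival["observed_time"].sum()
        chain = draws.params["lambda[1]"]
        n_eff = ess(chain)
        est_mean = float(np.mean(chain))
        mcse_mean = float(np.std(chain, ddof=1)) / math.sqrt(n_eff)
        assert abs(est_mean - shape / rate) < 3 * mcse_mean
        est_sd = float(np.std(chain, ddof=1))
        true_sd = math.sqrt(shape) / rate
        assert abs(est_sd - true_sd) < 3 * est_sd / math.sqrt(2 * (n_eff - 1))
        # exact-distribution check on pooled draws
        ks = stats.kstest(
            draws.pooled("lambda[1]"), stats.gamma(shape, scale=1 / rate).cdf
        )
        assert ks.pvalue > 1e-4


class TestDeterminism:
    def test_same_seed_identical_draws(self, small_sim_dataset):
        spec = ModelSpec.simulation_mjm(Q=3)
        arrays = build_arrays(
            small_sim_dataset, spec, equal_length_grid(9.0, 3)
        )
        cfg = McmcConfig(chains=2, adapt=20, burn_in=30, thin=1,
                         draws_per_chain=20, seed=77)
        d1 = run_mcmc(arrays, PriorSpec(), cfg)
        d2 = run_mcmc(arrays, PriorSpec(), cfg)
        for nm in d1.names:
            np.testing.assert_array_equal(d1.params[nm], d2.params[nm])
        np.testing.assert_array_equal(d1.deviance, d2.deviance)

    def test_different_seed_differs(self, small_sim_dataset):
        spec = ModelSpec.simulation_mjm(Q=3)
        arrays = build_arrays(
            small_sim_dataset, spec, equal_length_grid(9.0, 3)
        )
        d1 = run_mcmc(arrays, PriorSpec(), McmcConfig(
            chains=1, adapt=20, burn_in=30, thin=1, draws_per_chain=20, seed=1))
        d2 = run_mcmc(arrays, PriorSpec(), McmcConfig(
            chains=1, adapt=20, burn_in=30, thin=1, draws_per_chain=20, seed=2))
        assert not np.array_equal(
            d1.params["beta:Intercept"], d2.params["beta:Intercept"]
        )


class TestInitialization:
    def test_bad_initial_state_raises(self, small_sim_dataset):
        spec = ModelSpec.simulation_mjm(Q=3)
        arrays = build_arrays(
            small_sim_dataset, spec, equal_length_grid(9.0, 3)
        )
        bad = ParamState(
            beta=np.zeros(arrays.p_beta),
            sigma_eps=1.0,
            lam=np.array([-1.0, 0.1, 0.1]),  # outside the support
            alpha=0.0,
            Sigma_u=np.eye(2),
            sigma_v=1.0,
            sigma_g=1.0,
            u=np.zeros((arrays.n, 2)),
            v=np.zeros(arrays.L),
            g=np.zeros(arrays.L),
        )
        with pytest.raises(InitializationError, match="non-finite"):
            run_mcmc(arrays, PriorSpec(), McmcConfig(
                chains=1, adapt=1, burn_in=1, thin=1, draws_per_chain=1,
                seed=0), initial_state=bad)


class TestDic:
    def test_two_pass_oracle_no_random_effects(self):
        """With no random effects the stored scalars determine the state,
        so the recorded per-draw deviance can be recomputed independently."""
        from mjm.likelihood import (
            log_density_longitudinal,
            log_density_survival,
        )

        data = flat_dataset(n=25, seed=12)
        spec = bare_spec(include_survival=True)
        arrays = build_arrays(data, spec, equal_length_grid(4.0, 1))
        draws = run_mcmc(
            arrays, PriorSpec(), McmcConfig(chains=1, adapt=20, burn_in=50,
                                            thin=1, draws_per_chain=40, seed=5)
        )
        recomputed = np.empty(draws.n_draws)
        for k in range(draws.n_draws):
            st = ParamState(
                beta=np.array(
                    [draws.params["beta:Intercept"][0, k],
                     draws.params["beta:time"][0, k]]
                ),
                sigma_eps=draws.params["sigma_eps"][0, k],
                lam=np.array([draws.params["lambda[1]"][0, k]]),
            )
            recomputed[k] = -2.0 * (
                log_density_longitudinal(st, arrays)
                + log_density_survival(st, arrays)
            )
        np.testing.assert_allclose(recomputed, draws.deviance[0], rtol=1e-10)

        out = dic(draws, arrays)
        assert out["dic"] == pytest.approx(out["d_bar"] + out["p_d"])
        assert out["p_d"] == pytest.approx(out["d_bar"] - out["d_hat"])

    def test_degenerate_draws_give_zero_pd(self):
        """If every draw is the same state, theta-bar is that state and
        p_D collapses to zero."""
        data = flat_dataset(n=25, seed=13)
        spec = bare_spec(include_survival=True)
        arrays = build_arrays(data, spec, equal_length_grid(4.0, 1))
        draws = run_mcmc(
            arrays, PriorSpec(), McmcConfig(chains=1, adapt=10, burn_in=10,
                                            thin=1, draws_per_chain=1, seed=6)
        )
        # tile the single kept draw
        for nm in draws.names:
            draws.params[nm] = np.tile(draws.params[nm], (2, 8))
        draws.deviance = np.tile(draws.deviance, (2, 8))
        out = dic(draws, arrays)
        assert out["p_d"] == pytest.approx(0.0, abs=1e-8)
        assert out["dic"] == pytest.approx(out["d_bar"], abs=1e-8)
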