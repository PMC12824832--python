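"""Convergence diagnostics and posterior summaries.

Implements the reference MCMC workflow: the split-chain Gelman-Rubin-Brooks
potential scale reduction factor (convergence declared when R-hat < 1.1 for
all gated parameters), autocorrelation functions for choosing the thinning
interval, an autocorrelation-sum effective sample size, and per-parameter
posterior summaries (mean, SD, 2.5% and 97.5% quantiles).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ModelArrays
from .likelihood import log_density_longitudinal, log_density_survival
from .params import ParamState, PriorSpec
from .sampler import PosteriorDraws

__all__ = [
    "rhat",
    "acf",
    "ess",
    "summarize",
    "PosteriorSummary",
    "RHAT_THRESHOLD",
    "dic",
    "posterior_mean_state",
]

RHAT_THRESHOLD = 1.1


def rhat(chains: np.ndarray | list) -> float:
    """Split-chain Gelman-Rubin-Brooks potential scale reduction factor.

    ``chains`` is an (n_chains, n_draws) array (or list of equal-length
     1-d arrays).  Each chain is split in half, so the statistic also
    detects trends within chains.  Returns ``inf`` when the within-chain
    variance vanishes while chains disagree.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-d (chain, draw) array")
    c, d = arr.shape
    if c < 2:
        raise ValueError("rhat needs at least 2 chains")
    if d < 4:
        raise ValueError("rhat needs at least 4 draws per chain")
    half = d // 2
    split = np.concatenate([arr[:, :half], arr[:, half: 2 * half]], axis=0)
    m, n = split.shape
    means = split.mean(axis=1)
    W = float(np.mean(np.var(split, axis=1, ddof=1)))
    B = n * float(np.var(means, ddof=1))
    if W == 0.0:
        return math.inf if B > 0 else 1.0
    var_plus = (n - 1) / n * W + B / n
    return math.sqrt(var_plus / W)


def acf(draws: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation of a single chain at lags 0..max_lag.

    Uses the standard biased estimator (normalized by the lag-0
    autocovariance).  A constant chain has undefined autocorrelation; NaNs
    are returned with a warning.
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = len(x)
    if n <= max_lag:
        raise ValueError("need more draws than max_lag")
    x = x - x.mean()
    c0 = float(x @ x) / n
    if c0 == 0.0:
        warnings.warn("constant chain: autocorrelation undefined", RuntimeWarning)
        return np.full(max_lag + 1, np.nan)
    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        out[lag] = float(x[: n - lag] @ x[lag:]) / n / c0
    return out


def ess(chains: np.ndarray) -> float:
    """Effective sample size via the autocorrelation-sum estimator.

    Autocorrelations are averaged across chains and summed in Geyer pairs
    until a pair sum turns negative.
    """
    arr = np.atleast_2d(np.asarray(chains, dtype=float))
    c, d = arr.shape
    if d < 4:
        return float(c * d)
    max_lag = min(d - 2, 1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rhos = np.array([acf(arr[i], max_lag) for i in range(c)])
    if np.isnan(rhos).all():
        return float("nan")
    rho = np.nanmean(rhos, axis=0)
    s = 0.0
    lag = 1
    while lag + 1 <= max_lag:
        pair = rho[lag] + rho[lag + 1]
        if not np.isfinite(pair) or pair < 0:
            break
        s += pair
        lag += 2
    return float(c * d / (1.0 + 2.0 * s))


@dataclass
class PosteriorSummary:
    """Per-parameter posterior summary with the convergence verdict."""

    table: pd.DataFrame
    gated: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        gated = self.gated or list(self.table.index)
        vals = self.table.loc[gated, "rhat"].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        return bool(finite.all() and (vals < RHAT_THRESHOLD).all())

    @property
    def max_rhat(self) -> float:
        gated = self.gated or list(self.table.index)
        return float(np.max(self.table.loc[gated, "rhat"].to_numpy(dtype=float)))

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]


def gated_parameters(names: list[str]) -> list[str]:
    """Parameters whose R-hat gates the convergence verdict.

    All fixed effects, the association parameter and every variance
    component; the (derived) correlation, SD aliases and per-interval
    hazard pieces are reported but not gated.
    """
    keep = []
    for nm in names:
        if nm.startswith("beta:") or nm.startswith("gamma:") or nm == "alpha":
            keep.append(nm)
        elif nm in ("var_eps", "var_u0", "var_u1", "cov_u01", "var_v", "var_g"):
            keep.append(nm)
    return keep


def summarize(draws: PosteriorDraws | dict[str, np.ndarray]) -> PosteriorSummary:
    """Pooled mean, SD, 2.5%/97.5% quantiles, R-hat and ESS per parameter.

    Quantiles use linear interpolation; the SD is the pooled sample
    standard deviation (ddof=1).  With a single chain R-hat is undefined
    and reported as NaN.
    """
    if isinstance(draws, PosteriorDraws):
        params = draws.params
        gated = gated_parameters(draws.names)
    else:
        params = {k: np.atleast_2d(np.asarray(v, float)) for k, v in draws.items()}
        gated = []
    rows = []
    for nm, arr in params.items():
        pooled = arr.reshape(-1)
        c = arr.shape[0]
        if c >= 2 and arr.shape[1] >= 4:
            r = rhat(arr)
        else:
            r = float("nan")
        rows.append(
            {
                "mean": float(np.mean(pooled)),
                "sd": float(np.std(pooled, ddof=1)) if len(pooled) > 1 else 0.0,
                "q2.5": float(np.percentile(pooled, 2.5)),
                "q97.5": float(np.percentile(pooled, 97.5)),
                "rhat": r,
                "ess": ess(arr),
            }
        )
    table = pd.DataFrame(rows, index=list(params.keys()))
    gated = [g for g in gated if g in table.index]
    return PosteriorSummary(table=table, gated=gated)


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

def posterior_mean_state(draws: PosteriorDraws, model: ModelArrays) -> ParamState:
    """State assembled from the posterior means of every sampled quantity."""
    def pmean(name: str) -> float:
        return float(np.mean(draws.params[name]))

    beta = np.array([pmean(f"beta:{nm}") for nm in model.beta_names])
    lam = np.array([pmean(f"lambda[{q}]") for q in range(1, model.Q + 1)])
    gamma = np.array([pmean(f"gamma:{nm}") for nm in model.gamma_names])
    Sigma_u = None
    if model.has_u:
        if model.p_u == 2:
            Sigma_u = np.array(
                [
                    [pmean("var_u0"), pmean("cov_u01")],
                    [pmean("cov_u01"), pmean("var_u1")],
                ]
            )
        else:
            Sigma_u = np.array([[pmean("var_u0")]])
    re = draws.random_effects
    return ParamState(
        beta=beta,
        sigma_eps=pmean("sigma_eps"),
        lam=lam,
        gamma=gamma,
        alpha=pmean("alpha") if model.has_alpha else None,
        Sigma_u=Sigma_u,
        sigma_v=pmean("sigma_v") if model.has_v else None,
        sigma_g=pmean("sigma_g") if model.has_g else None,
        u=re["u"].mean(axis=(0, 1)) if model.has_u else None,
        v=re["v"].mean(axis=(0, 1)) if model.has_v else None,
        g=re["g"].mean(axis=(0, 1)) if model.has_g else None,
    )


def dic(draws: PosteriorDraws, model: ModelArrays) -> dict[str, float]:
    """Deviance information criterion with the conditional deviance.

    The deviance D = -2*(longitudinal + survival log-likelihood) is
    conditional on the random effects (the BUGS/JAGS convention, under
    which group-level structure contributes to the effective number of
    parameters p_D).  D-bar averages the per-draw deviances recorded
    during sampling; D(theta-bar) plugs in the posterior means of every
    quantity entering D.  DIC = D-bar + p_D with p_D = D-bar - D(theta-bar).
    """
    d_bar = float(np.mean(draws.deviance))
    state = posterior_mean_state(draws, model)
    d_hat = -2.0 * (
        log_density_longitudinal(state, model) + log_density_survival(state, model)
    )
    p_d = d_bar - d_hat
    return {"dic": d_bar + p_d, "p_d": p_d, "d_bar": d_bar, "d_hat": d_hat}
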