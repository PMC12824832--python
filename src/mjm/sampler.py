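"""Blocked MCMC for the multilevel joint model.

The sampler targets the joint posterior over parameters and random effects
exactly as defined in :mod:`mjm.likelihood`, using a Metropolis-within-
Gibbs sweep tailored to the model's structure:

* ``(beta, v)`` — joint independence proposal from their exact Gaussian
  conditional under the longitudinal likelihood and priors, corrected by a
  Metropolis step for the survival factor (which involves beta and v only
  through the current value alpha*m(t)).  When the association is absent
  the step is an exact Gibbs draw.
* ``u`` — the same construction per subject, vectorized across subjects
  (subjects are conditionally independent given the rest).
* ``g`` (frailties), ``alpha``, ``gamma`` — adaptive random-walk
  Metropolis; the alpha proposal is tilted by a compensating shift of the
  log baseline-hazard pieces to decorrelate the association parameter from
  the hazard level.
* ``sigma_eps^2``, ``Sigma_u``, ``sigma_v^2``, ``sigma_g^2``, ``lambda_q``
  — exact conjugate Gibbs draws (inverse-gamma / inverse-Wishart / gamma).
* translation moves — exact Gibbs draws along directions in which a fixed
  effect shift is perfectly compensated by random-effect shifts (for
  example intercept vs. mean group effect).  These directions leave the
  likelihood invariant and are the classic slow directions of
  hierarchical-model Gibbs samplers.

Proposal scales adapt by Robbins-Monro during the adaptation and burn-in
phases and are frozen afterwards, so the retained draws come from a fixed
Markov kernel.  Runs are bit-reproducible for a given (seed, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import stats

from .design import ModelArrays
from .likelihood import (
    log_density_longitudinal,
    log_density_survival,
    log_mu_vec,
    log_posterior,
    m_longitudinal,
    m_pseudo,
)
from .params import ParamState, PriorSpec

__all__ = ["McmcConfig", "PosteriorDraws", "InitializationError", "run_mcmc"]


class InitializationError(RuntimeError):
    """The log-posterior is not finite at the initial state."""


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run configuration.

    Defaults follow the reference workflow: three chains, a short
    adaptation phase, 4000 burn-in sweeps, thinning interval 150 and 200
    retained draws per chain.
    """

    chains: int = 3
    adapt: int = 100
    burn_in: int = 4000
    thin: int = 150
    draws_per_chain: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.adapt < 0 or self.burn_in < 0 or self.draws_per_chain < 0:
            raise ValueError("iteration counts must be >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PosteriorDraws:
    """Per-parameter posterior draws indexed (chain, draw).

    ``params`` holds named scalar chains (fixed effects, association,
    variance components and baseline-hazard pieces, plus derived
    variance-scale aliases); ``random_effects`` holds the full random-
    effect draws needed for conditional-deviance DIC; ``deviance`` is
    -2*(longitudinal + survival log-likelihood) at each kept draw.
    """

    names: list[str]
    params: dict[str, np.ndarray]
    random_effects: dict[str, np.ndarray]
    deviance: np.ndarray
    config: McmcConfig
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    @property
    def n_draws(self) -> int:
        return self.deviance.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)


# ---------------------------------------------------------------------------
# workspace of precomputed quantities
# ---------------------------------------------------------------------------

class _Workspace:
    def __init__(self, model: ModelArrays, priors: PriorSpec):
        m = model
        self.model = m
        self.priors = priors
        self.XtX = m.X.T @ m.X
        self.n_l = np.bincount(m.obs_grp, minlength=m.L).astype(float)
        self.Xg = np.zeros((m.L, m.p_beta))
        np.add.at(self.Xg, m.obs_grp, m.X)
        if m.has_u:
            self.ZtZ = np.zeros((m.n, m.p_u, m.p_u))
            np.add.at(
                self.ZtZ, m.obs_sub, m.Z[:, :, None] * m.Z[:, None, :]
            )
        self.d_per_q = np.bincount(m.qidx, weights=m.d, minlength=m.Q)
        # frozen reference means of m(t) per interval for the tilted
        # alpha proposal (set after warm start)
        self.m_ref_q = np.zeros(m.Q)


def _warm_start(model: ModelArrays, priors: PriorSpec) -> ParamState:
    """Two-stage warm start: longitudinal least squares, event-rate hazard."""
    m = model
    XtX = m.X.T @ m.X + 1e-8 * np.eye(m.p_beta)
    beta = np.linalg.solve(XtX, m.X.T @ m.y)
    resid = m.y - m.X @ beta
    var_resid = float(np.var(resid)) if len(resid) > 1 else 1.0
    sigma_eps = math.sqrt(max(0.5 * var_resid, 1e-3))

    Sigma_u = None
    if m.has_u:
        # crude per-subject intercept/slope spread to scale Sigma_u
        u0 = np.zeros(m.n)
        cnt = np.bincount(m.obs_sub, minlength=m.n).astype(float)
        np.add.at(u0, m.obs_sub, resid)
        u0 /= np.maximum(cnt, 1.0)
        diag = [max(float(np.var(u0)), 0.5)]
        if m.p_u == 2:
            tbar = np.zeros(m.n)
            np.add.at(tbar, m.obs_sub, m.Z[:, 1])
            tbar /= np.maximum(cnt, 1.0)
            num = np.zeros(m.n)
            den = np.zeros(m.n)
            tc = m.Z[:, 1] - tbar[m.obs_sub]
            np.add.at(num, m.obs_sub, tc * resid)
            np.add.at(den, m.obs_sub, tc**2)
            slope = np.where(den > 1e-8, num / np.maximum(den, 1e-8), 0.0)
            diag.append(max(float(np.var(slope)), 0.5))
        Sigma_u = np.diag(diag)

    if m.has_survival:
        lam = np.zeros(m.Q)
        for q in range(m.Q):
            mask = m.qidx == q
            lam[q] = (m.d[mask].sum() + 0.5) / (m.expo[mask].sum() + 1.0)
        lam = np.maximum(lam, 1e-6)
    else:
        lam = np.full(m.Q, 0.1)

    return ParamState(
        beta=beta,
        sigma_eps=sigma_eps,
        lam=lam,
        gamma=np.zeros(m.p_gamma),
        alpha=0.0 if m.has_alpha else None,
        Sigma_u=Sigma_u,
        sigma_v=math.sqrt(1.0 / 3.0) if m.has_v else None,
        sigma_g=math.sqrt(1.0 / 3.0) if m.has_g else None,
        u=np.zeros((m.n, m.p_u)) if m.has_u else None,
        v=np.zeros(m.L) if m.has_v else None,
        g=np.zeros(m.L) if m.has_g else None,
    )


def _jitter(state: ParamState, model: ModelArrays, rng: np.random.Generator) -> None:
    state.beta = state.beta + 0.1 * rng.standard_normal(len(state.beta))
    state.sigma_eps *= math.exp(0.05 * rng.standard_normal())
    state.lam = state.lam * np.exp(0.1 * rng.standard_normal(len(state.lam)))
    if model.has_alpha:
        state.alpha += 0.02 * rng.standard_normal()
    if model.p_gamma:
        state.gamma = state.gamma + 0.05 * rng.standard_normal(model.p_gamma)
    if model.has_u:
        state.Sigma_u = state.Sigma_u * math.exp(0.1 * rng.standard_normal())
    if model.has_v:
        state.sigma_v *= math.exp(0.1 * rng.standard_normal())
    if model.has_g:
        state.sigma_g *= math.exp(0.1 * rng.standard_normal())


# ---------------------------------------------------------------------------
# survival helpers
# ---------------------------------------------------------------------------

def _mu_vec(state: ParamState, model: ModelArrays) -> np.ndarray:
    return np.exp(log_mu_vec(state, model))


def _surv_delta(
    model: ModelArrays, mu: np.ndarray, dlogmu: np.ndarray
) -> np.ndarray:
    """Per-record change in the Poisson log-likelihood for a shift in log mu."""
    with np.errstate(over="ignore"):
        return model.d * dlogmu - mu * np.expm1(dlogmu)


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

class _Adapt:
    """Robbins-Monro scale adaptation toward a target acceptance rate."""

    def __init__(self, size, scale=0.1, target=0.44):
        self.log_scale = np.full(size, math.log(scale))
        self.target = target
        self.t = 0
        self.accepted = np.zeros(size)
        self.proposed = np.zeros(size)

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accepted, adapting: bool) -> None:
        acc = np.asarray(accepted, dtype=float)
        self.accepted += acc
        self.proposed += 1.0
        if adapting:
            self.t += 1
            gain = min(0.25, 2.0 * self.t**-0.6)
            self.log_scale += gain * (acc - self.target)

    def rate(self) -> float:
        tot = float(np.sum(self.proposed))
        return float(np.sum(self.accepted)) / tot if tot else math.nan


class _ChainSampler:
    def __init__(
        self,
        ws: _Workspace,
        state: ParamState,
        rng: np.random.Generator,
    ):
        self.ws = ws
        self.m = ws.model
        self.pr = ws.priors
        self.state = state
        self.rng = rng
        m = self.m
        self.ad_alpha = _Adapt(1, scale=0.05) if m.has_alpha else None
        self.ad_gamma = _Adapt(m.p_gamma, scale=0.1) if m.p_gamma else None
        self.ad_g = _Adapt(m.L, scale=0.3) if m.has_g else None
        self.ad_shift = _Adapt(1, scale=0.1) if m.has_g else None
        self.ad_sigeps = (
            _Adapt(1, scale=0.1) if self.pr.sigma_eps_target == "sd" else None
        )
        self.acc_beta = _Adapt(1)  # bookkeeping only (independence proposal)
        self.acc_u = _Adapt(1)

    # -- (beta, v) block --------------------------------------------------

    def update_beta_v(self, adapting: bool) -> None:
        m, st, ws = self.m, self.state, self.ws
        sig2 = st.sigma_eps**2
        r0 = m.y.copy()
        if m.has_u:
            r0 -= np.einsum("ij,ij->i", m.Z, st.u[m.obs_sub])
        pb = m.p_beta
        if m.has_v:
            dim = pb + m.L
            A = np.zeros((dim, dim))
            A[:pb, :pb] = ws.XtX / sig2 + np.eye(pb) / self.pr.beta_variance
            A[:pb, pb:] = ws.Xg.T / sig2
            A[pb:, :pb] = ws.Xg / sig2
            A[pb:, pb:] = np.diag(ws.n_l / sig2 + 1.0 / st.sigma_v**2)
            b = np.empty(dim)
            b[:pb] = m.X.T @ r0 / sig2 + self.pr.beta_mean / self.pr.beta_variance
            gsum = np.zeros(m.L)
            np.add.at(gsum, m.obs_grp, r0)
            b[pb:] = gsum / sig2
        else:
            A = ws.XtX / sig2 + np.eye(pb) / self.pr.beta_variance
            b = m.X.T @ r0 / sig2 + self.pr.beta_mean / self.pr.beta_variance
        chol = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b)
        z = self.rng.standard_normal(len(b))
        prop = mean + np.linalg.solve(chol.T, z)
        beta_new = prop[:pb]
        v_new = prop[pb:] if m.has_v else None

        accept = True
        if m.has_survival and m.has_alpha:
            mu = _mu_vec(st, m)
            dm = m.Xe @ (beta_new - st.beta)
            if m.has_v:
                dm = dm + (v_new - st.v)[m.ps_grp]
            delta = float(np.sum(_surv_delta(m, mu, st.alpha * dm)))
            accept = math.log(self.rng.uniform()) < delta
        if accept:
            st.beta = beta_new
            if m.has_v:
                st.v = v_new
        self.acc_beta.update([float(accept)], False)

    # -- subject random effects -------------------------------------------

    def update_u(self, adapting: bool) -> None:
        m, st, ws = self.m, self.state, self.ws
        if not m.has_u:
            return
        sig2 = st.sigma_eps**2
        r = m.y - m.X @ st.beta
        if m.has_v:
            r = r - st.v[m.obs_grp]
        Sinv = np.linalg.inv(st.Sigma_u)
        P = ws.ZtZ / sig2 + Sinv  # (n, pu, pu)
        b = np.zeros((m.n, m.p_u))
        np.add.at(b, m.obs_sub, m.Z * (r / sig2)[:, None])
        chol = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, b[:, :, None])[:, :, 0]
        z = self.rng.standard_normal((m.n, m.p_u))
        step = np.linalg.solve(np.transpose(chol, (0, 2, 1)), z[:, :, None])[:, :, 0]
        u_new = mean + step

        if m.has_survival and m.has_alpha:
            mu = _mu_vec(st, m)
            du = u_new - st.u
            dm = np.einsum("ij,ij->i", m.Ze, du[m.ps_sub])
            delta_rec = _surv_delta(m, mu, st.alpha * dm)
            delta = np.zeros(m.n)
            np.add.at(delta, m.ps_sub, delta_rec)
            accept = np.log(self.rng.uniform(size=m.n)) < delta
        else:
            accept = np.ones(m.n, dtype=bool)
        st.u = np.where(accept[:, None], u_new, st.u)
        self.acc_u.update([float(np.mean(accept))], False)

    # -- frailties ---------------------------------------------------------

    def update_g(self, adapting: bool) -> None:
        m, st = self.m, self.state
        if not m.has_g:
            return
        if not m.has_survival:
            st.g = st.sigma_g * self.rng.standard_normal(m.L)
            return
        step = self.ad_g.scale * self.rng.standard_normal(m.L)
        mu = _mu_vec(st, m)
        delta_rec = _surv_delta(m, mu, step[m.ps_grp])
        delta = np.zeros(m.L)
        np.add.at(delta, m.ps_grp, delta_rec)
        g_new = st.g + step
        delta += (st.g**2 - g_new**2) / (2.0 * st.sigma_g**2)
        accept = np.log(self.rng.uniform(size=m.L)) < delta
        st.g = np.where(accept, g_new, st.g)
        self.ad_g.update(accept, adapting)

    # -- association -------------------------------------------------------

    def update_alpha(self, adapting: bool) -> None:
        m, st, ws = self.m, self.state, self.ws
        if not (m.has_alpha and m.has_survival):
            return
        dalpha = float(self.ad_alpha.scale[0]) * self.rng.standard_normal()
        # compensate via the log baseline hazard to decorrelate alpha from
        # the hazard level: log lambda_q -> log lambda_q - dalpha * mref_q
        lam_new = st.lam * np.exp(-dalpha * ws.m_ref_q)
        mu = _mu_vec(st, m)
        mps = m_pseudo(st, m)
        dlogmu = dalpha * (mps - ws.m_ref_q[m.qidx])
        delta = float(np.sum(_surv_delta(m, mu, dlogmu)))
        alpha_new = st.alpha + dalpha
        delta += (st.alpha**2 - alpha_new**2) / (2.0 * self.pr.alpha_variance)
        al, bl = self.pr.lambda_gamma
        delta += float(
            np.sum(al * (np.log(lam_new) - np.log(st.lam)) - bl * (lam_new - st.lam))
        )
        accept = math.log(self.rng.uniform()) < delta
        if accept:
            st.alpha = alpha_new
            st.lam = lam_new
        self.ad_alpha.update([float(accept)], adapting)

    # -- survival fixed effects ---------------------------------------------

    def update_gamma(self, adapting: bool) -> None:
        m, st = self.m, self.state
        if not (m.p_gamma and m.has_survival):
            return
        acc = np.zeros(m.p_gamma)
        for s in range(m.p_gamma):
            dg = float(self.ad_gamma.scale[s]) * self.rng.standard_normal()
            mu = _mu_vec(st, m)
            delta = float(np.sum(_surv_delta(m, mu, dg * m.Xs[:, s])))
            gam_new = st.gamma[s] + dg
            delta += (st.gamma[s] ** 2 - gam_new**2) / (
                2.0 * self.pr.gamma_variance
            )
            if math.log(self.rng.uniform()) < delta:
                st.gamma[s] = gam_new
                acc[s] = 1.0
        self.ad_gamma.update(acc, adapting)

    # -- conjugate Gibbs blocks ---------------------------------------------

    def update_lambda(self) -> None:
        m, st, ws = self.m, self.state, self.ws
        al, bl = self.pr.lambda_gamma
        if not m.has_survival:
            st.lam = self.rng.gamma(al, 1.0 / bl, size=m.Q)
            return
        mu = _mu_vec(st, m)
        base = mu / st.lam[m.qidx]
        rate = np.full(m.Q, bl)
        np.add.at(rate, m.qidx, base)
        shape = al + ws.d_per_q
        st.lam = self.rng.gamma(shape, 1.0 / rate)

    def update_sigma_eps(self, adapting: bool) -> None:
        m, st = self.m, self.state
        r = m.y - m_longitudinal(st, m)
        ssr = float(r @ r)
        a, b = self.pr.sigma_eps_ig
        if self.pr.sigma_eps_target == "variance":
            var = 1.0 / self.rng.gamma(a + 0.5 * m.n_obs, 1.0 / (b + 0.5 * ssr))
            st.sigma_eps = math.sqrt(var)
        else:
            # IG prior on the SD: random walk on log sigma
            s = st.sigma_eps
            ds = float(self.ad_sigeps.scale[0]) * self.rng.standard_normal()
            s_new = s * math.exp(ds)
            delta = (
                -m.n_obs * (math.log(s_new) - math.log(s))
                - 0.5 * ssr * (1.0 / s_new**2 - 1.0 / s**2)
                - (a + 1) * (math.log(s_new) - math.log(s))
                - b * (1.0 / s_new - 1.0 / s)
                + ds  # Jacobian of the log transform
            )
            accept = math.log(self.rng.uniform()) < delta
            if accept:
                st.sigma_eps = s_new
            self.ad_sigeps.update([float(accept)], adapting)

    def update_Sigma_u(self) -> None:
        m, st = self.m, self.state
        if not m.has_u:
            return
        Psi, df = self.pr.wishart(m.p_u)
        scale = Psi + st.u.T @ st.u
        st.Sigma_u = stats.invwishart.rvs(
            df=df + m.n, scale=scale, random_state=self.rng
        ).reshape(m.p_u, m.p_u)

    def update_group_variances(self) -> None:
        m, st = self.m, self.state
        Psi, df = self.pr.wishart(1)
        a0, b0 = 0.5 * df, 0.5 * Psi[0, 0]
        if m.has_v:
            var = 1.0 / self.rng.gamma(
                a0 + 0.5 * m.L, 1.0 / (b0 + 0.5 * float(st.v @ st.v))
            )
            st.sigma_v = math.sqrt(var)
        if m.has_g:
            var = 1.0 / self.rng.gamma(
                a0 + 0.5 * m.L, 1.0 / (b0 + 0.5 * float(st.g @ st.g))
            )
            st.sigma_g = math.sqrt(var)

    # -- exact translation moves ---------------------------------------------

    def update_translations(self, adapting: bool) -> None:
        m, st = self.m, self.state
        vb = self.pr.beta_variance
        if m.has_u:
            Sinv = np.linalg.inv(st.Sigma_u)
            for s, c in m.beta_u_translations:
                cS = c @ Sinv  # (n, pu)
                P = float(np.einsum("ij,ij->", cS, c)) + 1.0 / vb
                lin = float(np.einsum("ij,ij->", cS, st.u)) - (
                    st.beta[s] - self.pr.beta_mean
                ) / vb
                delta = lin / P + self.rng.standard_normal() / math.sqrt(P)
                st.beta[s] += delta
                st.u = st.u - delta * c
        if m.has_v:
            for s, w in m.beta_v_translations:
                sv2 = st.sigma_v**2
                P = float(w @ w) / sv2 + 1.0 / vb
                lin = float(w @ st.v) / sv2 - (st.beta[s] - self.pr.beta_mean) / vb
                delta = lin / P + self.rng.standard_normal() / math.sqrt(P)
                st.beta[s] += delta
                st.v = st.v - delta * w
        if m.has_g and m.p_gamma:
            vgam = self.pr.gamma_variance
            for s, w in m.gamma_g_translations:
                sg2 = st.sigma_g**2
                P = float(w @ w) / sg2 + 1.0 / vgam
                lin = float(w @ st.g) / sg2 - st.gamma[s] / vgam
                delta = lin / P + self.rng.standard_normal() / math.sqrt(P)
                st.gamma[s] += delta
                st.g = st.g - delta * w
        # joint shift of log lambda and the frailties (hazard level)
        if m.has_g and m.has_survival:
            c = float(self.ad_shift.scale[0]) * self.rng.standard_normal()
            lam_new = st.lam * math.exp(c)
            g_new = st.g - c
            al, bl = self.pr.lambda_gamma
            delta = float(
                np.sum(al * c - bl * (lam_new - st.lam))
            )
            delta += float(np.sum(st.g**2 - g_new**2)) / (2.0 * st.sigma_g**2)
            accept = math.log(self.rng.uniform()) < delta
            if accept:
                st.lam = lam_new
                st.g = g_new
            self.ad_shift.update([float(accept)], adapting)

    # -- one sweep ------------------------------------------------------------

    def sweep(self, adapting: bool) -> None:
        self.update_beta_v(adapting)
        self.update_u(adapting)
        self.update_translations(adapting)
        self.update_alpha(adapting)
        self.update_gamma(adapting)
        self.update_g(adapting)
        self.update_lambda()
        self.update_sigma_eps(adapting)
        self.update_Sigma_u()
        self.update_group_variances()


# ---------------------------------------------------------------------------
# parameter naming and extraction
# ---------------------------------------------------------------------------

def scalar_param_names(model: ModelArrays) -> list[str]:
    names = [f"beta:{nm}" for nm in model.beta_names]
    names += ["sigma_eps", "var_eps"]
    if model.has_u:
        names += ["var_u0"]
        if model.p_u == 2:
            names += ["var_u1", "cov_u01", "rho_u"]
    if model.has_v:
        names += ["sigma_v", "var_v"]
    names += [f"gamma:{nm}" for nm in model.gamma_names]
    if model.has_alpha:
        names += ["alpha"]
    if model.has_g:
        names += ["sigma_g", "var_g"]
    names += [f"lambda[{q}]" for q in range(1, model.Q + 1)]
    return names


def _extract_scalars(state: ParamState, model: ModelArrays) -> dict[str, float]:
    out = {}
    for k, nm in enumerate(model.beta_names):
        out[f"beta:{nm}"] = float(state.beta[k])
    out["sigma_eps"] = state.sigma_eps
    out["var_eps"] = state.sigma_eps**2
    if model.has_u:
        out["var_u0"] = float(state.Sigma_u[0, 0])
        if model.p_u == 2:
            out["var_u1"] = float(state.Sigma_u[1, 1])
            out["cov_u01"] = float(state.Sigma_u[0, 1])
            denom = math.sqrt(state.Sigma_u[0, 0] * state.Sigma_u[1, 1])
            out["rho_u"] = float(state.Sigma_u[0, 1]) / denom if denom > 0 else 0.0
    if model.has_v:
        out["sigma_v"] = state.sigma_v
        out["var_v"] = state.sigma_v**2
    for k, nm in enumerate(model.gamma_names):
        out[f"gamma:{nm}"] = float(state.gamma[k])
    if model.has_alpha:
        out["alpha"] = state.alpha
    if model.has_g:
        out["sigma_g"] = state.sigma_g
        out["var_g"] = state.sigma_g**2
    for q in range(model.Q):
        out[f"lambda[{q + 1}]"] = float(state.lam[q])
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_mcmc(
    model: ModelArrays,
    priors: PriorSpec,
    config: McmcConfig,
    initial_state: Optional[ParamState] = None,
) -> PosteriorDraws:
    """Sample the joint posterior; bit-reproducible for a given config.

    Raises :class:`InitializationError` if the log-posterior is not finite
    at the (possibly jittered) initial state of any chain.
    """
    m = model
    names = scalar_param_names(m)
    C, D = config.chains, config.draws_per_chain
    params = {nm: np.empty((C, D)) for nm in names}
    re_draws: dict[str, np.ndarray] = {}
    if m.has_u:
        re_draws["u"] = np.empty((C, D, m.n, m.p_u))
    if m.has_v:
        re_draws["v"] = np.empty((C, D, m.L))
    if m.has_g:
        re_draws["g"] = np.empty((C, D, m.L))
    deviance = np.empty((C, D))

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(C)
    acceptance: dict[str, list[float]] = {}

    for c in range(C):
        rng = np.random.default_rng(children[c])
        ws = _Workspace(m, priors)
        state = _warm_start(m, priors) if initial_state is None else initial_state.copy()
        if initial_state is None and C > 1:
            _jitter(state, m, rng)
        lp0 = log_posterior(state, m, priors)
        if not np.isfinite(lp0):
            raise InitializationError(
                f"chain {c}: non-finite log-posterior at initialization "
                f"(lp={lp0}); state summary: beta={state.beta}, "
                f"sigma_eps={state.sigma_eps}, lam={state.lam}"
            )
        if m.has_survival and m.has_alpha:
            mps0 = m_pseudo(state, m)
            for q in range(m.Q):
                sel = m.qidx == q
                ws.m_ref_q[q] = float(mps0[sel].mean()) if sel.any() else 0.0
        sampler = _ChainSampler(ws, state, rng)

        n_adaptive = config.adapt + config.burn_in
        for _ in range(n_adaptive):
            sampler.sweep(adapting=True)
        for k in range(D):
            for _ in range(config.thin):
                sampler.sweep(adapting=False)
            scalars = _extract_scalars(state, m)
            for nm in names:
                params[nm][c, k] = scalars[nm]
            if m.has_u:
                re_draws["u"][c, k] = state.u
            if m.has_v:
                re_draws["v"][c, k] = state.v
            if m.has_g:
                re_draws["g"][c, k] = state.g
            deviance[c, k] = -2.0 * (
                log_density_longitudinal(state, m)
                + log_density_survival(state, m)
            )
        for key, ad in (
            ("beta_v", sampler.acc_beta),
            ("u", sampler.acc_u),
            ("alpha", sampler.ad_alpha),
            ("gamma", sampler.ad_gamma),
            ("g", sampler.ad_g),
            ("lam_g_shift", sampler.ad_shift),
        ):
            if ad is not None:
                acceptance.setdefault(key, []).append(ad.rate())

    return PosteriorDraws(
        names=names,
        params=params,
        random_effects=re_draws,
        deviance=deviance,
        config=config,
        acceptance={
            k: float(np.nanmean(v)) if not np.all(np.isnan(v)) else math.nan
            for k, v in acceptance.items()
        },
    )
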