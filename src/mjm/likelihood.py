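"""Joint log-posterior of the multilevel joint model and its gradient.

The posterior factorizes, conditional on the random effects, into

* the longitudinal normal likelihood at mean m_jl(t) and SD sigma_eps,
* the pseudo-Poisson survival likelihood sum d*log(mu) - mu (the d! term
  vanishes for binary pseudo-outcomes),
* multivariate normal densities of the random effects u ~ N(0, Sigma_u),
  v ~ N(0, sigma_v^2), g ~ N(0, sigma_g^2),
* the priors of PriorSpec.

Scale priors are densities over the *variance* (sigma_eps^2, sigma_v^2,
sigma_g^2, Sigma_u); the state stores standard deviations for readability
but the dominating measure is the variance scale throughout, so the Gibbs
updates in the sampler and these functions agree.

For gradient-based samplers and the finite-difference contract the same
density is exposed on an unconstrained vector: log-variances, log baseline
hazards, and a log-diagonal Cholesky factor for Sigma_u, with the exact
log-Jacobian terms included.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.special import gammaln, multigammaln

from .design import ModelArrays
from .params import ModelSpec, ParamState, PriorSpec

__all__ = [
    "longitudinal_mean",
    "m_longitudinal",
    "m_pseudo",
    "log_mu",
    "log_mu_vec",
    "log_density_longitudinal",
    "log_density_survival",
    "log_density_random_effects",
    "log_prior",
    "log_posterior",
    "UnconstrainedMap",
]

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# means
# ---------------------------------------------------------------------------

def m_longitudinal(state: ParamState, model: ModelArrays) -> np.ndarray:
    """m_jl(t) on every longitudinal row."""
    m = model.X @ state.beta
    if model.has_u:
        m = m + np.einsum("ij,ij->i", model.Z, state.u[model.obs_sub])
    if model.has_v:
        m = m + state.v[model.obs_grp]
    return m


def m_pseudo(state: ParamState, model: ModelArrays) -> np.ndarray:
    """m_jl(eval_time) on every pseudo-Poisson record."""
    m = model.Xe @ state.beta
    if model.has_u:
        m = m + np.einsum("ij,ij->i", model.Ze, state.u[model.ps_sub])
    if model.has_v:
        m = m + state.v[model.ps_grp]
    return m


def longitudinal_mean(
    state: ParamState, model: ModelArrays, subject: int, t: float
) -> float:
    """Model-implied longitudinal mean m_jl(t) for one subject.

    Linear in each of beta, u and v: x(t)'beta + z(t)'u_jl + v_l.
    """
    x, z = model.design_row(subject, t)
    m = float(x @ state.beta)
    if model.has_u:
        m += float(z @ state.u[subject])
    if model.has_v:
        m += float(state.v[model.subject_group[subject]])
    return m


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def log_density_longitudinal(state: ParamState, model: ModelArrays) -> float:
    """Normal log-likelihood of all measurements given the random effects."""
    if state.sigma_eps <= 0:
        raise ValueError("sigma_eps must be > 0")
    r = model.y - m_longitudinal(state, model)
    n = len(r)
    return float(
        -0.5 * n * (LOG2PI + 2.0 * math.log(state.sigma_eps))
        - 0.5 * float(r @ r) / state.sigma_eps**2
    )


def log_mu(
    state: ParamState,
    model: ModelArrays,
    exposure: float,
    q: int,
    m_value: float,
    group: int,
    omega: Optional[np.ndarray] = None,
) -> float:
    """Log-mean of one pseudo-Poisson record.

    log mu = log exposure + log lambda_q + omega'gamma + alpha*m + g_l,
    with ``q`` 1-based as in the interval records.
    """
    if exposure <= 0:
        raise ValueError("exposure must be > 0")
    out = math.log(exposure) + math.log(state.lam[q - 1])
    if model.p_gamma:
        out += float(np.asarray(omega) @ state.gamma)
    if model.has_alpha:
        out += state.alpha * m_value
    if model.has_g:
        out += float(state.g[group])
    return out


def log_mu_vec(
    state: ParamState, model: ModelArrays, m_ps: Optional[np.ndarray] = None
) -> np.ndarray:
    """log mu on every pseudo-record (vectorized)."""
    if m_ps is None and model.has_alpha:
        m_ps = m_pseudo(state, model)
    out = np.log(model.expo) + np.log(state.lam)[model.qidx]
    if model.p_gamma:
        out = out + model.Xs @ state.gamma
    if model.has_alpha:
        out = out + state.alpha * m_ps
    if model.has_g:
        out = out + state.g[model.ps_grp]
    return out


def log_density_survival(
    state: ParamState, model: ModelArrays, m_ps: Optional[np.ndarray] = None
) -> float:
    """Pseudo-Poisson log-likelihood sum(d*log mu - mu)."""
    if not model.has_survival:
        return 0.0
    lmu = log_mu_vec(state, model, m_ps)
    return float(model.d @ lmu - np.exp(lmu).sum())


def log_density_random_effects(state: ParamState, model: ModelArrays) -> float:
    """Log-density of (u, v, g) under their multivariate normal laws."""
    out = 0.0
    if model.has_u:
        p = model.p_u
        Su = state.Sigma_u
        chol = np.linalg.cholesky(Su)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        sol = np.linalg.solve(chol, state.u.T)
        out += float(
            -0.5 * model.n * (p * LOG2PI + logdet) - 0.5 * np.sum(sol**2)
        )
    if model.has_v:
        out += float(
            -0.5 * model.L * (LOG2PI + 2 * math.log(state.sigma_v))
            - 0.5 * float(state.v @ state.v) / state.sigma_v**2
        )
    if model.has_g:
        out += float(
            -0.5 * model.L * (LOG2PI + 2 * math.log(state.sigma_g))
            - 0.5 * float(state.g @ state.g) / state.sigma_g**2
        )
    return out


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def _log_invgamma(x: float, a: float, b: float) -> float:
    return a * math.log(b) - gammaln(a) - (a + 1) * math.log(x) - b / x


def _log_gamma_pdf(x: float, a: float, b: float) -> float:
    return a * math.log(b) - gammaln(a) + (a - 1) * math.log(x) - b * x


def _log_invwishart(S: np.ndarray, Psi: np.ndarray, df: float) -> float:
    p = S.shape[0]
    sign, logdet_S = np.linalg.slogdet(S)
    _, logdet_Psi = np.linalg.slogdet(Psi)
    if sign <= 0:
        return -np.inf
    tr = float(np.trace(np.linalg.solve(S, Psi)))
    return (
        0.5 * df * logdet_Psi
        - 0.5 * df * p * math.log(2.0)
        - multigammaln(0.5 * df, p)
        - 0.5 * (df + p + 1) * logdet_S
        - 0.5 * tr
    )


def log_prior(state: ParamState, model: ModelArrays, priors: PriorSpec) -> float:
    """Sum of component log-priors; -inf outside the support."""
    try:
        state.validate()
    except ValueError:
        return -np.inf
    out = 0.0
    vb = priors.beta_variance
    out += float(
        -0.5 * len(state.beta) * (LOG2PI + math.log(vb))
        - 0.5 * np.sum((state.beta - priors.beta_mean) ** 2) / vb
    )
    a, b = priors.sigma_eps_ig
    if priors.sigma_eps_target == "variance":
        out += _log_invgamma(state.sigma_eps**2, a, b)
    else:
        out += _log_invgamma(state.sigma_eps, a, b)
    al, bl = priors.lambda_gamma
    out += float(sum(_log_gamma_pdf(lq, al, bl) for lq in state.lam))
    if model.p_gamma:
        vg = priors.gamma_variance
        out += float(
            -0.5 * model.p_gamma * (LOG2PI + math.log(vg))
            - 0.5 * np.sum(state.gamma**2) / vg
        )
    if model.has_alpha:
        va = priors.alpha_variance
        out += -0.5 * (LOG2PI + math.log(va)) - 0.5 * state.alpha**2 / va
    if model.has_u:
        Psi, df = priors.wishart(model.p_u)
        out += _log_invwishart(state.Sigma_u, Psi, df)
    if model.has_v:
        # IW(I_1, 1) == IG(1/2, 1/2) on the variance
        Psi, df = priors.wishart(1)
        out += _log_invgamma(state.sigma_v**2, 0.5 * df, 0.5 * Psi[0, 0])
    if model.has_g:
        Psi, df = priors.wishart(1)
        out += _log_invgamma(state.sigma_g**2, 0.5 * df, 0.5 * Psi[0, 0])
    return out


def log_posterior(
    state: ParamState, model: ModelArrays, priors: PriorSpec
) -> float:
    """Unnormalized joint log-posterior over parameters and random effects."""
    lp = log_prior(state, model, priors)
    if not np.isfinite(lp):
        return -np.inf
    return (
        lp
        + log_density_longitudinal(state, model)
        + log_density_survival(state, model)
        + log_density_random_effects(state, model)
    )


# ---------------------------------------------------------------------------
# unconstrained parameterization with analytic gradient
# ---------------------------------------------------------------------------

class UnconstrainedMap:
    """Bijection between a ParamState and an unconstrained vector.

    Layout: beta, phi_eps = log sigma_eps^2, Cholesky of Sigma_u (row by
    row, diagonal entries as logs), phi_v = log sigma_v^2, gamma, alpha,
    phi_g = log sigma_g^2, log lambda_q, u (row-major), v, g.  The density
    on the unconstrained scale includes the log-Jacobians of the variance
    and Cholesky transforms, so it corresponds exactly to the
    variance-scale posterior used by the sampler.
    """

    def __init__(self, model: ModelArrays, priors: PriorSpec):
        self.model = model
        self.priors = priors
        m = model
        self.blocks: list[tuple[str, int]] = [("beta", m.p_beta), ("phi_eps", 1)]
        if m.has_u:
            self.blocks.append(("chol_u", m.p_u * (m.p_u + 1) // 2))
        if m.has_v:
            self.blocks.append(("phi_v", 1))
        if m.p_gamma:
            self.blocks.append(("gamma", m.p_gamma))
        if m.has_alpha:
            self.blocks.append(("alpha", 1))
        if m.has_g:
            self.blocks.append(("phi_g", 1))
        self.blocks.append(("log_lam", m.Q))
        if m.has_u:
            self.blocks.append(("u", m.n * m.p_u))
        if m.has_v:
            self.blocks.append(("v", m.L))
        if m.has_g:
            self.blocks.append(("g", m.L))
        self.size = sum(sz for _, sz in self.blocks)
        self.slices: dict[str, slice] = {}
        off = 0
        for name, sz in self.blocks:
            self.slices[name] = slice(off, off + sz)
            off += sz
        if m.has_u:
            self._tril = np.tril_indices(m.p_u)

    # -- packing ---------------------------------------------------------

    def pack(self, state: ParamState) -> np.ndarray:
        m = self.model
        vec = np.empty(self.size)
        vec[self.slices["beta"]] = state.beta
        vec[self.slices["phi_eps"]] = 2.0 * math.log(state.sigma_eps)
        if m.has_u:
            C = np.linalg.cholesky(state.Sigma_u)
            vals = C[self._tril].copy()
            diag_pos = [k for k, (i, j) in enumerate(zip(*self._tril)) if i == j]
            vals[diag_pos] = np.log(vals[diag_pos])
            vec[self.slices["chol_u"]] = vals
        if m.has_v:
            vec[self.slices["phi_v"]] = 2.0 * math.log(state.sigma_v)
        if m.p_gamma:
            vec[self.slices["gamma"]] = state.gamma
        if m.has_alpha:
            vec[self.slices["alpha"]] = state.alpha
        if m.has_g:
            vec[self.slices["phi_g"]] = 2.0 * math.log(state.sigma_g)
        vec[self.slices["log_lam"]] = np.log(state.lam)
        if m.has_u:
            vec[self.slices["u"]] = state.u.ravel()
        if m.has_v:
            vec[self.slices["v"]] = state.v
        if m.has_g:
            vec[self.slices["g"]] = state.g
        return vec

    def _chol_from_vec(self, vals: np.ndarray) -> np.ndarray:
        p = self.model.p_u
        C = np.zeros((p, p))
        C[self._tril] = vals
        idx = np.arange(p)
        C[idx, idx] = np.exp(np.diag(C))
        return C

    def unpack(self, vec: np.ndarray) -> ParamState:
        m = self.model
        beta = vec[self.slices["beta"]].copy()
        sigma_eps = math.exp(0.5 * float(vec[self.slices["phi_eps"]][0]))
        Sigma_u = None
        if m.has_u:
            C = self._chol_from_vec(vec[self.slices["chol_u"]])
            Sigma_u = C @ C.T
        sigma_v = (
            math.exp(0.5 * float(vec[self.slices["phi_v"]][0])) if m.has_v else None
        )
        gamma = vec[self.slices["gamma"]].copy() if m.p_gamma else np.zeros(0)
        alpha = float(vec[self.slices["alpha"]][0]) if m.has_alpha else None
        sigma_g = (
            math.exp(0.5 * float(vec[self.slices["phi_g"]][0])) if m.has_g else None
        )
        lam = np.exp(vec[self.slices["log_lam"]])
        u = vec[self.slices["u"]].reshape(m.n, m.p_u) if m.has_u else None
        v = vec[self.slices["v"]].copy() if m.has_v else None
        g = vec[self.slices["g"]].copy() if m.has_g else None
        return ParamState(
            beta=beta,
            sigma_eps=sigma_eps,
            lam=lam,
            gamma=gamma,
            alpha=alpha,
            Sigma_u=Sigma_u,
            sigma_v=sigma_v,
            sigma_g=sigma_g,
            u=u,
            v=v,
            g=g,
        )

    # -- density and gradient ---------------------------------------------

    def _log_jacobian(self, vec: np.ndarray) -> float:
        m = self.model
        out = float(vec[self.slices["phi_eps"]][0])  # d sigma^2 = e^phi d phi
        if m.has_v:
            out += float(vec[self.slices["phi_v"]][0])
        if m.has_g:
            out += float(vec[self.slices["phi_g"]][0])
        out += float(np.sum(vec[self.slices["log_lam"]]))
        if m.has_u:
            # Sigma = C C' with log-diagonal Cholesky coordinates eta_i:
            # |J| = 2^p * prod_i C_ii^(p - i + 1) * prod_i C_ii
            p = m.p_u
            vals = vec[self.slices["chol_u"]]
            diag_eta = [
                vals[k] for k, (i, j) in enumerate(zip(*self._tril)) if i == j
            ]
            out += p * math.log(2.0) + sum(
                (p - i + 1.0) * eta for i, eta in enumerate(diag_eta)
            )
        return out

    def log_posterior(self, vec: np.ndarray) -> float:
        state = self.unpack(vec)
        return log_posterior(state, self.model, self.priors) + self._log_jacobian(vec)

    def grad_log_posterior(self, vec: np.ndarray) -> np.ndarray:
        """Analytic gradient of :meth:`log_posterior`."""
        m = self.model
        pr = self.priors
        state = self.unpack(vec)
        grad = np.zeros(self.size)

        sig2 = state.sigma_eps**2
        r = m.y - m_longitudinal(state, m)
        # longitudinal likelihood
        g_beta = m.X.T @ r / sig2
        g_phi_eps = -0.5 * m.n_obs + 0.5 * float(r @ r) / sig2
        g_u = np.zeros((m.n, m.p_u)) if m.has_u else None
        if m.has_u:
            np.add.at(g_u, m.obs_sub, m.Z * (r / sig2)[:, None])
        g_v = np.zeros(m.L) if m.has_v else None
        if m.has_v:
            np.add.at(g_v, m.obs_grp, r / sig2)

        # survival likelihood
        g_gamma = np.zeros(m.p_gamma)
        g_alpha = 0.0
        g_g = np.zeros(m.L) if m.has_g else None
        g_loglam = np.zeros(m.Q)
        if m.has_survival:
            m_ps = m_pseudo(state, m) if m.has_alpha else None
            w = m.d - np.exp(log_mu_vec(state, m, m_ps))
            np.add.at(g_loglam, m.qidx, w)
            if m.p_gamma:
                g_gamma += m.Xs.T @ w
            if m.has_alpha:
                g_alpha += float(w @ m_ps)
                aw = state.alpha * w
                g_beta += m.Xe.T @ aw
                if m.has_u:
                    np.add.at(g_u, m.ps_sub, m.Ze * aw[:, None])
                if m.has_v:
                    np.add.at(g_v, m.ps_grp, aw)
            if m.has_g:
                np.add.at(g_g, m.ps_grp, w)

        # random-effect densities
        g_chol = None
        if m.has_u:
            Sinv = np.linalg.inv(state.Sigma_u)
            g_u -= state.u @ Sinv
            S = state.u.T @ state.u
            G = -0.5 * m.n * Sinv + 0.5 * Sinv @ S @ Sinv
            # prior IW(Psi, df) contribution
            Psi, df = pr.wishart(m.p_u)
            G += -0.5 * (df + m.p_u + 1) * Sinv + 0.5 * Sinv @ Psi @ Sinv
            C = self._chol_from_vec(vec[self.slices["chol_u"]])
            GL = 2.0 * G @ C
            g_chol = GL[self._tril].copy()
            # chain rule for log-diagonal coords and Jacobian term
            p = m.p_u
            k_diag = [k for k, (i, j) in enumerate(zip(*self._tril)) if i == j]
            for i, k in enumerate(k_diag):
                g_chol[k] *= C[i, i]
                g_chol[k] += p - i + 1.0  # d/d eta_i of the log-Jacobian
        g_phi_v = 0.0
        if m.has_v:
            sv2 = state.sigma_v**2
            g_v -= state.v / sv2
            g_phi_v = -0.5 * m.L + 0.5 * float(state.v @ state.v) / sv2
            Psi, df = pr.wishart(1)
            a_v, b_v = 0.5 * df, 0.5 * Psi[0, 0]
            g_phi_v += -a_v + b_v / sv2  # IG prior + Jacobian
        g_phi_g = 0.0
        if m.has_g:
            sg2 = state.sigma_g**2
            g_g -= state.g / sg2
            g_phi_g = -0.5 * m.L + 0.5 * float(state.g @ state.g) / sg2
            Psi, df = pr.wishart(1)
            a_g, b_g = 0.5 * df, 0.5 * Psi[0, 0]
            g_phi_g += -a_g + b_g / sg2

        # priors on location parameters
        g_beta -= (state.beta - pr.beta_mean) / pr.beta_variance
        if m.p_gamma:
            g_gamma -= state.gamma / pr.gamma_variance
        if m.has_alpha:
            g_alpha -= state.alpha / pr.alpha_variance
        a, b = pr.sigma_eps_ig
        if pr.sigma_eps_target == "variance":
            g_phi_eps += -a + b / sig2  # IG on variance + Jacobian
        else:
            # IG on the SD: log p(sigma) + Jacobian d sigma^2/d phi
            # contributes (-(a+1)/2 - b/(2 sigma) ... ) via sigma = e^(phi/2)
            g_phi_eps += -0.5 * (a + 1) + 0.5 * b / state.sigma_eps + 1.0
        al, bl = pr.lambda_gamma
        g_loglam += al - bl * state.lam  # Gamma prior + Jacobian

        grad[self.slices["beta"]] = g_beta
        grad[self.slices["phi_eps"]] = g_phi_eps
        if m.has_u:
            grad[self.slices["chol_u"]] = g_chol
            grad[self.slices["u"]] = g_u.ravel()
        if m.has_v:
            grad[self.slices["phi_v"]] = g_phi_v
            grad[self.slices["v"]] = g_v
        if m.p_gamma:
            grad[self.slices["gamma"]] = g_gamma
        if m.has_alpha:
            grad[self.slices["alpha"]] = g_alpha
        if m.has_g:
            grad[self.slices["phi_g"]] = g_phi_g
            grad[self.slices["g"]] = g_g
        grad[self.slices["log_lam"]] = g_loglam
        return grad
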