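"""Model specification, priors and the explicit parameter state.

The joint model couples a three-level linear mixed model for the
longitudinal outcome,

    y_jl(t) = m_jl(t) + eps,   m_jl(t) = x(t)'beta + z(t)'u_jl + v_l,

with a piecewise-constant proportional-hazards survival submodel expressed
as an auxiliary mixed-effect Poisson regression on interval pseudo-records,

    log mu_jlq = log t_jlq + log lambda_q + omega'gamma + alpha*m(t) + g_l.

``ModelSpec`` fixes the structural choices (trajectory shape, random-effect
structure at each level, covariate sets, interval count, and whether the
group level is modelled at all); ``PriorSpec`` holds the weakly-informative
prior hyperparameters; ``ParamState`` is the full parameter vector
Theta = (beta, sigma_eps, Sigma_u, sigma_v, gamma, alpha, sigma_g, lambda)
together with the random effects (u, v, g).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

__all__ = ["ModelSpec", "PriorSpec", "ParamState", "SpecError"]

TRAJECTORIES = ("linear", "quadratic_shared_curvature", "quadratic_full")
SUBJECT_RANDOM = ("none", "intercept_only", "intercept_slope")
GROUP_RANDOM = ("none", "intercept")
ASSOCIATIONS = ("none", "current_value")


class SpecError(ValueError):
    """Inconsistent or unsupported model specification."""


@dataclass(frozen=True)
class ModelSpec:
    """Structural specification of a (multilevel) joint model.

    ``multilevel=False`` yields the standard two-level joint model that
    ignores the group level: both group-level random-effect blocks are
    forced to ``none``.  ``association='none'`` (no current-value term) and
    ``subject_random='none'`` are degenerate configurations kept for
    conjugate diagnostics and warm starts; every substantive fit uses the
    current-value association.

    Covariate terms are names referring to time-fixed subject- or
    group-level columns, optionally interacted with time:
    ``"treatment"``, ``"treatment:time"``, ``"treatment:time2"``.
    """

    trajectory: str = "linear"
    subject_random: str = "intercept_slope"
    group_random_longitudinal: str = "intercept"
    group_random_survival: str = "intercept"
    fixed_covariates_long: tuple[str, ...] = ("treatment", "treatment:time")
    fixed_covariates_surv: tuple[str, ...] = ()
    association: str = "current_value"
    Q: int = 3
    multilevel: bool = True
    include_survival: bool = True

    def __post_init__(self):
        object.__setattr__(
            self, "fixed_covariates_long", tuple(self.fixed_covariates_long)
        )
        object.__setattr__(
            self, "fixed_covariates_surv", tuple(self.fixed_covariates_surv)
        )
        if self.trajectory not in TRAJECTORIES:
            raise SpecError(f"unknown trajectory {self.trajectory!r}")
        if self.subject_random not in SUBJECT_RANDOM:
            raise SpecError(f"unknown subject_random {self.subject_random!r}")
        for fld in ("group_random_longitudinal", "group_random_survival"):
            if getattr(self, fld) not in GROUP_RANDOM:
                raise SpecError(f"unknown {fld} {getattr(self, fld)!r}")
        if self.association not in ASSOCIATIONS:
            raise SpecError(
                f"association {self.association!r} unsupported; only the "
                "current-value form alpha*m(t) is implemented"
            )
        if self.Q < 1:
            raise SpecError("Q must be >= 1")
        if not self.multilevel:
            object.__setattr__(self, "group_random_longitudinal", "none")
            object.__setattr__(self, "group_random_survival", "none")
        if self.trajectory == "linear":
            bad = [t for t in self.fixed_covariates_long if t.endswith(":time2")]
            if bad:
                raise SpecError(f"time2 interactions {bad} need a quadratic trajectory")
        if self.trajectory == "quadratic_shared_curvature":
            bad = [t for t in self.fixed_covariates_long if t.endswith(":time2")]
            if bad:
                raise SpecError(
                    f"{bad}: curvature is shared across arms in this trajectory; "
                    "use trajectory='quadratic_full'"
                )

    # -- the reference-analysis and simulation-study specifications ------

    @classmethod
    def mjm(cls, variant: int = 1, Q: int = 3, **kw) -> "ModelSpec":
        """The three multilevel JM variants fitted to the trial data.

        1. linear trajectory, subject random intercept + slope;
        2. quadratic trajectory (treatment shifts the linear slope only),
           subject random intercept;
        3. quadratic trajectory with treatment-specific curvature, subject
           random intercept.
        """
        common = dict(
            group_random_longitudinal="intercept",
            group_random_survival="intercept",
            fixed_covariates_surv=("treatment",),
            association="current_value",
            Q=Q,
            multilevel=True,
        )
        common.update(kw)
        if variant == 1:
            return cls(
                trajectory="linear",
                subject_random="intercept_slope",
                fixed_covariates_long=("treatment", "treatment:time"),
                **common,
            )
        if variant == 2:
            return cls(
                trajectory="quadratic_shared_curvature",
                subject_random="intercept_only",
                fixed_covariates_long=("treatment", "treatment:time"),
                **common,
            )
        if variant == 3:
            return cls(
                trajectory="quadratic_full",
                subject_random="intercept_only",
                fixed_covariates_long=(
                    "treatment",
                    "treatment:time",
                    "treatment:time2",
                ),
                **common,
            )
        raise SpecError("variant must be 1, 2 or 3")

    @classmethod
    def simulation_mjm(cls, Q: int = 3) -> "ModelSpec":
        """Model 1 of the simulation study: three-level joint model.

        Linear trajectory, random intercept and slope at the subject
        level, random intercepts at the group level in both submodels, no
        direct fixed effect in the survival submodel (the treatment acts
        on the hazard only through the current value of the trajectory).
        """
        return cls(
            trajectory="linear",
            subject_random="intercept_slope",
            group_random_longitudinal="intercept",
            group_random_survival="intercept",
            fixed_covariates_long=("treatment", "treatment:time"),
            fixed_covariates_surv=(),
            association="current_value",
            Q=Q,
            multilevel=True,
        )

    @classmethod
    def simulation_jm(cls, Q: int = 3) -> "ModelSpec":
        """Model 2 of the simulation study: two-level JM ignoring groups."""
        return replace(cls.simulation_mjm(Q=Q), multilevel=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fixed_covariates_long"] = list(self.fixed_covariates_long)
        d["fixed_covariates_surv"] = list(self.fixed_covariates_surv)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative priors.

    Normal priors written with precision 0.001 correspond to variance
    1000.  The inverse-gamma prior on the residual noise targets the
    *variance* sigma_eps^2 by default (equivalently a gamma prior on the
    precision, the common BUGS/JAGS convention); set
    ``sigma_eps_target='sd'`` to place it on the standard deviation
    instead.  Scalar inverse-Wishart(I_1x1, 1) priors on the group-level
    covariances reduce exactly to inverse-gamma(1/2, 1/2) on the variance
    and are implemented through that reduction.
    """

    beta_mean: float = 0.0
    beta_variance: float = 1000.0
    sigma_eps_ig: tuple[float, float] = (0.01, 0.01)
    sigma_eps_target: str = "variance"
    lambda_gamma: tuple[float, float] = (0.01, 0.01)
    gamma_variance: float = 1000.0
    alpha_variance: float = 1000.0
    # inverse-Wishart(scale * I_p, df_offset + p) for each random-effect
    # covariance block; the defaults give IW(I_p, p).
    wishart_identity_scale: float = 1.0
    wishart_df_offset: float = 0.0

    def __post_init__(self):
        for name, val in (
            ("beta_variance", self.beta_variance),
            ("gamma_variance", self.gamma_variance),
            ("alpha_variance", self.alpha_variance),
            ("wishart_identity_scale", self.wishart_identity_scale),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be > 0")
        for name, pair in (
            ("sigma_eps_ig", self.sigma_eps_ig),
            ("lambda_gamma", self.lambda_gamma),
        ):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ValueError(f"{name} hyperparameters must be > 0")
        if self.sigma_eps_target not in ("variance", "sd"):
            raise ValueError("sigma_eps_target must be 'variance' or 'sd'")
        object.__setattr__(self, "sigma_eps_ig", tuple(self.sigma_eps_ig))
        object.__setattr__(self, "lambda_gamma", tuple(self.lambda_gamma))

    def wishart(self, p: int) -> tuple[np.ndarray, float]:
        """(scale matrix, df) of the IW prior for a p-dim covariance."""
        return self.wishart_identity_scale * np.eye(p), self.wishart_df_offset + p

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sigma_eps_ig"] = list(self.sigma_eps_ig)
        d["lambda_gamma"] = list(self.lambda_gamma)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**d)


@dataclass
class ParamState:
    """Full parameter vector plus random effects.

    Arrays are sized by the model design: ``beta`` (p_beta,), ``Sigma_u``
    (p_u, p_u), ``gamma`` (p_gamma,), ``lam`` (Q,), ``u`` (n, p_u), ``v``
    and ``g`` (L,).  Blocks absent from the specification are ``None``
    (or empty arrays for ``gamma``/``u``).  Scale parameters are stored
    as standard deviations; priors on them are defined on the variance
    scale (see :class:`PriorSpec`).
    """

    beta: np.ndarray
    sigma_eps: float
    lam: np.ndarray
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    alpha: Optional[float] = None
    Sigma_u: Optional[np.ndarray] = None
    sigma_v: Optional[float] = None
    sigma_g: Optional[float] = None
    u: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    g: Optional[np.ndarray] = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.Sigma_u is not None:
            self.Sigma_u = np.asarray(self.Sigma_u, dtype=float)
        for arr in ("u", "v", "g"):
            val = getattr(self, arr)
            if val is not None:
                setattr(self, arr, np.asarray(val, dtype=float))

    def validate(self) -> None:
        """Raise if the state is outside the parameter support."""
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be > 0")
        if np.any(self.lam <= 0):
            raise ValueError("baseline hazard pieces must be > 0")
        for name in ("sigma_v", "sigma_g"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.Sigma_u is not None:
            if not np.allclose(self.Sigma_u, self.Sigma_u.T):
                raise ValueError("Sigma_u must be symmetric")
            if np.any(np.linalg.eigvalsh(self.Sigma_u) <= 0):
                raise ValueError("Sigma_u must be positive definite")

    def copy(self) -> "ParamState":
        return ParamState(
            beta=self.beta.copy(),
            sigma_eps=self.sigma_eps,
            lam=self.lam.copy(),
            gamma=self.gamma.copy(),
            alpha=self.alpha,
            Sigma_u=None if self.Sigma_u is None else self.Sigma_u.copy(),
            sigma_v=self.sigma_v,
            sigma_g=self.sigma_g,
            u=None if self.u is None else self.u.copy(),
            v=None if self.v is None else self.v.copy(),
            g=None if self.g is None else self.g.copy(),
        )
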