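"""Assembly of dense model arrays from a trial dataset and a model spec.

Everything the likelihood and the sampler need is precomputed here: the
longitudinal design (X, Z), the pseudo-Poisson records with their survival
design and the design rows of the current value m(eval_time), and the
"translation" directions along which a shift of a fixed effect can be
exactly compensated by shifting random effects (used by the sampler to mix
the weakly identified location directions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import TrialDataset
from .intervals import IntervalGrid, equal_length_grid, split_dataset
from .params import ModelSpec, SpecError

__all__ = ["ModelArrays", "build_arrays"]


def _term_parts(term: str) -> tuple[str, int]:
    """Split a covariate term 'name[:time|:time2]' into (name, time power)."""
    if term.endswith(":time2"):
        return term[: -len(":time2")], 2
    if term.endswith(":time"):
        return term[: -len(":time")], 1
    return term, 0


@dataclass
class ModelArrays:
    """Dense arrays for one model/dataset pair.

    Longitudinal rows are sorted by (subject, time); pseudo-records by
    (subject, q).  ``long_terms`` lists the beta columns as (covariate
    name or None for the base time polynomial, time power).
    """

    spec: ModelSpec
    grid: IntervalGrid
    eval_rule: str
    n: int
    L: int
    # longitudinal part
    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    obs_sub: np.ndarray
    obs_grp: np.ndarray
    # pseudo-Poisson part
    d: np.ndarray
    expo: np.ndarray
    qidx: np.ndarray  # 0-based interval index
    Xs: np.ndarray
    Xe: np.ndarray
    Ze: np.ndarray
    ps_sub: np.ndarray
    ps_grp: np.ndarray
    # design description
    beta_names: list[str]
    gamma_names: list[str]
    long_terms: list[tuple[Optional[str], int]]
    subject_covariates: dict[str, np.ndarray]
    subject_group: np.ndarray
    subject_ids: list[str]
    group_ids: list[str]
    # exact-compensation directions for the sampler
    beta_u_translations: list[tuple[int, np.ndarray]] = field(default_factory=list)
    beta_v_translations: list[tuple[int, np.ndarray]] = field(default_factory=list)
    gamma_g_translations: list[tuple[int, np.ndarray]] = field(default_factory=list)

    @property
    def p_beta(self) -> int:
        return self.X.shape[1]

    @property
    def p_u(self) -> int:
        return self.Z.shape[1]

    @property
    def p_gamma(self) -> int:
        return self.Xs.shape[1]

    @property
    def Q(self) -> int:
        return self.grid.Q

    @property
    def has_u(self) -> bool:
        return self.p_u > 0

    @property
    def has_v(self) -> bool:
        return self.spec.group_random_longitudinal == "intercept"

    @property
    def has_g(self) -> bool:
        return self.spec.group_random_survival == "intercept"

    @property
    def has_alpha(self) -> bool:
        return self.spec.association == "current_value"

    @property
    def has_survival(self) -> bool:
        return self.spec.include_survival and len(self.d) > 0

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_events(self) -> int:
        return int(self.d.sum())

    def design_row(self, subject: int, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(x, z) design rows of m_jl(t) for one subject at time t."""
        x = np.empty(self.p_beta)
        for k, (name, power) in enumerate(self.long_terms):
            base = 1.0 if name is None else self.subject_covariates[name][subject]
            x[k] = base * t**power
        z = np.array([t**p for p in range(self.p_u)])
        return x, z


def _subject_covariate(
    data: TrialDataset, name: str
) -> np.ndarray:
    """Resolve a time-fixed covariate to one value per subject."""
    if name in data.survival_covariates():
        surv = data.survival.set_index("subject_id")
        return np.array(
            [float(surv.loc[s, name]) for s in data.subject_ids], dtype=float
        )
    if name in data.groups.covariate_names:
        col = data.groups.frame.set_index("group_id")[name]
        return np.array(
            [float(col[data.group_ids[data.subject_group[j]]])
             for j in range(data.n_subjects)],
            dtype=float,
        )
    raise SpecError(
        f"unknown covariate {name!r}: not a survival-table or group-table column"
    )


def build_arrays(
    data: TrialDataset,
    spec: ModelSpec,
    grid: IntervalGrid | None = None,
    eval_rule: str = "interval_start",
) -> ModelArrays:
    """Build all model arrays for a dataset under a specification.

    If no interval grid is given, an equal-length grid over
    [0, max observed time] with ``spec.Q`` intervals is used.
    """
    if grid is None:
        grid = equal_length_grid(float(data.survival["observed_time"].max()), spec.Q)
    elif grid.Q != spec.Q:
        raise SpecError(f"grid has {grid.Q} intervals but spec.Q = {spec.Q}")

    n, L = data.n_subjects, data.n_groups

    # beta columns: base time polynomial then covariate terms
    long_terms: list[tuple[Optional[str], int]] = [(None, 0), (None, 1)]
    if spec.trajectory != "linear":
        long_terms.append((None, 2))
    for term in spec.fixed_covariates_long:
        long_terms.append(_term_parts(term))
    beta_names = []
    for name, power in long_terms:
        base = "Intercept" if name is None else name
        if name is None:
            beta_names.append({0: "Intercept", 1: "time", 2: "time2"}[power])
        else:
            beta_names.append(base + {0: "", 1: ":time", 2: ":time2"}[power])

    subject_covariates = {
        name: _subject_covariate(data, name)
        for name in {nm for nm, _ in long_terms if nm is not None}
        | set(spec.fixed_covariates_surv)
    }

    p_u = {"none": 0, "intercept_only": 1, "intercept_slope": 2}[spec.subject_random]

    long = data.longitudinal.sort_values(["subject_id", "time"], kind="stable")
    obs_sub = np.array([data.subject_index[s] for s in long["subject_id"]], dtype=np.intp)
    order = np.argsort(obs_sub, kind="stable")
    long = long.iloc[order]
    obs_sub = obs_sub[order]
    obs_grp = data.subject_group[obs_sub]
    t_obs = long["time"].to_numpy(dtype=float)
    y = long["y"].to_numpy(dtype=float)

    def design(t: np.ndarray, sub: np.ndarray) -> np.ndarray:
        cols = []
        for name, power in long_terms:
            base = 1.0 if name is None else subject_covariates[name][sub]
            cols.append(base * t**power)
        return np.column_stack(cols)

    X = design(t_obs, obs_sub)
    Z = np.column_stack([t_obs**p for p in range(p_u)]) if p_u else np.zeros((len(y), 0))

    # pseudo-Poisson records
    if spec.include_survival:
        records = split_dataset(data, grid, eval_rule)
        ps_sub = np.array([data.subject_index[r.subject_id] for r in records], dtype=np.intp)
        ps_grp = data.subject_group[ps_sub]
        d = np.array([r.d for r in records], dtype=float)
        expo = np.array([r.exposure for r in records], dtype=float)
        qidx = np.array([r.q - 1 for r in records], dtype=np.intp)
        t_eval = np.array([r.eval_time for r in records], dtype=float)
        Xe = design(t_eval, ps_sub)
        Ze = (
            np.column_stack([t_eval**p for p in range(p_u)])
            if p_u
            else np.zeros((len(records), 0))
        )
        if spec.fixed_covariates_surv:
            Xs = np.column_stack(
                [subject_covariates[nm][ps_sub] for nm in spec.fixed_covariates_surv]
            )
        else:
            Xs = np.zeros((len(records), 0))
    else:
        ps_sub = np.zeros(0, dtype=np.intp)
        ps_grp = np.zeros(0, dtype=np.intp)
        d = expo = np.zeros(0)
        qidx = np.zeros(0, dtype=np.intp)
        Xe = np.zeros((0, len(long_terms)))
        Ze = np.zeros((0, p_u))
        Xs = np.zeros((0, len(spec.fixed_covariates_surv)))

    arrays = ModelArrays(
        spec=spec,
        grid=grid,
        eval_rule=eval_rule,
        n=n,
        L=L,
        y=y,
        X=X,
        Z=Z,
        obs_sub=obs_sub,
        obs_grp=obs_grp,
        d=d,
        expo=expo,
        qidx=qidx,
        Xs=Xs,
        Xe=Xe,
        Ze=Ze,
        ps_sub=ps_sub,
        ps_grp=ps_grp,
        beta_names=beta_names,
        gamma_names=list(spec.fixed_covariates_surv),
        long_terms=long_terms,
        subject_covariates=subject_covariates,
        subject_group=data.subject_group.copy(),
        subject_ids=list(data.subject_ids),
        group_ids=list(data.group_ids),
    )
    _find_translations(arrays)
    return arrays


def _find_translations(m: ModelArrays) -> None:
    """Detect fixed-effect columns whose shift is exactly compensable.

    A shift beta_s -> beta_s + delta leaves every value of m_jl(t)
    unchanged if u_j -> u_j - delta*c_j with a per-subject constant c_j
    satisfying X[:, s] = Z @ c_j on all longitudinal and eval rows of
    subject j.  With the polynomial designs used here, c_j is the
    covariate value placed on the matching time power.  Analogously a
    group-constant column can be absorbed by the group intercepts v (and
    a group-constant survival covariate by the frailties g).
    """
    # beta <-> u: term (name, power) compensable when power < p_u
    if m.has_u:
        for s, (name, power) in enumerate(m.long_terms):
            if power >= m.p_u:
                continue
            c = np.zeros((m.n, m.p_u))
            c[:, power] = 1.0 if name is None else m.subject_covariates[name]
            m.beta_u_translations.append((s, c))
    # beta <-> v: intercept-power terms whose covariate is group-constant
    if m.has_v:
        for s, (name, power) in enumerate(m.long_terms):
            if power != 0:
                continue
            if name is None:
                w = np.ones(m.L)
            else:
                vals = m.subject_covariates[name]
                w = np.full(m.L, np.nan)
                for j in range(m.n):
                    l = m.subject_group[j]
                    if np.isnan(w[l]):
                        w[l] = vals[j]
                    elif w[l] != vals[j]:
                        w[:] = np.nan
                        break
                if np.isnan(w).any():
                    continue
            m.beta_v_translations.append((s, w))
    # gamma <-> g: group-constant survival covariates
    if m.has_g and m.p_gamma:
        for s, name in enumerate(m.gamma_names):
            vals = m.subject_covariates[name]
            w = np.full(m.L, np.nan)
            ok = True
            for j in range(m.n):
                l = m.subject_group[j]
                if np.isnan(w[l]):
                    w[l] = vals[j]
                elif w[l] != vals[j]:
                    ok = False
                    break
            if ok and not np.isnan(w).any():
                m.gamma_g_translations.append((s, w))
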