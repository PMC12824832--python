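"""Simulation-study orchestration: scenario grid, replicates, metrics.

The full design crosses 2 censoring rates x 3 group counts x 1 group size
x 2 group-level longitudinal variances x 2 frailty variances x 3 interval
counts = 72 scenarios, each intended for hundreds of replicates on a
cluster.  A desk-scale preset (30 groups of 15, Q = 3, short chains) runs
the same machinery at laptop scale for tests and acceptance checks.

Per replicate, the three-level multilevel joint model (MJM) and optionally
the two-level joint model that ignores the group structure (JM) are fitted
to the *same* generated dataset, so model comparisons are paired.
Estimator performance is summarized per parameter by the mean estimate,
bias, relative bias, the mean estimated standard error (MESE: average
posterior SD across replicates) and the empirical standard error (ESE: SD
of the posterior means across replicates), over converged replicates only.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .diagnostics import PosteriorSummary
from .intervals import equal_length_grid
from .model import MJMResults, MultilevelJointModel
from .params import ModelSpec
from .sampler import McmcConfig
from .simulate import ScenarioConfig, TrueParams, generate_dataset

__all__ = [
    "MetricsRow",
    "ComparisonRow",
    "ReplicateFit",
    "scenario_grid",
    "desk_scenario",
    "desk_mcmc",
    "run_replicate",
    "metrics",
    "metrics_frame",
    "compare_models",
    "run_study",
    "truth_values",
]

#: parameters tracked in the study reports, mapped to generating values
def truth_values(truths: TrueParams, multilevel: bool = True) -> dict[str, float]:
    vals = {
        "beta:Intercept": truths.beta000,
        "beta:time": truths.beta100,
        "beta:treatment": truths.beta001,
        "beta:treatment:time": truths.beta101,
        "alpha": truths.alpha,
        "var_u0": truths.var_u0,
        "var_u1": truths.var_u1,
        "cov_u01": truths.rho_u * math.sqrt(truths.var_u0 * truths.var_u1),
        "var_eps": truths.var_eps,
    }
    if multilevel:
        vals["var_v"] = truths.var_v
        vals["var_g"] = truths.var_g
    return vals


@dataclass
class MetricsRow:
    """Estimator performance for one parameter over converged replicates."""

    parameter: str
    true: float
    mean_est: float
    bias: float
    relative_bias: Optional[float]
    mese: float
    ese: float
    n_replicates: int
    n_converged: int


@dataclass
class ComparisonRow:
    """Paired MJM-vs-JM performance for one parameter on shared data."""

    parameter: str
    mjm: MetricsRow
    jm: MetricsRow
    delta_relative_bias: Optional[float]


@dataclass
class ReplicateFit:
    """One model fit within one replicate."""

    scenario_id: str
    replicate: int
    model: str  # "mjm" or "jm"
    summary: Optional[PosteriorSummary]
    converged: bool
    seconds: float
    error: Optional[str] = None


def scenario_grid(base_seed: int = 0) -> list[ScenarioConfig]:
    """The fully crossed 72-cell design, in deterministic order."""
    grid = []
    idx = 0
    for censoring in (0.2, 0.6):
        for L in (50, 100, 200):
            for group_size in (30,):
                for var_v in (5.0, 18.0):
                    for var_g in (0.4, 1.0):
                        for Q in (11, 7, 3):
                            grid.append(
                                ScenarioConfig(
                                    censoring_target=censoring,
                                    L=L,
                                    group_size=group_size,
                                    var_v=var_v,
                                    var_g=var_g,
                                    Q=Q,
                                    seed=base_seed + idx,
                                )
                            )
                            idx += 1
    return grid


def desk_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """Desk-scale preset: 30 groups of 15, Q = 3, 20% censoring."""
    kw = dict(
        censoring_target=0.2, L=30, group_size=15, var_v=5.0, var_g=0.4,
        Q=3, seed=seed,
    )
    kw.update(overrides)
    return ScenarioConfig(**kw)


def desk_mcmc(seed: int = 0, **overrides) -> McmcConfig:
    """Short-chain configuration for desk-scale runs."""
    kw = dict(chains=3, adapt=100, burn_in=600, thin=6, draws_per_chain=180,
              seed=seed)
    kw.update(overrides)
    return McmcConfig(**kw)


def _replicate_seed(scenario_seed: int, replicate_index: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence([scenario_seed, replicate_index, salt])
    return int(ss.generate_state(1)[0] % (2**31))


def fit_scenario_model(
    data, scenario: ScenarioConfig, which: str, mcmc: McmcConfig
) -> MJMResults:
    """Fit the three-level MJM (Model 1) or the two-level JM (Model 2)."""
    spec = (
        ModelSpec.simulation_mjm(Q=scenario.Q)
        if which == "mjm"
        else ModelSpec.simulation_jm(Q=scenario.Q)
    )
    grid = equal_length_grid(scenario.survival_follow_up, scenario.Q)
    model = MultilevelJointModel(data, spec, grid=grid)
    return model.fit(mcmc)


def run_replicate(
    scenario: ScenarioConfig,
    replicate_index: int,
    fit_both: bool = False,
    mcmc: Optional[McmcConfig] = None,
    log: Optional[Callable[[str], None]] = None,
) -> dict[str, ReplicateFit]:
    """Generate one replicate dataset and fit the model(s) on it.

    The replicate dataset is drawn from a substream derived from
    (scenario seed, replicate index); the MJM and JM always see the
    identical dataset.  Sampler failures are recorded and the replicate
    is marked non-converged rather than aborting the study.
    """
    mcmc = mcmc if mcmc is not None else desk_mcmc()
    rep_scenario = replace(
        scenario, seed=_replicate_seed(scenario.seed, replicate_index)
    )
    data, _ = generate_dataset(rep_scenario)
    out: dict[str, ReplicateFit] = {}
    models = ("mjm", "jm") if fit_both else ("mjm",)
    for which in models:
        chain_cfg = replace(
            mcmc, seed=_replicate_seed(mcmc.seed, replicate_index,
                                       salt=1 if which == "mjm" else 2)
        )
        t0 = time.perf_counter()
        try:
            res = fit_scenario_model(data, scenario, which, chain_cfg)
            fit = ReplicateFit(
                scenario_id=scenario.scenario_id,
                replicate=replicate_index,
                model=which,
                summary=res.summary(),
                converged=res.converged,
                seconds=time.perf_counter() - t0,
            )
        except Exception as exc:  # sampler failure: record and continue
            fit = ReplicateFit(
                scenario_id=scenario.scenario_id,
                replicate=replicate_index,
                model=which,
                summary=None,
                converged=False,
                seconds=time.perf_counter() - t0,
                error=f"{type(exc).__name__}: {exc}",
            )
        out[which] = fit
        if log is not None:
            log(
                f"scenario={scenario.scenario_id} replicate={replicate_index} "
                f"model={which} converged={fit.converged} "
                f"time={fit.seconds:.1f}s"
                + (f" error={fit.error}" if fit.error else "")
            )
    return out


def metrics(
    fits: list[ReplicateFit],
    truths: TrueParams,
    multilevel: bool = True,
    require_convergence: bool = True,
) -> list[MetricsRow]:
    """Per-parameter performance over the converged replicates.

    Raises if no replicate converged (reports are conditional on
    convergence).  ``require_convergence=False`` includes every fit with a
    summary — intended for smoke-scale chains too short for a meaningful
    R-hat gate, never for reported results.
    """
    n_total = len(fits)
    if require_convergence:
        good = [f for f in fits if f.converged and f.summary is not None]
    else:
        good = [f for f in fits if f.summary is not None]
    if not good:
        raise ValueError("no converged replicates to summarize")
    targets = truth_values(truths, multilevel=multilevel)
    rows = []
    for name, true in targets.items():
        means = np.array([f.summary.table.loc[name, "mean"] for f in good])
        sds = np.array([f.summary.table.loc[name, "sd"] for f in good])
        mean_est = float(np.mean(means))
        bias = mean_est - true
        rows.append(
            MetricsRow(
                parameter=name,
                true=true,
                mean_est=mean_est,
                bias=bias,
                relative_bias=bias / true if true != 0 else None,
                mese=float(np.mean(sds)),
                ese=float(np.std(means, ddof=1)) if len(means) > 1 else 0.0,
                n_replicates=n_total,
                n_converged=len(good),
            )
        )
    return rows


def metrics_frame(
    rows: list[MetricsRow], scenario_id: str, model: str
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scenario_id": scenario_id,
            "model": model,
            "parameter": [r.parameter for r in rows],
            "true": [r.true for r in rows],
            "mean_est": [r.mean_est for r in rows],
            "bias": [r.bias for r in rows],
            "relative_bias": [
                np.nan if r.relative_bias is None else r.relative_bias
                for r in rows
            ],
            "MESE": [r.mese for r in rows],
            "ESE": [r.ese for r in rows],
            "n_reps": [r.n_replicates for r in rows],
            "n_converged": [r.n_converged for r in rows],
        }
    )


def compare_models(
    scenario: ScenarioConfig,
    n_replicates: int,
    mcmc: Optional[McmcConfig] = None,
    log: Optional[Callable[[str], None]] = None,
    require_convergence: bool = True,
) -> list[ComparisonRow]:
    """Paired MJM/JM metrics on shared replicate datasets.

    The comparison quantifies the cost of ignoring the group level; the
    headline quantities are the relative-bias deltas of the time slope,
    the treatment-by-time effect and the association parameter.
    """
    all_fits: dict[str, list[ReplicateFit]] = {"mjm": [], "jm": []}
    for rep in range(n_replicates):
        fits = run_replicate(scenario, rep, fit_both=True, mcmc=mcmc, log=log)
        for which in ("mjm", "jm"):
            all_fits[which].append(fits[which])
    rows_mjm = metrics(
        all_fits["mjm"], scenario.truths, multilevel=True,
        require_convergence=require_convergence,
    )
    rows_jm = metrics(
        all_fits["jm"], scenario.truths, multilevel=False,
        require_convergence=require_convergence,
    )
    jm_by_name = {r.parameter: r for r in rows_jm}
    out = []
    for rm in rows_mjm:
        rj = jm_by_name.get(rm.parameter)
        if rj is None:
            continue
        delta = (
            rj.relative_bias - rm.relative_bias
            if rm.relative_bias is not None and rj.relative_bias is not None
            else None
        )
        out.append(
            ComparisonRow(
                parameter=rm.parameter, mjm=rm, jm=rj, delta_relative_bias=delta
            )
        )
    return out


def run_study(
    scenarios: list[ScenarioConfig],
    n_replicates: int,
    mcmc: Optional[McmcConfig] = None,
    fit_both: bool = False,
    log: Optional[Callable[[str], None]] = None,
    require_convergence: bool = True,
) -> pd.DataFrame:
    """Run replicates for each scenario and return the metrics table."""
    frames = []
    for scenario in scenarios:
        fits: dict[str, list[ReplicateFit]] = {"mjm": [], "jm": []}
        for rep in range(n_replicates):
            res = run_replicate(scenario, rep, fit_both=fit_both, mcmc=mcmc, log=log)
            for which, fit in res.items():
                fits[which].append(fit)
        for which, flist in fits.items():
            if not flist:
                continue
            rows = metrics(
                flist,
                scenario.truths,
                multilevel=(which == "mjm"),
                require_convergence=require_convergence,
            )
            frames.append(metrics_frame(rows, scenario.scenario_id, which))
    return pd.concat(frames, ignore_index=True)
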