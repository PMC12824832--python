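"""Model and Results objects for the multilevel joint model.

:class:`MultilevelJointModel` is built from a :class:`~mjm.data.TrialDataset`
and a :class:`~mjm.params.ModelSpec`; its :meth:`fit` runs the blocked MCMC
sampler and returns an :class:`MJMResults` carrying the posterior draws,
summaries, the convergence verdict, and DIC for model comparison.

Example
-------
>>> from mjm import MultilevelJointModel, ModelSpec, McmcConfig
>>> from mjm.simulate import ScenarioConfig, generate_dataset
>>> data, _ = generate_dataset(ScenarioConfig(L=10, group_size=10, seed=1))
>>> model = MultilevelJointModel(data, ModelSpec.simulation_mjm(Q=3))
>>> res = model.fit(McmcConfig(chains=2, burn_in=200, thin=2,
...                            draws_per_chain=100, seed=1))
>>> print(res.summary().table.loc["alpha"])  # doctest: +SKIP
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import diagnostics
from .data import TrialDataset, read_trial
from .design import ModelArrays, build_arrays
from .intervals import IntervalGrid
from .likelihood import (
    UnconstrainedMap,
    log_posterior,
    longitudinal_mean,
)
from .params import ModelSpec, ParamState, PriorSpec
from .sampler import McmcConfig, PosteriorDraws, run_mcmc

__all__ = ["MultilevelJointModel", "MJMResults"]


class MultilevelJointModel:
    """Bayesian multilevel joint model of longitudinal and survival data.

    Parameters
    ----------
    data : TrialDataset
        Validated nested trial data.
    spec : ModelSpec, optional
        Structural specification; defaults to the three-level linear
        model with current-value association.
    priors : PriorSpec, optional
        Weakly-informative defaults.
    grid : IntervalGrid, optional
        Interval grid for the piecewise-constant baseline hazard.  By
        default an equal-length grid with ``spec.Q`` intervals over
        [0, max observed time].  Pass a custom grid (e.g. one aligned
        with the measurement schedule) to override.
    eval_rule : str
        Where within an interval the current value m(t) is evaluated:
        ``interval_start`` (default), ``interval_mid`` or ``event_or_end``.
    """

    def __init__(
        self,
        data: TrialDataset,
        spec: Optional[ModelSpec] = None,
        priors: Optional[PriorSpec] = None,
        grid: Optional[IntervalGrid] = None,
        eval_rule: str = "interval_start",
    ):
        self.data = data
        self.spec = spec if spec is not None else ModelSpec()
        self.priors = priors if priors is not None else PriorSpec()
        self.arrays: ModelArrays = build_arrays(data, self.spec, grid, eval_rule)

    @classmethod
    def from_csv(
        cls,
        long_path,
        surv_path,
        group_path,
        spec: Optional[ModelSpec] = None,
        **kwargs,
    ) -> "MultilevelJointModel":
        """Build the model directly from the three CSV tables."""
        return cls(read_trial(long_path, surv_path, group_path), spec, **kwargs)

    # -- log-posterior surface -------------------------------------------

    def log_posterior(self, state: ParamState) -> float:
        return log_posterior(state, self.arrays, self.priors)

    def longitudinal_mean(self, state: ParamState, subject_id: str, t: float) -> float:
        j = self.data.subject_index[subject_id]
        return longitudinal_mean(state, self.arrays, j, t)

    def unconstrained(self) -> UnconstrainedMap:
        """Unconstrained-parameterization view (for gradient samplers)."""
        return UnconstrainedMap(self.arrays, self.priors)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        config: Optional[McmcConfig] = None,
        initial_state: Optional[ParamState] = None,
    ) -> "MJMResults":
        config = config if config is not None else McmcConfig()
        draws = run_mcmc(self.arrays, self.priors, config, initial_state)
        return MJMResults(self, draws)


class MJMResults:
    """Posterior fit of a :class:`MultilevelJointModel`.

    Attributes
    ----------
    draws : PosteriorDraws
        Raw per-chain draws.
    params : pandas.Series
        Posterior means of the scalar parameters.
    post_sd : pandas.Series
        Posterior standard deviations (the Bayesian analogue of standard
        errors).
    """

    def __init__(self, model: MultilevelJointModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self._summary = diagnostics.summarize(draws)

    def summary(self) -> diagnostics.PosteriorSummary:
        return self._summary

    @property
    def params(self) -> pd.Series:
        return self._summary.table["mean"]

    @property
    def post_sd(self) -> pd.Series:
        return self._summary.table["sd"]

    @property
    def converged(self) -> bool:
        """R-hat < 1.1 on all gated parameters (fixed effects, association
        and variance components)."""
        return self._summary.converged

    @property
    def max_rhat(self) -> float:
        return self._summary.max_rhat

    def dic(self) -> dict[str, float]:
        return diagnostics.dic(self.draws, self.model.arrays)

    def posterior_mean_state(self) -> ParamState:
        return diagnostics.posterior_mean_state(self.draws, self.model.arrays)

    def __str__(self) -> str:
        tbl = self._summary.table
        head = (
            f"Multilevel joint model fit: {self.draws.n_chains} chains x "
            f"{self.draws.n_draws} draws (thin {self.draws.config.thin}), "
            f"converged={self.converged} (max gated R-hat "
            f"{self.max_rhat:.3f})\n"
        )
        return head + tbl.to_string(float_format=lambda x: f"{x:9.4f}")

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        """Fit report: summaries, convergence verdict, DIC, config echo."""
        tbl = self._summary.table
        report = {
            "spec": self.model.spec.to_dict(),
            "priors": self.model.priors.to_dict(),
            "mcmc": self.draws.config.to_dict(),
            "eval_rule": self.model.arrays.eval_rule,
            "grid_cuts": list(self.model.arrays.grid.cuts),
            "converged": self.converged,
            "max_rhat": self.max_rhat,
            "gated_parameters": self._summary.gated,
            "dic": self.dic(),
            "acceptance": self.draws.acceptance,
            "summary": {
                name: {k: _jsonable(v) for k, v in row.items()}
                for name, row in tbl.iterrows()
            },
        }
        if path is not None:
            Path(path).write_text(json.dumps(report, indent=1))
        return report

    def save_draws(self, path: str | Path) -> None:
        """Archive the scalar draws with a manifest, re-loadable via
        :func:`load_draws`."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "names": self.draws.names,
            "chains": self.draws.n_chains,
            "draws_per_chain": self.draws.n_draws,
            "config": self.draws.config.to_dict(),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        wide = np.column_stack(
            [self.draws.params[nm].reshape(-1) for nm in self.draws.names]
        )
        pd.DataFrame(wide, columns=self.draws.names).to_csv(
            path / "draws.csv", index=False, float_format="%.12g"
        )


def load_draws(path: str | Path) -> dict[str, np.ndarray]:
    """Load an archived draw table back into (chain, draw) arrays."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    frame = pd.read_csv(path / "draws.csv")
    c, d = manifest["chains"], manifest["draws_per_chain"]
    return {
        nm: frame[nm].to_numpy().reshape(c, d) for nm in manifest["names"]
    }


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not np.isfinite(v):
        return str(v)
    return v
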