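"""Follow-up splitting and pseudo-Poisson records for the survival submodel.

The piecewise-constant proportional-hazards (PCPH) likelihood is carried by
interval-level pseudo-observations: the follow-up period is divided into Q
intervals [tau_{q-1}, tau_q) and each subject contributes one record per
interval entered, with a binary pseudo-outcome d (1 only in the interval
where the event occurred) and an exposure offset equal to the time spent in
the interval.  A Poisson regression on these records with offset
log(exposure) has a likelihood proportional to the PCPH likelihood, so
posteriors over shared parameters coincide ("Poisson trick").

Boundary conventions
--------------------
* An observed time exactly equal to an interior cut is assigned to the
  interval *ending* at that cut (full exposure, event there); this avoids a
  zero-exposure record whose log-offset would be undefined and only affects
  measure-zero inputs.
* The final cut is closed at the administrative end of follow-up supplied by
  the caller (pseudo-records need finite exposure).

Each record carries an ``eval_time`` at which the current value m(t) of the
longitudinal trajectory is evaluated for the hazard.  The within-interval
evaluation point is not uniquely determined by the PCPH construction; the
default ``interval_start`` (tau_{q-1}) aligns with splitting the follow-up
consistently with the longitudinal measurement schedule, and
``interval_mid`` / ``event_or_end`` are selectable alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .data import SurvivalRecord, TrialDataset

__all__ = [
    "IntervalGrid",
    "PseudoPoissonRecord",
    "equal_length_grid",
    "split_subject",
    "split_dataset",
    "pseudo_records_frame",
    "EVAL_RULES",
]

EVAL_RULES = ("interval_start", "interval_mid", "event_or_end")


@dataclass(frozen=True)
class IntervalGrid:
    """Strictly increasing cut points 0 = tau_0 < ... < tau_Q."""

    cuts: tuple[float, ...]

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cuts)
        if len(cuts) < 2:
            raise ValueError("grid needs at least one interval (two cut points)")
        if cuts[0] != 0.0:
            raise ValueError("first cut point must be 0")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cut points must be strictly increasing")
        object.__setattr__(self, "cuts", cuts)

    @property
    def Q(self) -> int:
        return len(self.cuts) - 1

    @property
    def end(self) -> float:
        return self.cuts[-1]


@dataclass(frozen=True)
class PseudoPoissonRecord:
    """One interval-level pseudo-observation.

    ``q`` is the 1-based interval index, ``exposure`` the time spent in the
    interval (the Poisson offset), ``d`` the pseudo-outcome, and
    ``eval_time`` the time at which the current value m(t) is evaluated.
    """

    subject_id: str
    group_id: str
    q: int
    exposure: float
    d: int
    eval_time: float


def equal_length_grid(max_time: float, Q: int) -> IntervalGrid:
    """Equal-length grid (0, max_time/Q, ..., max_time) with Q intervals."""
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if max_time <= 0:
        raise ValueError("max_time must be > 0")
    return IntervalGrid(tuple(np.linspace(0.0, float(max_time), Q + 1)))


def _eval_time(t0: float, t1: float, exit_time: float, rule: str) -> float:
    if rule == "interval_start":
        return t0
    if rule == "interval_mid":
        return 0.5 * (t0 + exit_time)
    if rule == "event_or_end":
        return exit_time
    raise ValueError(f"unknown eval rule {rule!r}; choose from {EVAL_RULES}")


def split_subject(
    record: SurvivalRecord,
    grid: IntervalGrid,
    eval_rule: str = "interval_start",
) -> list[PseudoPoissonRecord]:
    """Split one subject's follow-up into pseudo-Poisson records.

    Exposures sum exactly to the observed time; d = 1 appears only in the
    final record and only if the subject's event was observed.
    """
    T = float(record.observed_time)
    if T <= 0:
        raise ValueError(f"observed time must be > 0, got {T}")
    if T > grid.end:
        raise ValueError(
            f"observed time {T} exceeds the grid end {grid.end}; "
            "extend the final cut to the administrative end of follow-up"
        )
    out: list[PseudoPoissonRecord] = []
    cuts = grid.cuts
    for q in range(1, grid.Q + 1):
        t0, t1 = cuts[q - 1], cuts[q]
        last = T <= t1  # boundary time belongs to the interval ending there
        exit_time = T if last else t1
        exposure = exit_time - t0
        d = int(record.event) if last else 0
        out.append(
            PseudoPoissonRecord(
                subject_id=record.subject_id,
                group_id=record.group_id,
                q=q,
                exposure=exposure,
                d=d,
                eval_time=_eval_time(t0, t1, exit_time, eval_rule),
            )
        )
        if last:
            break
    return out


def split_dataset(
    data: TrialDataset,
    grid: IntervalGrid,
    eval_rule: str = "interval_start",
) -> list[PseudoPoissonRecord]:
    """Pseudo-Poisson records for every subject, in (subject, q) order.

    Subjects are iterated in the dataset's dense subject order so the
    likelihood assembly is deterministic.
    """
    records: list[PseudoPoissonRecord] = []
    surv = data.survival.set_index("subject_id")
    for sid in data.subject_ids:
        row = surv.loc[sid]
        rec = SurvivalRecord(
            subject_id=sid,
            group_id=str(row["group_id"]),
            observed_time=float(row["observed_time"]),
            event=int(row["event"]),
        )
        records.extend(split_subject(rec, grid, eval_rule))
    return records


def pseudo_records_frame(records: Iterable[PseudoPoissonRecord]) -> pd.DataFrame:
    """Tabular view ``subject_id,group_id,q,exposure,d,eval_time``."""
    return pd.DataFrame(
        [
            (r.subject_id, r.group_id, r.q, r.exposure, r.d, r.eval_time)
            for r in records
        ],
        columns=["subject_id", "group_id", "q", "exposure", "d", "eval_time"],
    )
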