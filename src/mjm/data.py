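"""Domain types, file I/O and validation for nested trial data.

The data model mirrors a cluster randomized trial (CRCT) with a
longitudinal biomarker and a time-to-event outcome: repeated measurements
(level 1) are nested in subjects (level 2), which are nested in groups
(level 3, the unit of randomization).  Three comma-delimited tables carry
the data:

``longitudinal.csv``
    columns ``subject_id,group_id,time,y[,<covariate>...]``
``survival.csv``
    columns ``subject_id,group_id,observed_time,event[,<covariate>...]``
``groups.csv``
    columns ``group_id,treatment[,<covariate>...]``

Identifiers are opaque strings; a dense integer indexing (subjects
``0..n-1``, groups ``0..L-1``) is built at load time and recorded on the
dataset so parameter ordering is stable and reproducible.  Times are years
stored as decimals (``0.5`` = 6 months).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "SchemaError",
    "LinkageError",
    "DuplicateError",
    "LongitudinalRecord",
    "SurvivalRecord",
    "GroupTable",
    "TrialDataset",
    "ValidationReport",
    "read_trial",
    "write_trial",
    "validate_nesting",
]


class DataError(ValueError):
    """Base class for trial-data construction errors."""


class SchemaError(DataError):
    """A table is missing required columns or contains no records."""


class LinkageError(DataError):
    """Subject/group membership is inconsistent across tables."""


class DuplicateError(DataError):
    """Duplicate (subject, time) measurement or duplicate id."""


@dataclass(frozen=True)
class LongitudinalRecord:
    """One outcome measurement nested in a subject nested in a group."""

    subject_id: str
    group_id: str
    time: float
    y: float
    covariates: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-subject observed follow-up time and event indicator.

    ``observed_time`` is min(true event time, censoring time); ``event``
    is 1 if the event was observed, 0 if censored.
    """

    subject_id: str
    group_id: str
    observed_time: float
    event: int
    covariates: Mapping[str, float] = field(default_factory=dict)


LONG_REQUIRED = ["subject_id", "group_id", "time", "y"]
SURV_REQUIRED = ["subject_id", "group_id", "observed_time", "event"]
GROUP_REQUIRED = ["group_id", "treatment"]


def _check_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns {missing}")


class GroupTable:
    """Group-level table: one row per group with the treatment indicator.

    Treatment is the group-level (cluster-randomized) intervention flag;
    additional columns are group-level covariates.
    """

    def __init__(self, frame: pd.DataFrame):
        _check_columns(frame, GROUP_REQUIRED, "groups")
        frame = frame.copy()
        frame["group_id"] = frame["group_id"].astype(str)
        if frame["group_id"].duplicated().any():
            dups = frame.loc[frame["group_id"].duplicated(), "group_id"].tolist()
            raise DuplicateError(f"duplicate group ids {dups}")
        trt = frame["treatment"].to_numpy()
        if not np.isin(trt, [0, 1]).all():
            raise DataError("treatment must be binary 0/1")
        self.frame = frame.reset_index(drop=True)

    @property
    def group_ids(self) -> list[str]:
        return self.frame["group_id"].tolist()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != "group_id"]

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, GroupTable) and self.frame.equals(other.frame)


class TrialDataset:
    """Validated container for the three linked trial tables.

    Parameters
    ----------
    longitudinal : pandas.DataFrame
        Long-format measurements, one row per (subject, time).
    survival : pandas.DataFrame
        One row per subject with observed time and event indicator.
    groups : GroupTable or pandas.DataFrame
        Group-level table.

    Construction validates the nesting invariants: non-negative
    measurement times, positive observed times, binary event indicators,
    one survival row per subject, a single group per subject consistent
    across tables, and matching subject sets in the two subject-level
    tables.  Dense indices ``subject_index`` / ``group_index`` map each
    identifier to ``0..n-1`` / ``0..L-1``.
    """

    def __init__(
        self,
        longitudinal: pd.DataFrame,
        survival: pd.DataFrame,
        groups: GroupTable | pd.DataFrame,
        validate: bool = True,
    ):
        if not isinstance(groups, GroupTable):
            groups = GroupTable(groups)
        _check_columns(longitudinal, LONG_REQUIRED, "longitudinal")
        _check_columns(survival, SURV_REQUIRED, "survival")
        if len(longitudinal) == 0:
            raise SchemaError("no longitudinal records")
        if len(survival) == 0:
            raise SchemaError("no survival records")

        longitudinal = longitudinal.copy().reset_index(drop=True)
        survival = survival.copy().reset_index(drop=True)
        for df in (longitudinal, survival):
            df["subject_id"] = df["subject_id"].astype(str)
            df["group_id"] = df["group_id"].astype(str)

        gmap_surv = dict(zip(survival["subject_id"], survival["group_id"]))
        if validate:
            self._validate(longitudinal, survival, groups, gmap_surv)

        self.longitudinal = longitudinal
        self.survival = survival
        self.groups = groups

        self.subject_ids: list[str] = survival["subject_id"].tolist()
        self.subject_index: dict[str, int] = {
            s: i for i, s in enumerate(self.subject_ids)
        }
        self.group_ids: list[str] = groups.group_ids
        self.group_index: dict[str, int] = {g: i for i, g in enumerate(self.group_ids)}
        self.subject_group: np.ndarray = np.array(
            [self.group_index[gmap_surv[s]] for s in self.subject_ids], dtype=np.intp
        )

    @staticmethod
    def _validate(
        longitudinal: pd.DataFrame,
        survival: pd.DataFrame,
        groups: GroupTable,
        gmap_surv: dict[str, str],
    ) -> None:
        if (longitudinal["time"] < 0).any():
            raise DataError("measurement times must be >= 0")
        if (survival["observed_time"] <= 0).any():
            raise DataError("observed times must be > 0")
        if not np.isin(survival["event"].to_numpy(), [0, 1]).all():
            raise DataError("event indicator must be binary 0/1")

        if survival["subject_id"].duplicated().any():
            dups = survival.loc[
                survival["subject_id"].duplicated(), "subject_id"
            ].tolist()
            raise DuplicateError(f"more than one survival record for {dups}")
        pair_dup = longitudinal.duplicated(subset=["subject_id", "time"])
        if pair_dup.any():
            dups = longitudinal.loc[pair_dup, ["subject_id", "time"]]
            raise DuplicateError(
                f"duplicate (subject, time) measurements: {dups.values.tolist()}"
            )

        long_subjects = set(longitudinal["subject_id"])
        surv_subjects = set(survival["subject_id"])
        if long_subjects != surv_subjects:
            only_long = sorted(long_subjects - surv_subjects)
            only_surv = sorted(surv_subjects - long_subjects)
            raise LinkageError(
                "subject sets differ between tables: "
                f"longitudinal-only {only_long}, survival-only {only_surv}"
            )

        known_groups = set(groups.group_ids)
        used_groups = set(longitudinal["group_id"]) | set(survival["group_id"])
        unknown = sorted(used_groups - known_groups)
        if unknown:
            raise LinkageError(f"groups {unknown} not present in group table")

        # each subject maps to exactly one group, the same in both tables
        long_groups = longitudinal.groupby("subject_id")["group_id"].nunique()
        multi = long_groups[long_groups > 1].index.tolist()
        if multi:
            raise LinkageError(f"subjects {multi} appear in more than one group")
        mismatched = [
            s
            for s, g in zip(longitudinal["subject_id"], longitudinal["group_id"])
            if gmap_surv[s] != g
        ]
        if mismatched:
            raise LinkageError(
                f"group membership differs between tables for {sorted(set(mismatched))}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    def longitudinal_covariates(self) -> list[str]:
        return [c for c in self.longitudinal.columns if c not in LONG_REQUIRED]

    def survival_covariates(self) -> list[str]:
        return [c for c in self.survival.columns if c not in SURV_REQUIRED]

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        return (
            self.longitudinal.equals(other.longitudinal)
            and self.survival.equals(other.survival)
            and self.groups == other.groups
        )

    def __repr__(self) -> str:
        return (
            f"TrialDataset(n_measurements={len(self.longitudinal)}, "
            f"n_subjects={self.n_subjects}, n_groups={self.n_groups})"
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_nesting`: violations and warnings."""

    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.violations and not self.warnings


def read_trial(
    long_path: str | Path, surv_path: str | Path, group_path: str | Path
) -> TrialDataset:
    """Read and validate the three CSV tables into a :class:`TrialDataset`."""
    frames = []
    for path, name in ((long_path, "longitudinal"), (surv_path, "survival"),
                       (group_path, "groups")):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"{name} table not found at {path}")
        frames.append(pd.read_csv(path, dtype={"subject_id": str, "group_id": str}))
    return TrialDataset(frames[0], frames[1], frames[2])


def write_trial(data: TrialDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tables to ``out_dir`` as CSV (12 significant digits).

    Returns the mapping of table name to written path.  A write/read
    round trip reproduces the dataset exactly at that precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "longitudinal": out_dir / "longitudinal.csv",
        "survival": out_dir / "survival.csv",
        "groups": out_dir / "groups.csv",
    }
    data.longitudinal.to_csv(paths["longitudinal"], index=False, float_format="%.12g")
    data.survival.to_csv(paths["survival"], index=False, float_format="%.12g")
    data.groups.frame.to_csv(paths["groups"], index=False, float_format="%.12g")
    return paths


def validate_nesting(data: TrialDataset) -> ValidationReport:
    """Scan a dataset for nesting violations and schedule warnings.

    A dataset that passed :class:`TrialDataset` construction can still
    contain measurements recorded after the subject's observed event
    time; the real-data design has a longitudinal window shorter than the
    survival follow-up, so these are flagged as warnings, never errors.
    Group-membership inconsistencies (possible when tables are assembled
    by hand and bypass the constructor checks) are reported as
    violations.
    """
    report = ValidationReport()
    gmap = dict(zip(data.survival["subject_id"], data.survival["group_id"]))
    for s, g in zip(data.longitudinal["subject_id"], data.longitudinal["group_id"]):
        if gmap.get(s) != g:
            report.violations.append(
                f"subject {s} assigned to group {g} in longitudinal table "
                f"but {gmap.get(s)} in survival table"
            )
    tmap = dict(zip(data.survival["subject_id"], data.survival["observed_time"]))
    emap = dict(zip(data.survival["subject_id"], data.survival["event"]))
    for s, t in zip(data.longitudinal["subject_id"], data.longitudinal["time"]):
        if emap.get(s, 0) == 1 and t > tmap[s]:
            report.warnings.append(
                f"subject {s} measured at {t} after observed event time {tmap[s]}"
            )
    return report
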