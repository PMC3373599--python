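"""Reading, validating and cleaning per-trial visual-search RT records.

Trials are tabular: one row per search trial with a subject label, a target
condition (C, O, M, CO, MO or CM), the reaction time in seconds and a
correct-response flag.  Cleaning drops incorrect trials and RT outliers --
RTs below a 0.2 s floor or more than 3 standard deviations above the
per-(subject, condition) mean of the correct trials.  The mean and SD are
computed once, over ALL correct trials (including eventual outliers); the
rule is deliberately single-pass, since iterative trimming would change the
retained set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from racewin.constants import CONDITIONS

__all__ = [
    "TrialRecord",
    "CleaningParams",
    "CleaningReport",
    "SubjectDataset",
    "read_trials",
    "write_trials",
    "clean_trials",
    "split_by_subject",
]

_COLUMNS = ("subject", "condition", "rt", "correct")

_TRUE_STRINGS = {"1", "true", "t", "yes"}
_FALSE_STRINGS = {"0", "false", "f", "no"}


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral search trial."""

    subject_id: str
    condition: str
    rt: float  # seconds
    correct: bool

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if not np.isfinite(self.rt) or self.rt <= 0:
            raise ValueError(f"rt must be finite and positive, got {self.rt}")


@dataclass(frozen=True)
class CleaningParams:
    """Outlier-exclusion parameters.

    ``min_rt`` is the anticipation floor in seconds; ``sd_multiplier`` sets
    the upper cut at mean + sd_multiplier * SD of the correct trials.  The
    upper cut is one-sided: only implausibly long RTs are trimmed.
    """

    min_rt: float = 0.2
    sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.min_rt <= 0:
            raise ValueError("min_rt must be > 0")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")


@dataclass(frozen=True)
class ConditionCleaningStats:
    n_total: int
    n_incorrect: int
    n_outlier: int

    @property
    def fraction_excluded(self) -> float:
        return (self.n_incorrect + self.n_outlier) / self.n_total


@dataclass(frozen=True)
class CleaningReport:
    """Per-(subject, condition) exclusion tallies."""

    subject_id: str
    per_condition: Mapping[str, ConditionCleaningStats]

    @property
    def fraction_excluded(self) -> float:
        """Overall excluded fraction across all conditions of the subject."""
        total = sum(s.n_total for s in self.per_condition.values())
        excl = sum(s.n_incorrect + s.n_outlier for s in self.per_condition.values())
        return excl / total

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "per_condition": {
                cond: {
                    "n_total": s.n_total,
                    "n_incorrect": s.n_incorrect,
                    "n_outlier": s.n_outlier,
                    "fraction_excluded": s.fraction_excluded,
                }
                for cond, s in self.per_condition.items()
            },
            "fraction_excluded": self.fraction_excluded,
        }


@dataclass
class SubjectDataset:
    """All trials of one subject, as a DataFrame with the standard columns."""

    subject_id: str
    trials: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trials missing column(s): {missing}")
        if not (self.trials["subject"] == self.subject_id).all():
            raise ValueError("all trials must carry the dataset's subject_id")
        bad = set(self.trials["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition label(s): {sorted(bad)}")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(c for c in CONDITIONS if c in set(self.trials["condition"]))

    def rts(self, condition: str, correct_only: bool = True) -> np.ndarray:
        """RTs (seconds) of one condition, by default correct trials only."""
        mask = self.trials["condition"] == condition
        if correct_only:
            mask &= self.trials["correct"]
        return self.trials.loc[mask, "rt"].to_numpy(dtype=float)

    def pooled_rts(self, correct_only: bool = True) -> np.ndarray:
        """RTs pooled over all conditions (the binning policy pools them)."""
        mask = self.trials["correct"] if correct_only else slice(None)
        if correct_only:
            return self.trials.loc[mask, "rt"].to_numpy(dtype=float)
        return self.trials["rt"].to_numpy(dtype=float)


class SchemaError(ValueError):
    """The trial table does not have the expected columns."""


class TrialParseError(ValueError):
    """A trial row could not be parsed; carries the offending row number."""


class CleaningError(ValueError):
    """Cleaning could not be performed (too few correct trials, etc.)."""


def _parse_correct(values: pd.Series, path) -> pd.Series:
    text = values.astype(str).str.strip().str.lower()
    ok_true = text.isin(_TRUE_STRINGS)
    ok_false = text.isin(_FALSE_STRINGS)
    bad = ~(ok_true | ok_false)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TrialParseError(
            f"{path}: row {row + 2}: cannot parse correct flag {values.iloc[row]!r}"
        )
    return ok_true


def read_trials(
    path: str | Path,
    delimiter: str | None = None,
    rt_unit: str = "s",
) -> pd.DataFrame:
    """Read a trial table from CSV/TSV.

    Parameters
    ----------
    path
        File with header ``subject,condition,rt,correct``.
    delimiter
        Field delimiter; ``None`` infers ``\\t`` for ``.tsv`` and ``,``
        otherwise.
    rt_unit
        ``"s"`` (default) or ``"ms"``; milliseconds are converted to seconds.

    Returns
    -------
    DataFrame with columns subject (str), condition (str), rt (float,
    seconds) and correct (bool).
    """
    path = Path(path)
    if rt_unit not in ("s", "ms"):
        raise ValueError("rt_unit must be 's' or 'ms'")
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    df = df[list(_COLUMNS)].copy()
    df["subject"] = df["subject"].astype(str).str.strip()
    df["condition"] = df["condition"].astype(str).str.strip()

    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        row = int(np.flatnonzero(bad_cond.to_numpy())[0])
        raise TrialParseError(
            f"{path}: row {row + 2}: unknown condition {df['condition'].iloc[row]!r}"
        )

    rt = pd.to_numeric(df["rt"], errors="coerce")
    bad_rt = rt.isna() | ~np.isfinite(rt) | (rt <= 0)
    if bad_rt.any():
        row = int(np.flatnonzero(bad_rt.to_numpy())[0])
        raise TrialParseError(
            f"{path}: row {row + 2}: invalid rt {df['rt'].iloc[row]!r}"
        )
    df["rt"] = rt.astype(float)
    if rt_unit == "ms":
        df["rt"] /= 1000.0
    df["correct"] = _parse_correct(df["correct"], path)
    return df


def write_trials(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a trial table in the same schema ``read_trials`` accepts."""
    out = df[list(_COLUMNS)].copy()
    out["correct"] = out["correct"].astype(int)
    out.to_csv(path, sep=delimiter, index=False)


def split_by_subject(df: pd.DataFrame) -> dict[str, SubjectDataset]:
    """Split a trial table into per-subject datasets (insertion order kept)."""
    return {
        str(sid): SubjectDataset(str(sid), grp.reset_index(drop=True))
        for sid, grp in df.groupby("subject", sort=False)
    }


def clean_trials(
    dataset: SubjectDataset,
    params: CleaningParams = CleaningParams(),
) -> tuple[SubjectDataset, CleaningReport]:
    """Apply the exclusion rules to one subject's trials.

    Per condition: incorrect trials are dropped; among correct trials the
    mean ``m`` and sample SD ``s`` are computed once over all correct trials,
    and trials with ``rt < min_rt`` or ``rt > m + sd_multiplier * s`` are
    dropped.  Thresholds of one condition never depend on another
    condition's trials.

    Returns the cleaned dataset and a report tallying all exclusions.

    Raises
    ------
    CleaningError
        If a condition has fewer than 2 correct trials (no SD exists) or if
        every trial of a condition would be excluded.
    """
    keep_masks = []
    stats: dict[str, ConditionCleaningStats] = {}
    df = dataset.trials
    for cond in dataset.conditions:
        in_cond = df["condition"] == cond
        correct = in_cond & df["correct"]
        n_total = int(in_cond.sum())
        n_correct = int(correct.sum())
        if n_correct < 2:
            raise CleaningError(
                f"subject {dataset.subject_id}, condition {cond}: "
                f"{n_correct} correct trial(s); need >= 2 for an SD"
            )
        rts = df.loc[correct, "rt"]
        m = rts.mean()
        s = rts.std(ddof=1)  # sample SD over ALL correct trials, one pass
        outlier = correct & ((df["rt"] < params.min_rt) | (df["rt"] > m + params.sd_multiplier * s))
        keep = correct & ~outlier
        if not keep.any():
            raise CleaningError(
                f"subject {dataset.subject_id}, condition {cond}: all trials excluded"
            )
        keep_masks.append(keep)
        stats[cond] = ConditionCleaningStats(
            n_total=n_total,
            n_incorrect=n_total - n_correct,
            n_outlier=int(outlier.sum()),
        )
    keep_all = np.logical_or.reduce([m.to_numpy() for m in keep_masks])
    cleaned = SubjectDataset(dataset.subject_id, df.loc[keep_all].reset_index(drop=True))
    return cleaned, CleaningReport(dataset.subject_id, stats)
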