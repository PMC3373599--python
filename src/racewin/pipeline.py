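"""End-to-end orchestration: clean -> bin -> fit -> contributions ->
consistency -> chance level -> (optional) bootstrap -> report.

The per-subject report mirrors the analysis a reader would run on the
behavioral study: every stage's output is serialized to JSON, and a
cross-subject summary gives subject-averaged contributions with standard
errors, a one-sample t-test of the mean conjunctive contribution against
the subject-averaged chance level, and matched-pair t-tests between the
conjunctive and single-feature contributions.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from racewin.binning import BinnedCounts, bin_rts, make_bin_grid
from racewin.constants import CONDITIONS, DOUBLE_CONDITIONS, RACE_SINGLES
from racewin.diagnostics import bootstrap_intervals, fit_consistency
from racewin.inference import FitConfig, fit_model
from racewin.rt_data import CleaningParams, SubjectDataset, clean_trials, split_by_subject
from racewin.significance import chance_level

logger = logging.getLogger("racewin")

__all__ = ["PipelineConfig", "run_pipeline", "run_subject", "summarize_across_subjects"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run depends on (serialized into the report)."""

    n_bins: int = 10
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    fit: FitConfig = field(default_factory=FitConfig)
    chance_reps: int = 1000
    refit_scope: str = "race_only"
    null_resample: str = "double_only"
    bootstrap_reps: int = 0  # 0 disables the bootstrap stage
    bootstrap_percentiles: tuple[float, float] = (2.5, 97.5)
    tie_credit: str = "full"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bootstrap_percentiles"] = list(self.bootstrap_percentiles)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "cleaning" in d and isinstance(d["cleaning"], Mapping):
            d["cleaning"] = CleaningParams(**d["cleaning"])
        if "fit" in d and isinstance(d["fit"], Mapping):
            d["fit"] = FitConfig(**d["fit"])
        if "bootstrap_percentiles" in d:
            d["bootstrap_percentiles"] = tuple(d["bootstrap_percentiles"])
        return cls(**d)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and subject."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject_id!r}: {cause}")
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause


def _subject_seed(base_seed: int, subject_id: str, stage: str) -> int:
    h = hashlib.sha256(f"{base_seed}:{subject_id}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run_subject(dataset: SubjectDataset, config: PipelineConfig) -> dict:
    """Full per-subject analysis; returns a JSON-serializable report."""
    sid = dataset.subject_id

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - wrapped with stage context
            raise StageError(name, sid, exc) from exc

    cleaned, cleaning_report = stage("cleaning", lambda: clean_trials(dataset, config.cleaning))
    grid = stage("binning", lambda: make_bin_grid(cleaned.pooled_rts(), config.n_bins))
    counts = BinnedCounts(
        grid, {c: bin_rts(cleaned.rts(c), grid) for c in cleaned.conditions}
    )
    fit_cfg = FitConfig(
        max_iterations=config.fit.max_iterations,
        tolerance=config.fit.tolerance,
        n_restarts=config.fit.n_restarts,
        seed=_subject_seed(config.seed, sid, "fit"),
        prob_floor=config.fit.prob_floor,
    )
    fit = stage("fit", lambda: fit_model(counts, fit_cfg))
    contributions = {
        dc: fit.params.contributions(dc, config.tie_credit).as_dict()
        for dc in DOUBLE_CONDITIONS
        if dc in cleaned.conditions
    }
    consistency = stage(
        "consistency",
        lambda: {c: r.to_dict() for c, r in fit_consistency(counts, fit).items()},
    )
    chance = {}
    for dc in contributions:
        res = stage(
            f"chance_{dc}",
            lambda dc=dc: chance_level(
                counts,
                fit,
                dc,
                n_reps=config.chance_reps,
                seed=_subject_seed(config.seed, sid, f"chance_{dc}"),
                refit_scope=config.refit_scope,
                null_resample=config.null_resample,
                fit_config=fit_cfg,
            ),
        )
        d = res.to_dict()
        d.pop("chance_values")  # keep reports compact; summary stats retained
        chance[dc] = d

    report = {
        "subject_id": sid,
        "cleaning": cleaning_report.to_dict(),
        "grid": grid.to_dict(),
        "counts": {c: v.tolist() for c, v in counts.counts.items()},
        "fit": {
            "dists": {k: v.tolist() for k, v in fit.params.dists.items()},
            "nll": fit.nll,
            "converged": fit.converged,
            "restart_nlls": np.asarray(fit.restart_nlls).tolist(),
        },
        "contributions": contributions,
        "consistency": consistency,
        "chance": chance,
    }
    if config.bootstrap_reps > 0:
        boot = stage(
            "bootstrap",
            lambda: bootstrap_intervals(
                cleaned,
                n_bins=config.n_bins,
                fit_config=fit_cfg,
                n_reps=config.bootstrap_reps,
                seed=_subject_seed(config.seed, sid, "bootstrap"),
                percentiles=config.bootstrap_percentiles,
                point_fit=fit,
            ),
        )
        report["bootstrap"] = boot.to_dict()
    return report


def summarize_across_subjects(reports: list[dict]) -> dict:
    """Group-level summary over per-subject reports.

    Subject-averaged contributions with standard errors; one-sample t-test
    of each conjunctive contribution against the subject-averaged mean
    chance level; matched-pair t-tests between the conjunctive and each
    single-feature contribution.
    """
    if len(reports) < 2:
        raise ValueError("need >= 2 subject reports for a group summary")
    summary: dict = {"n_subjects": len(reports), "conditions": {}}
    for dc in DOUBLE_CONDITIONS:
        rows = [r for r in reports if dc in r.get("contributions", {})]
        if len(rows) < 2:
            continue
        a, b = RACE_SINGLES[dc]
        c_first = np.array([r["contributions"][dc]["c_first"] for r in rows])
        c_second = np.array([r["contributions"][dc]["c_second"] for r in rows])
        c_conj = np.array([r["contributions"][dc]["c_conj"] for r in rows])
        chance = np.array([r["chance"][dc]["mean_chance"] for r in rows])
        n_sig = sum(bool(r["chance"][dc]["significant"]) for r in rows)

        def _sem(x):
            return float(x.std(ddof=1) / np.sqrt(x.size))

        diffs = c_conj - chance
        if np.allclose(diffs.std(ddof=1), 0.0):
            t_chance = {"t": None, "p": None, "degenerate": True}
        else:
            t, p = stats.ttest_1samp(diffs, 0.0, alternative="greater")
            t_chance = {"t": float(t), "p": float(p), "degenerate": False}

        def _paired(x, y):
            if np.allclose((x - y).std(ddof=1), 0.0):
                return {"t": None, "p": None, "degenerate": True}
            t, p = stats.ttest_rel(x, y)
            return {"t": float(t), "p": float(p), "degenerate": False}

        summary["conditions"][dc] = {
            "mean": {
                f"c_{a}": float(c_first.mean()),
                f"c_{b}": float(c_second.mean()),
                "c_conj": float(c_conj.mean()),
                "chance": float(chance.mean()),
            },
            "sem": {
                f"c_{a}": _sem(c_first),
                f"c_{b}": _sem(c_second),
                "c_conj": _sem(c_conj),
            },
            "n_significant_subjects": n_sig,
            "t_conj_vs_chance": t_chance,
            "t_conj_vs_first": _paired(c_conj, c_first),
            "t_conj_vs_second": _paired(c_conj, c_second),
        }
    summary["note"] = (
        "one-sample and matched-pair t-tests, no multiple-testing correction"
    )
    return summary


def run_pipeline(
    trials: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """Run every subject in a trial table and assemble the full report.

    A subject missing one of the six conditions is skipped with a logged
    warning; other subjects are still processed.  With a fixed seed and
    config the report (and its JSON serialization) is reproducible
    bit-for-bit.
    """
    datasets = split_by_subject(trials)
    reports = []
    skipped = []
    for sid, ds in datasets.items():
        missing = [c for c in CONDITIONS if c not in ds.conditions]
        if missing:
            logger.warning("subject %s skipped: missing condition(s) %s", sid, missing)
            skipped.append({"subject_id": sid, "missing_conditions": missing})
            continue
        logger.info("subject %s: seed=%d config=%s", sid, config.seed, config.config_hash())
        reports.append(run_subject(ds, config))
    full = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "subjects": reports,
        "skipped": skipped,
    }
    if len(reports) >= 2:
        full["summary"] = summarize_across_subjects(reports)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(dumps_report(full))
        for rep in reports:
            (out_dir / f"subject_{rep['subject_id']}.json").write_text(dumps_report(rep))
    return full


def dumps_report(obj) -> str:
    """Canonical JSON serialization (sorted keys, fixed separators) so that
    identical runs produce byte-identical files."""
    return json.dumps(obj, sort_keys=True, indent=1, separators=(",", ": "))
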