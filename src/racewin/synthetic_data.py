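"""Trial-level RT generator with the statistical structure the race model assumes.

Single-feature RTs are i.i.d. draws from their racer's distribution.
Double-feature RTs are the minimum of the two corresponding single racers'
draws plus, if configured, one conjunctive racer's draw.  The default
calibration mirrors the study conditions the analysis was designed for:
8 subjects, 320 trials per condition, single-target mean RT about 600 ms,
and conjunctive CO and MO racers matched to the singles so that
double-target means come out near 500 ms (the mean of the minimum of three
i.i.d. normals is mu - 0.8463 sigma; with sigma = 118 ms that is ~500 ms).
No CM racer exists by default, matching the physiological absence of
color-motion conjunctive cells in V1.

A small fraction of trials is corrupted on purpose -- button-press errors
(correct = False) and long outlier RTs -- so that the cleaning rules have
something to do; the defaults keep the excluded fraction under the study's
9.2% ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from racewin.constants import DOUBLE_CONDITIONS, RACE_SINGLES, SINGLE_CONDITIONS
from racewin.binning import BinGrid
from racewin.rt_data import SubjectDataset

__all__ = [
    "RacerSpec",
    "SyntheticConfig",
    "GroundTruth",
    "sample_racer_rts",
    "generate_dataset",
    "true_contributions",
]

_MAX_REDRAW_ROUNDS = 1000


@dataclass(frozen=True)
class RacerSpec:
    """Parametric RT distribution of one racer.

    families
        ``truncated_normal``: normal(location, scale) redrawn below ``floor``;
        ``exgaussian``: normal(location, scale) + exponential(tail), redrawn
        below ``floor``;
        ``empirical_table``: resampling of a fixed value table;
        ``latent_response``: a latent neural response r ~ normal(resp_mean,
        resp_sd) mapped through the monotone decreasing f(r) =
        map_offset + map_scale / r.  The analysis pipeline is invariant to
        the map -- only the ordering of racer draws matters -- so this mode
        exists to make that invariance testable, not because f is needed.
    All times in seconds; responses in arbitrary units.
    """

    family: str = "truncated_normal"
    location: float = 0.600
    scale: float = 0.118
    tail: float = 0.0
    floor: float = 0.2
    table: tuple[float, ...] | None = None
    resp_mean: float = 10.0
    resp_sd: float = 2.0
    map_scale: float = 4.0
    map_offset: float = 0.2

    def __post_init__(self) -> None:
        if self.family not in (
            "truncated_normal", "exgaussian", "empirical_table", "latent_response"
        ):
            raise ValueError(f"unknown family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.floor <= 0:
            raise ValueError("floor must be > 0")
        if self.family == "exgaussian" and self.tail <= 0:
            raise ValueError("exgaussian needs tail > 0")
        if self.family == "latent_response":
            if self.resp_sd <= 0 or self.resp_mean <= 0 or self.map_scale <= 0:
                raise ValueError("latent_response needs positive resp_mean, resp_sd, map_scale")
        if self.family == "empirical_table":
            if not self.table:
                raise ValueError("empirical_table needs a value table")
            if min(self.table) < self.floor:
                raise ValueError("table values below floor")

    @property
    def mean(self) -> float:
        """Exact mean where closed-form (truncated normal), else MC-free approx."""
        if self.family == "truncated_normal":
            from scipy.stats import truncnorm

            a = (self.floor - self.location) / self.scale
            return float(truncnorm.mean(a, np.inf, loc=self.location, scale=self.scale))
        if self.family == "exgaussian":
            return self.location + self.tail  # truncation at 3+ SD is negligible
        if self.family == "latent_response":
            from scipy.integrate import quad
            from scipy.stats import norm

            pdf = norm(self.resp_mean, self.resp_sd).pdf
            lo = max(1e-9, self.resp_mean - 8 * self.resp_sd)
            hi = self.resp_mean + 8 * self.resp_sd
            num, _ = quad(lambda r: (self.map_offset + self.map_scale / r) * pdf(r), lo, hi)
            den, _ = quad(pdf, lo, hi)
            return float(num / den)
        return float(np.mean(self.table))

    def bin_probabilities(self, grid: BinGrid) -> np.ndarray:
        """Exact probability of each grid bin under this racer (truncated
        normal and empirical_table analytically; exgaussian via scipy)."""
        b = grid.boundaries
        if self.family == "truncated_normal":
            from scipy.stats import norm

            z = norm.cdf((b - self.location) / self.scale)
            z0 = norm.cdf((self.floor - self.location) / self.scale)
            cdf = np.clip((z - z0) / (1 - z0), 0.0, 1.0)
        elif self.family == "exgaussian":
            from scipy.stats import exponnorm

            k = self.tail / self.scale
            cdf = exponnorm.cdf(b, k, loc=self.location, scale=self.scale)
            c0 = exponnorm.cdf(self.floor, k, loc=self.location, scale=self.scale)
            cdf = np.clip((cdf - c0) / (1 - c0), 0.0, 1.0)
        elif self.family == "latent_response":
            from scipy.stats import norm

            # P(RT <= t) = P(r >= map_scale / (t - offset)), r > 0 kept
            rdist = norm(self.resp_mean, self.resp_sd)
            keep = rdist.sf(0.0)
            with np.errstate(divide="ignore"):
                r_at = self.map_scale / np.clip(b - self.map_offset, 1e-300, None)
            cdf = np.where(b > max(self.map_offset, self.floor), rdist.sf(r_at) / keep, 0.0)
            cdf = np.clip(cdf, 0.0, 1.0)
        else:
            vals = np.asarray(self.table)
            cdf = np.array([(vals <= t).mean() for t in b])
        p = np.diff(cdf)
        # mass below t_0 (possible if the grid comes from another sample) goes
        # to the first bin so the vector stays a distribution
        p[0] += cdf[0]
        return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


def sample_racer_rts(spec: RacerSpec, n: int, seed=None) -> np.ndarray:
    """``n`` i.i.d. RT draws (seconds); draws below the floor are redrawn.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    if spec.family == "empirical_table":
        return rng.choice(np.asarray(spec.table, dtype=float), size=n, replace=True)

    def draw(m: int) -> np.ndarray:
        if spec.family == "latent_response":
            r = rng.normal(spec.resp_mean, spec.resp_sd, size=m)
            with np.errstate(divide="ignore"):
                return np.where(r > 0, spec.map_offset + spec.map_scale / np.abs(r), -1.0)
        x = rng.normal(spec.location, spec.scale, size=m)
        if spec.family == "exgaussian":
            x = x + rng.exponential(spec.tail, size=m)
        return x

    out = draw(n)
    for _ in range(_MAX_REDRAW_ROUNDS):
        low = out < spec.floor
        m = int(low.sum())
        if m == 0:
            return out
        out[low] = draw(m)
    raise RuntimeError(
        f"truncation unsatisfiable: {spec} keeps drawing below floor {spec.floor}"
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults ARE the emulated study conditions."""

    racers: Mapping[str, RacerSpec] = field(
        default_factory=lambda: {
            "C": RacerSpec(),
            "O": RacerSpec(),
            "M": RacerSpec(),
            "CO": RacerSpec(),
            "MO": RacerSpec(),
            # no CM racer: V1 has no color-motion conjunctive cells
        }
    )
    n_trials: int = 320
    n_subjects: int = 8
    seed: int | None = None
    error_rate: float = 0.03
    outlier_rate: float = 0.02

    def __post_init__(self) -> None:
        for name, rate in (("error_rate", self.error_rate), ("outlier_rate", self.outlier_rate)):
            if not 0 <= rate <= 0.2:
                raise ValueError(f"{name} must be in [0, 0.2]")
        for cond in SINGLE_CONDITIONS:
            if cond not in self.racers:
                raise ValueError(f"single racer {cond} is required")

    def race_members(self, double_condition: str) -> list[str]:
        """Racers participating in one double condition's race."""
        a, b = RACE_SINGLES[double_condition]
        members = [a, b]
        if double_condition in self.racers:
            members.append(double_condition)
        return members


@dataclass(frozen=True)
class GroundTruth:
    """Continuous-limit contributions and racer moments of a generator config."""

    contributions: Mapping[str, Mapping[str, float]]  # per double condition
    racer_means: Mapping[str, float]
    racer_sds: Mapping[str, float]

    def to_dict(self) -> dict:
        return {
            "contributions": {k: dict(v) for k, v in self.contributions.items()},
            "racer_means": dict(self.racer_means),
            "racer_sds": dict(self.racer_sds),
        }


def true_contributions(config: SyntheticConfig, n_mc: int = 100_000, seed=None) -> GroundTruth:
    """Monte-Carlo continuous-limit contributions (probability each racer is
    strictly smallest; ties have measure zero for continuous families)."""
    if n_mc < 10_000:
        raise ValueError("n_mc must be >= 10_000 for a stable estimate")
    for cond, spec in config.racers.items():
        if spec.family == "empirical_table":
            raise ValueError(
                f"{cond}: empirical_table has atoms; use the discrete race "
                "(race_core.win_probabilities) instead"
            )
    rng = np.random.default_rng(seed)
    contribs: dict[str, dict[str, float]] = {}
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for cond, spec in config.racers.items():
        x = sample_racer_rts(spec, n_mc, rng)
        means[cond] = float(x.mean())
        sds[cond] = float(x.std(ddof=1))
    for dc in DOUBLE_CONDITIONS:
        a, b = RACE_SINGLES[dc]
        draws = {
            m: sample_racer_rts(config.racers[m], n_mc, rng)
            for m in config.race_members(dc)
        }
        stacked = np.vstack([draws[m] for m in draws])
        winner = np.argmin(stacked, axis=0)
        keys = list(draws)
        c = {f"c_{'conj' if k in DOUBLE_CONDITIONS else k}": float((winner == i).mean())
             for i, k in enumerate(keys)}
        entry = {
            "c_first": c.get(f"c_{a}", 0.0),
            "c_second": c.get(f"c_{b}", 0.0),
            "c_conj": c.get("c_conj", 0.0),
        }
        contribs[dc] = entry
    return GroundTruth(contribs, means, sds)


def _inject_artifacts(
    rts: np.ndarray, spec: RacerSpec, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Flip some trials to errors and push some RTs far into the outlier range."""
    n = rts.size
    correct = np.ones(n, dtype=bool)
    if config.error_rate > 0:
        correct[rng.random(n) < config.error_rate] = False
    rts = rts.copy()
    if config.outlier_rate > 0:
        out = rng.random(n) < config.outlier_rate
        # additive 1.5-3 s: far beyond mean + 3 SD even after the outliers
        # themselves inflate the sample SD
        rts[out] = rts[out] + rng.uniform(1.5, 3.0, size=int(out.sum()))
    return rts, correct


def generate_dataset(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[dict[str, SubjectDataset], GroundTruth]:
    """Generate per-subject trial tables plus the generator's ground truth.

    Every double condition's RT is the per-trial minimum over its racers'
    independent draws.  Subjects are i.i.d. replicates of the same config
    (the racer specs do not vary across subjects).
    """
    root = np.random.SeedSequence(config.seed if config.seed is not None else 0)
    truth_seed, *subject_seeds = root.spawn(config.n_subjects + 1)
    truth = true_contributions(config, seed=truth_seed.generate_state(1)[0])

    datasets: dict[str, SubjectDataset] = {}
    for s, sseq in enumerate(subject_seeds, start=1):
        rng = np.random.default_rng(sseq)
        sid = f"S{s:02d}"
        frames = []
        for cond in SINGLE_CONDITIONS:
            rts = sample_racer_rts(config.racers[cond], config.n_trials, rng)
            rts, correct = _inject_artifacts(rts, config.racers[cond], config, rng)
            frames.append(pd.DataFrame(
                {"subject": sid, "condition": cond, "rt": rts, "correct": correct}
            ))
        for dc in DOUBLE_CONDITIONS:
            members = config.race_members(dc)
            draws = np.vstack(
                [sample_racer_rts(config.racers[m], config.n_trials, rng) for m in members]
            )
            rts = draws.min(axis=0)
            rts, correct = _inject_artifacts(rts, config.racers[members[0]], config, rng)
            frames.append(pd.DataFrame(
                {"subject": sid, "condition": dc, "rt": rts, "correct": correct}
            ))
        datasets[sid] = SubjectDataset(sid, pd.concat(frames, ignore_index=True))
    return datasets, truth


def discretized_truth(
    config: SyntheticConfig, grid: BinGrid, double_condition: str, tie_credit: str = "full"
):
    """Grid-level oracle: contributions from the racers' exact binned
    distributions on ``grid`` -- what a perfect fit at this resolution
    would recover (includes the finite-bin tie excess)."""
    from racewin.race_core import win_probabilities

    a, b = RACE_SINGLES[double_condition]
    pa = config.racers[a].bin_probabilities(grid)
    pb = config.racers[b].bin_probabilities(grid)
    if double_condition in config.racers:
        pc = config.racers[double_condition].bin_probabilities(grid)
    else:
        pc = np.zeros(grid.n_bins)
        pc[-1] = 1.0  # reservoir-only: never wins
    return win_probabilities(pa, pb, pc, tie_credit)
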