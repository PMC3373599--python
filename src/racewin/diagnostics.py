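"""Fit-consistency index and bootstrap uncertainty for the racer estimates.

Consistency: after fitting, the model-implied winner distribution of each
double condition should match the observed RT histogram of that condition
(and each fitted single distribution should match its observed histogram).
The mismatch is the Kullback-Leibler divergence from the empirical
distribution to the model one, normalized by the empirical entropy:
``k = KL(q || p) / H(q)``.  Small k (well under 0.1) means the fit
reproduces the data; k = 0 iff the two distributions coincide.

Uncertainty: a percentile bootstrap.  Each condition's empirical CDF is
approximated by a piecewise-linear interpolant through the sorted sample
(knot k at height (k - 0.5)/n, anchored at 0 and 1 just outside the sample
range); new samples of the original size are drawn by inverse-CDF sampling
and the full pipeline (binning, fit, contributions) is rerun per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from racewin.binning import bin_rts, make_bin_grid
from racewin.constants import CONDITIONS, DOUBLE_CONDITIONS, SINGLE_CONDITIONS
from racewin.inference import FitConfig, FitResult, fit_model
from racewin.race_core import as_distribution
from racewin.rt_data import SubjectDataset

__all__ = [
    "ConsistencyResult",
    "BootstrapResult",
    "empirical_distribution",
    "consistency_index",
    "piecewise_linear_cdf_sampler",
    "bootstrap_intervals",
]

_CDF_MARGIN = 0.0001  # seconds outside the sample range for the 0/1 anchors

#: warn-only threshold above which a fit is reported as inconsistent
CONSISTENCY_WARN_THRESHOLD = 0.1


@dataclass(frozen=True)
class ConsistencyResult:
    """Normalized KL fit-consistency index (all quantities in nats)."""

    kl: float
    entropy: float
    k: float
    support_mismatch: bool = False  # empirical mass where the model had (floored) zero

    def to_dict(self) -> dict:
        return {
            "kl": self.kl,
            "entropy": self.entropy,
            "k": self.k,
            "support_mismatch": self.support_mismatch,
        }


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile intervals over bootstrap replicates.

    ``dist_lower``/``dist_upper`` bound each racer distribution's per-bin
    probability; ``contribution_lower``/``contribution_upper`` bound the win
    probabilities of each double condition's racers.
    """

    n_reps: int
    percentiles: tuple[float, float]
    dist_lower: Mapping[str, np.ndarray] = field(repr=False)
    dist_upper: Mapping[str, np.ndarray] = field(repr=False)
    contribution_lower: Mapping[str, Mapping[str, float]] = field(repr=False)
    contribution_upper: Mapping[str, Mapping[str, float]] = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "percentiles": list(self.percentiles),
            "dist_lower": {k: v.tolist() for k, v in self.dist_lower.items()},
            "dist_upper": {k: v.tolist() for k, v in self.dist_upper.items()},
            "contribution_lower": {k: dict(v) for k, v in self.contribution_lower.items()},
            "contribution_upper": {k: dict(v) for k, v in self.contribution_upper.items()},
        }


def empirical_distribution(counts: np.ndarray) -> np.ndarray:
    """Relative frequencies n_i / sum(n) -- the unbiased per-bin estimate."""
    n = np.asarray(counts, dtype=float)
    total = n.sum()
    if total <= 0:
        raise ValueError("counts sum to zero")
    if (n < 0).any():
        raise ValueError("negative counts")
    return n / total


def consistency_index(
    empirical: np.ndarray,
    model: np.ndarray,
    prob_floor: float = 1e-12,
) -> ConsistencyResult:
    """``k = KL(empirical || model) / H(empirical)`` with 0 log 0 = 0.

    The model distribution is floored at ``prob_floor`` inside the log; if
    empirical mass sits on a floored bin the result carries
    ``support_mismatch=True``.  Raises on a point-mass empirical
    distribution (zero entropy makes the ratio undefined).
    """
    q = as_distribution(empirical)
    p = as_distribution(model)
    if q.size != p.size:
        raise ValueError("distributions must share one grid")
    pos = q > 0
    mismatch = bool((p[pos] < prob_floor).any())
    kl = float(np.sum(q[pos] * np.log(q[pos] / np.maximum(p[pos], prob_floor))))
    entropy = float(-np.sum(q[pos] * np.log(q[pos])))
    if entropy == 0.0:
        raise ValueError("empirical distribution is a point mass; k undefined")
    kl = max(kl, 0.0)
    k = kl / entropy
    if k > CONSISTENCY_WARN_THRESHOLD:
        warnings.warn(f"consistency index k = {k:.3f} exceeds {CONSISTENCY_WARN_THRESHOLD}")
    return ConsistencyResult(kl=kl, entropy=entropy, k=k, support_mismatch=mismatch)


def fit_consistency(
    counts, fit: FitResult, prob_floor: float = 1e-12
) -> dict[str, ConsistencyResult]:
    """Consistency index for every condition: empirical histogram vs the
    fitted single distribution (singles) or fitted race winner (doubles)."""
    out = {}
    for cond in CONDITIONS:
        if cond not in counts.counts:
            continue
        q = empirical_distribution(counts.counts[cond])
        if cond in SINGLE_CONDITIONS:
            p = fit.params[cond]
        else:
            p = fit.params.race_distribution(cond)
        out[cond] = consistency_index(q, p, prob_floor)
    return out


def piecewise_linear_cdf_sampler(sample: np.ndarray):
    """Inverse-CDF sampler for the piecewise-linear empirical CDF.

    Knots: F = 0 at min(sample) - 0.0001 s, F = (k - 0.5)/n at the k-th
    order statistic, F = 1 at max(sample) + 0.0001 s, linearly interpolated.
    Returns ``draw(n, rng) -> ndarray``.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    heights = np.concatenate(([0.0], (np.arange(1, n + 1) - 0.5) / n, [1.0]))
    knots = np.concatenate(([x[0] - _CDF_MARGIN], x, [x[-1] + _CDF_MARGIN]))

    def draw(m: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(m)
        return np.interp(u, heights, knots)

    return draw


def bootstrap_intervals(
    dataset: SubjectDataset,
    n_bins: int = 10,
    fit_config: FitConfig = FitConfig(),
    n_reps: int = 500,
    seed: int | None = None,
    percentiles: tuple[float, float] = (2.5, 97.5),
    point_fit: FitResult | None = None,
) -> BootstrapResult:
    """Percentile bootstrap of the full pipeline on one cleaned subject.

    Per replicate: resample each condition (original trial count) from its
    piecewise-linear CDF, rebuild the pooled grid, refit, recompute
    contributions.  Replicate fits warm-start from the subject's point fit
    (one restart), which keeps 500 replicates tractable.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    conditions = dataset.conditions
    samplers = {}
    n_orig = {}
    for cond in conditions:
        rts = dataset.rts(cond)
        if np.unique(rts).size < 2:
            # degenerate: resamples collapse to (near) the same values
            pass
        samplers[cond] = piecewise_linear_cdf_sampler(rts)
        n_orig[cond] = rts.size

    if point_fit is None:
        grid0 = make_bin_grid(dataset.pooled_rts(), n_bins)
        from racewin.binning import BinnedCounts

        counts0 = BinnedCounts(grid0, {c: bin_rts(dataset.rts(c), grid0) for c in conditions})
        point_fit = fit_model(counts0, fit_config)

    warm_config = FitConfig(
        max_iterations=fit_config.max_iterations,
        tolerance=fit_config.tolerance,
        n_restarts=1,
        seed=fit_config.seed,
        prob_floor=fit_config.prob_floor,
    )

    dist_reps: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    contrib_reps: dict[str, dict[str, list[float]]] = {
        dc: {"c_first": [], "c_second": [], "c_conj": [], "joint_win_prob": []}
        for dc in DOUBLE_CONDITIONS
        if dc in conditions
    }
    from racewin.binning import BinnedCounts

    for _ in range(n_reps):
        resampled = {c: samplers[c](n_orig[c], rng) for c in conditions}
        pooled = np.concatenate(list(resampled.values()))
        grid = make_bin_grid(pooled, n_bins)
        counts = BinnedCounts(grid, {c: bin_rts(resampled[c], grid) for c in conditions})
        init = _transfer_params(point_fit, grid)
        fit = fit_model(counts, warm_config, init_params=init)
        for cond in CONDITIONS:
            dist_reps[cond].append(fit.params[cond])
        for dc in contrib_reps:
            c = fit.params.contributions(dc)
            for key, val in c.as_dict().items():
                contrib_reps[dc][key].append(val)

    lo, hi = percentiles
    dist_lower = {c: np.percentile(np.vstack(v), lo, axis=0) for c, v in dist_reps.items()}
    dist_upper = {c: np.percentile(np.vstack(v), hi, axis=0) for c, v in dist_reps.items()}
    contribution_lower = {
        dc: {k: float(np.percentile(v, lo)) for k, v in d.items()}
        for dc, d in contrib_reps.items()
    }
    contribution_upper = {
        dc: {k: float(np.percentile(v, hi)) for k, v in d.items()}
        for dc, d in contrib_reps.items()
    }
    return BootstrapResult(
        n_reps=n_reps,
        percentiles=percentiles,
        dist_lower=dist_lower,
        dist_upper=dist_upper,
        contribution_lower=contribution_lower,
        contribution_upper=contribution_upper,
    )


def _transfer_params(fit: FitResult, grid) -> "ModelParameters":
    """Carry a fit's distributions onto a replicate grid of the same size."""
    from racewin.inference import ModelParameters

    return ModelParameters(grid, dict(fit.params.dists))
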