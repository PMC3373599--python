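"""Per-subject RT discretization.

RTs from all six conditions of a subject are pooled and split into N bins:
the first N-1 bins hold roughly equal pooled counts, and the last bin is an
infinite "reservoir" [t_{N-1}, inf) that contains no observed RT.  The
reservoir absorbs the probability mass of hidden long conjunctive-racer RTs
that never win a race and therefore never surface in behavior.

Boundaries: t_0 = min(RT) - 0.0001 s, t_{N-1} = max(RT) + 0.0001 s,
t_N = inf; interior boundaries sit midway between consecutive order
statistics of the pooled sample.  Bins are half-open intervals
(t_{i-1}, t_i].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["BinGrid", "BinnedCounts", "make_bin_grid", "bin_rts"]

_EDGE_MARGIN = 0.0001  # seconds beyond the observed extremes


class BinningError(ValueError):
    """The requested grid cannot be built from the given sample."""


@dataclass(frozen=True)
class BinGrid:
    """Bin boundaries t_0 < t_1 < ... < t_{N-1} < t_N = inf (seconds)."""

    boundaries: np.ndarray  # length N + 1, last entry inf

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        if b.ndim != 1 or b.size < 3:
            raise ValueError("need at least 3 boundaries (N >= 2 bins)")
        if not np.isinf(b[-1]) or b[-1] < 0:
            raise ValueError("last boundary must be +inf")
        if np.isinf(b[:-1]).any():
            raise ValueError("only the last boundary may be infinite")
        if not (np.diff(b) > 0).all():
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.boundaries.size - 1

    def to_dict(self) -> dict:
        finite = self.boundaries[:-1].tolist()
        return {"n_bins": self.n_bins, "boundaries": finite + ["inf"]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "BinGrid":
        b = [float(x) if x != "inf" else np.inf for x in d["boundaries"]]
        return cls(np.asarray(b))


@dataclass(frozen=True)
class BinnedCounts:
    """Integer RT counts per bin, keyed by condition, on one grid."""

    grid: BinGrid
    counts: Mapping[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        counts = {
            k: np.asarray(v, dtype=np.int64) for k, v in dict(self.counts).items()
        }
        for cond, n in counts.items():
            if n.shape != (self.grid.n_bins,):
                raise ValueError(
                    f"{cond}: count vector length {n.size} != n_bins {self.grid.n_bins}"
                )
            if (n < 0).any():
                raise ValueError(f"{cond}: negative counts")
        object.__setattr__(self, "counts", counts)

    def n_trials(self, condition: str) -> int:
        return int(self.counts[condition].sum())

    def replace(self, condition: str, counts: np.ndarray) -> "BinnedCounts":
        new = dict(self.counts)
        new[condition] = counts
        return BinnedCounts(self.grid, new)

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "counts": {k: v.tolist() for k, v in self.counts.items()},
        }


def make_bin_grid(pooled_rts: np.ndarray, n_bins: int = 10) -> BinGrid:
    """Build the equal-count grid from one subject's pooled RTs.

    The first ``n_bins - 1`` bins each receive (to within rounding) the same
    number of the pooled RT samples; the final bin is the empty reservoir.

    Raises
    ------
    BinningError
        If the sample has too few distinct values for strictly increasing
        boundaries (including the degenerate all-identical case).
    """
    x = np.sort(np.asarray(pooled_rts, dtype=float))
    if x.size == 0:
        raise BinningError("pooled_rts is empty")
    if n_bins < 2:
        raise BinningError("n_bins must be >= 2")
    n_content = n_bins - 1
    if np.unique(x).size < n_content:
        raise BinningError(
            f"only {np.unique(x).size} distinct RTs; cannot form {n_content} "
            "content bins — reduce n_bins"
        )
    edges = [x[0] - _EDGE_MARGIN]
    # interior boundaries midway between the k-th order statistic and its successor
    for j in range(1, n_content):
        k = int(round(j * x.size / n_content))
        k = min(max(k, 1), x.size - 1)
        edges.append(0.5 * (x[k - 1] + x[k]))
    edges.append(x[-1] + _EDGE_MARGIN)
    edges.append(np.inf)
    b = np.asarray(edges)
    if not (np.diff(b) > 0).all():
        raise BinningError(
            "duplicate bin boundaries (tied RTs at a split point) — reduce n_bins"
        )
    return BinGrid(b)


def bin_rts(rts: np.ndarray, grid: BinGrid) -> np.ndarray:
    """Assign RTs to bins (t_{i-1}, t_i]; returns the count vector.

    Raises
    ------
    BinningError
        If any RT falls at or below t_0 (a grid built from the pooled data
        covers every observed RT).
    """
    x = np.asarray(rts, dtype=float)
    if x.size == 0:
        return np.zeros(grid.n_bins, dtype=np.int64)
    b = grid.boundaries
    if (x <= b[0]).any():
        raise BinningError(f"RT at or below the grid floor t_0 = {b[0]:.4f} s")
    idx = np.searchsorted(b[1:-1], x, side="left")  # bin index in 0..N-1
    return np.bincount(idx, minlength=grid.n_bins).astype(np.int64)
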