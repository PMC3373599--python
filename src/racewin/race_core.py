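"""Exact algebra of the discrete minimum-race on a shared bin grid.

Each racer's RT is an independent draw from a discrete probability
distribution over the grid's bins; the behavioral RT is the bin of the
smallest draw.  Because bins are finite, two or three racers can land in the
same winning bin ("joint winners"); by default every joint winner receives
full credit, so the three contributions can sum to more than one -- the
excess equals the joint-win probability (counted once per extra winner).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "DiscreteDistribution",
    "Contributions",
    "as_distribution",
    "survivor",
    "race_min_distribution",
    "win_probabilities",
]

_ATOL = 1e-12

#: a distribution is simply a 1-D probability vector over the grid's bins
DiscreteDistribution = np.ndarray


def as_distribution(p: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Validate and return ``p`` as a probability vector.

    Entries must be non-negative (tiny optimizer-induced negatives below
    ``atol`` are clipped) and sum to 1 within ``atol``; the vector is
    renormalized to machine precision.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("distribution must be a non-empty 1-D vector")
    if (p < -atol).any():
        raise ValueError(f"negative probability: min = {p.min():.3e}")
    total = p.sum()
    if abs(total - 1.0) > atol:
        raise ValueError(f"probabilities sum to {total:.12f}, not 1")
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


@dataclass(frozen=True)
class Contributions:
    """Win probabilities of the racers of one double-feature race.

    ``c_first`` and ``c_second`` are the two single-feature racers (e.g. C
    and O for a CO target), ``c_conj`` the conjunctive racer.
    ``joint_win_prob`` is the probability that at least two racers tie for
    the winning bin; with full tie credit,
    ``c_first + c_second + c_conj >= 1`` with equality iff
    ``joint_win_prob == 0``.
    """

    c_first: float
    c_second: float
    c_conj: float
    joint_win_prob: float

    def __post_init__(self) -> None:
        for name in ("c_first", "c_second", "c_conj", "joint_win_prob"):
            v = getattr(self, name)
            if not (-_ATOL <= v <= 1 + _ATOL):
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "c_first": self.c_first,
            "c_second": self.c_second,
            "c_conj": self.c_conj,
            "joint_win_prob": self.joint_win_prob,
        }


def survivor(dist: np.ndarray) -> np.ndarray:
    """Tail sums S_i = sum_{j >= i} p_j; S_1 = 1, non-increasing."""
    p = np.asarray(dist, dtype=float)
    s = np.cumsum(p[::-1])[::-1]
    s[0] = 1.0
    return s


def _check_shared_grid(dists: list[np.ndarray]) -> list[np.ndarray]:
    out = [np.asarray(d, dtype=float) for d in dists]
    n = out[0].size
    for d in out:
        if d.ndim != 1 or d.size != n:
            raise ValueError("all racers must share one grid (equal lengths)")
    return out


def race_min_distribution(*dists: np.ndarray) -> np.ndarray:
    """Distribution of the winning (minimum) bin of 2 or 3 independent racers.

    ``q_i = prod_k S_k(i) - prod_k S_k(i+1)`` with S_k(N+1) = 0.
    """
    if not 2 <= len(dists) <= 3:
        raise ValueError("race takes 2 or 3 racers")
    ds = _check_shared_grid(list(dists))
    # padded survivors: S_k over bins 1..N plus S_k(N+1) = 0
    prod = np.ones(ds[0].size + 1)
    for d in ds:
        prod[:-1] *= survivor(d)
    prod[-1] = 0.0
    q = prod[:-1] - prod[1:]
    q = np.clip(q, 0.0, None)
    return q / q.sum()


def win_probabilities(
    first: np.ndarray,
    second: np.ndarray,
    conj: np.ndarray,
    tie_credit: str = "full",
) -> Contributions:
    """Each racer's probability of winning (dictating saliency).

    A racer wins bin-wise: it wins if no other racer lands in an earlier
    bin.  ``tie_credit="full"`` (default) gives every joint winner full
    credit, matching the convention that finite bins make the contributions
    sum to more than one; ``"fractional"`` splits a tie evenly among the
    joint winners, so the contributions sum to exactly one.
    """
    if tie_credit not in ("full", "fractional"):
        raise ValueError("tie_credit must be 'full' or 'fractional'")
    ds = _check_shared_grid([first, second, conj])
    n = ds[0].size
    # survivors shifted by one bin: probability of landing strictly later than i
    later = [np.append(survivor(d)[1:], 0.0) for d in ds]
    c = np.zeros(3)
    joint = 0.0
    # partition by the exact set W of racers achieving the minimum bin
    for size in (1, 2, 3):
        for w in combinations(range(3), size):
            rest = [k for k in range(3) if k not in w]
            p_w = np.ones(n)
            for k in w:
                p_w = p_w * ds[k]
            for k in rest:
                p_w = p_w * later[k]
            p_event = p_w.sum()
            if size >= 2:
                joint += p_event
            credit = p_event if tie_credit == "full" else p_event / size
            for k in w:
                c[k] += credit
    return Contributions(
        c_first=float(c[0]),
        c_second=float(c[1]),
        c_conj=float(c[2]),
        joint_win_prob=float(joint),
    )
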