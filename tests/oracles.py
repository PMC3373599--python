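"""Independent brute-force oracles for the discrete race.

These enumerate every joint bin-index outcome directly and never touch the
survivor-product algebra they are used to check.
"""

from itertools import product

import numpy as np


def brute_force_race_min(dists):
    """Winner-bin distribution by enumerating all index tuples."""
    n = len(dists[0])
    q = np.zeros(n)
    for idx in product(range(n), repeat=len(dists)):
        p = 1.0
        for d, i in zip(dists, idx):
            p *= d[i]
        q[min(idx)] += p
    return q


def brute_force_win_probabilities(dists, tie_credit="full"):
    """Per-racer win probability and joint-win probability by enumeration."""
    n = len(dists[0])
    k = len(dists)
    c = np.zeros(k)
    joint = 0.0
    for idx in product(range(n), repeat=k):
        p = 1.0
        for d, i in zip(dists, idx):
            p *= d[i]
        m = min(idx)
        winners = [j for j in range(k) if idx[j] == m]
        if len(winners) > 1:
            joint += p
        for j in winners:
            c[j] += p if tie_credit == "full" else p / len(winners)
    return c, joint
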