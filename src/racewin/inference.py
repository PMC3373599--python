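"""Joint maximum-likelihood estimation of the six racer RT distributions.

The data are multinomial bin counts for the six target conditions of one
subject.  Single-feature counts (C, O, M) are draws from their racer's
distribution directly; double-feature counts (CO, MO, CM) are draws from
the minimum-race winner distribution of the two corresponding single racers
plus the conjunctive racer.  All six distributions are fitted jointly by
minimizing the negative log likelihood under simplex constraints (each
distribution non-negative and normalized), so the single racers are shared
across races: P_C is constrained simultaneously by the C, CO and CM counts.

A simplifying attribution is built into the likelihood exactly as the race
model states it: conjunctive racers never dictate single-feature RTs, so
the single-feature terms involve only the single racer.  The recovered
conjunctive contribution is therefore the *additional* contribution beyond
any share silently absorbed into the single racers.

The simplex is handled with explicit equality constraints and bounds (SLSQP)
rather than a softmax reparameterization, so boundary solutions -- in
particular conjunctive mass pinned in the reservoir bin -- are reachable
exactly.  Analytic gradients keep repeated refits (chance-level Monte Carlo,
bootstrap) fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from racewin.binning import BinGrid, BinnedCounts
from racewin.constants import CONDITIONS, DOUBLE_CONDITIONS, RACE_SINGLES, SINGLE_CONDITIONS
from racewin.race_core import Contributions, race_min_distribution, survivor, win_probabilities

__all__ = [
    "ModelParameters",
    "FitConfig",
    "FitResult",
    "FitError",
    "negative_log_likelihood",
    "nll_gradient",
    "initialize_params",
    "fit_model",
]


class FitError(RuntimeError):
    """The optimizer failed on every restart; carries best-effort params."""

    def __init__(self, message: str, result: "FitResult | None" = None):
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class ModelParameters:
    """The six racer distributions P_C, P_O, P_M, P_CO, P_MO, P_CM on one grid."""

    grid: BinGrid
    dists: Mapping[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        dists = {k: np.asarray(v, dtype=float) for k, v in dict(self.dists).items()}
        n = self.grid.n_bins
        for cond in CONDITIONS:
            if cond not in dists:
                raise ValueError(f"missing distribution for condition {cond}")
            p = dists[cond]
            if p.shape != (n,):
                raise ValueError(f"{cond}: length {p.size} != n_bins {n}")
            if (p < -1e-9).any() or abs(p.sum() - 1) > 1e-9:
                raise ValueError(f"{cond}: not a probability vector")
            dists[cond] = np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()
        object.__setattr__(self, "dists", dists)

    def __getitem__(self, cond: str) -> np.ndarray:
        return self.dists[cond]

    def race_distribution(self, double_condition: str) -> np.ndarray:
        """Model-implied winner distribution for one double condition."""
        a, b = RACE_SINGLES[double_condition]
        return race_min_distribution(self[a], self[b], self[double_condition])

    def contributions(self, double_condition: str, tie_credit: str = "full") -> Contributions:
        a, b = RACE_SINGLES[double_condition]
        return win_probabilities(self[a], self[b], self[double_condition], tie_credit)

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "dists": {k: v.tolist() for k, v in self.dists.items()},
        }


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings.

    ``prob_floor`` is the epsilon inside the logs, keeping the NLL finite
    when a count lands in a zero-probability bin.
    """

    max_iterations: int = 2000
    tolerance: float = 1e-9
    n_restarts: int = 5
    seed: int | None = None
    prob_floor: float = 1e-12
    init_smoothing: float = 1e-3
    jitter_weight: float = 0.3

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if not (0 < self.prob_floor <= 1e-6):
            raise ValueError("prob_floor must be in (0, 1e-6]")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    params: ModelParameters
    nll: float
    converged: bool
    restart_nlls: np.ndarray
    n_iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "nll": self.nll,
            "converged": self.converged,
            "restart_nlls": np.asarray(self.restart_nlls).tolist(),
            "n_iterations": self.n_iterations,
        }


def _race_conditions(conditions: Sequence[str]) -> list[str]:
    return [c for c in conditions if c in DOUBLE_CONDITIONS]


def negative_log_likelihood(
    params: ModelParameters,
    counts: BinnedCounts,
    prob_floor: float = 1e-12,
    conditions: Sequence[str] | None = None,
) -> float:
    """Multinomial NLL of the binned counts under the race model (natural log).

    ``conditions`` restricts the sum to a subset of the six terms (used by
    partial refits); default is every condition present in ``counts``.
    """
    if conditions is None:
        conditions = [c for c in CONDITIONS if c in counts.counts]
    nll = 0.0
    for cond in conditions:
        n = counts.counts[cond]
        if (n < 0).any():
            raise ValueError(f"{cond}: negative counts")
        p = params[cond] if cond in SINGLE_CONDITIONS else params.race_distribution(cond)
        nll -= float(n @ np.log(np.maximum(p, prob_floor)))
    return nll


def _single_grad(p: np.ndarray, n: np.ndarray, floor: float) -> np.ndarray:
    g = np.zeros_like(p)
    ok = p > floor
    g[ok] = -n[ok] / p[ok]
    # counts in floored bins: d/dp log(floor) = 0 there
    return g


def _race_grads(
    pa: np.ndarray, pb: np.ndarray, pc: np.ndarray, n: np.ndarray, floor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of -sum_i n_i log q_i w.r.t. the three racer vectors.

    q_i = prod_k S_k(i) - prod_k S_k(i+1);
    dq_i/dp_k(j) = [j>=i] R_k(i) - [j>=i+1] R_k(i+1) with
    R_k(i) = prod_{l != k} S_l(i) and R_k(N+1) = 0; cumulative sums give the
    whole gradient in O(N).
    """
    survs = [survivor(pa), survivor(pb), survivor(pc)]
    prod = survs[0] * survs[1] * survs[2]
    prod_next = np.append(prod[1:], 0.0)
    q = np.clip(prod - prod_next, 0.0, None)
    g = np.where(q > floor, n / np.maximum(q, floor), 0.0)
    grads = []
    for k in range(3):
        r = np.ones_like(q)
        for l in range(3):
            if l != k:
                r *= survs[l]
        r_next = np.append(r[1:], 0.0)  # R_k(i+1)
        cum_a = np.cumsum(g * r)  # sum_{i<=j} g_i R_k(i)
        cum_b = np.cumsum(g * r_next)  # sum_{i<=j} g_i R_k(i+1)
        grad = cum_a.copy()
        grad[1:] -= cum_b[:-1]  # subtract sum_{i<=j-1} g_i R_k(i+1)
        grads.append(-grad)
    return grads[0], grads[1], grads[2]


def nll_gradient(
    params: ModelParameters,
    counts: BinnedCounts,
    prob_floor: float = 1e-12,
    conditions: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Analytic gradient of the NLL w.r.t. each racer distribution."""
    if conditions is None:
        conditions = [c for c in CONDITIONS if c in counts.counts]
    n_bins = params.grid.n_bins
    grad = {c: np.zeros(n_bins) for c in CONDITIONS}
    for cond in conditions:
        n = counts.counts[cond].astype(float)
        if cond in SINGLE_CONDITIONS:
            grad[cond] += _single_grad(params[cond], n, prob_floor)
        else:
            a, b = RACE_SINGLES[cond]
            ga, gb, gc = _race_grads(params[a], params[b], params[cond], n, prob_floor)
            grad[a] += ga
            grad[b] += gb
            grad[cond] += gc
    return grad


def initialize_params(
    counts: BinnedCounts,
    seed: int | None = None,
    jitter_weight: float = 0.0,
    smoothing: float = 1e-3,
) -> ModelParameters:
    """Starting point: smoothed empirical frequencies for the single racers,
    uniform distributions for the conjunctive racers.

    With ``jitter_weight > 0`` the start is mixed with a seeded Dirichlet
    draw (for optimizer restarts); the same seed reproduces the same start.
    """
    rng = np.random.default_rng(seed)
    n_bins = counts.grid.n_bins
    dists: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        if cond in SINGLE_CONDITIONS and cond in counts.counts:
            n = counts.counts[cond].astype(float)
            p = (n + smoothing) / (n.sum() + smoothing * n_bins)
        else:
            p = np.full(n_bins, 1.0 / n_bins)
        if jitter_weight > 0:
            p = (1 - jitter_weight) * p + jitter_weight * rng.dirichlet(np.ones(n_bins))
        dists[cond] = p
    return ModelParameters(counts.grid, dists)


def _pack(params: ModelParameters, free: Sequence[str]) -> np.ndarray:
    return np.concatenate([params[c] for c in free])


def _unpack(
    theta: np.ndarray, free: Sequence[str], base: ModelParameters, grid: BinGrid
) -> ModelParameters:
    n = grid.n_bins
    dists = dict(base.dists)
    for k, cond in enumerate(free):
        p = np.clip(theta[k * n : (k + 1) * n], 0.0, None)
        dists[cond] = p / p.sum()
    return ModelParameters(grid, dists)


def fit_model(
    counts: BinnedCounts,
    config: FitConfig = FitConfig(),
    free_dists: Sequence[str] | None = None,
    conditions: Sequence[str] | None = None,
    init_params: ModelParameters | None = None,
) -> FitResult:
    """Minimize the NLL over the racer distributions (simplex-constrained).

    Parameters
    ----------
    counts
        Binned counts of one subject on one grid.
    config
        Optimizer settings; restarts beyond the first use jittered starts.
    free_dists
        Distributions to optimize (default: all six).  The rest are held
        fixed at ``init_params`` -- this is how the chance-level procedure's
        race-only refit works.
    conditions
        Likelihood terms to include (default: all conditions in ``counts``).
    init_params
        Starting point (default: ``initialize_params``); also supplies the
        fixed distributions for partial fits.

    Returns the best restart; guarantees ``NLL(fit) <= NLL(start)``.
    """
    grid = counts.grid
    n_bins = grid.n_bins
    if free_dists is None:
        free_dists = list(CONDITIONS)
    if conditions is None:
        conditions = [c for c in CONDITIONS if c in counts.counts]
    base = init_params if init_params is not None else initialize_params(counts)
    floor = config.prob_floor

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        p = _unpack_raw(theta)
        nll = negative_log_likelihood(p, counts, floor, conditions)
        g = nll_gradient(p, counts, floor, conditions)
        return nll, np.concatenate([g[c] for c in free_dists])

    def _unpack_raw(theta: np.ndarray) -> ModelParameters:
        # no renormalization inside the optimizer: the equality constraints own it
        dists = dict(base.dists)
        for k, cond in enumerate(free_dists):
            dists[cond] = np.clip(theta[k * n_bins : (k + 1) * n_bins], 0.0, None)
        obj = object.__new__(ModelParameters)
        object.__setattr__(obj, "grid", grid)
        object.__setattr__(obj, "dists", dists)
        return obj

    n_free = len(free_dists)
    a_eq = np.zeros((n_free, n_free * n_bins))
    for k in range(n_free):
        a_eq[k, k * n_bins : (k + 1) * n_bins] = 1.0
    constraints = [
        {"type": "eq", "fun": lambda th: a_eq @ th - 1.0, "jac": lambda th: a_eq}
    ]
    bounds = [(0.0, 1.0)] * (n_free * n_bins)

    seed_seq = np.random.SeedSequence(config.seed if config.seed is not None else 0)
    child_seeds = seed_seq.generate_state(max(config.n_restarts - 1, 1))

    best: tuple[float, np.ndarray, bool, int] | None = None
    restart_nlls = []
    success_flags = []
    for r in range(config.n_restarts):
        if r == 0:
            start = base
        else:
            start = initialize_params(
                counts,
                seed=int(child_seeds[r - 1]),
                jitter_weight=config.jitter_weight,
                smoothing=config.init_smoothing,
            )
            # partial fits keep the fixed distributions from `base`
            dists = dict(base.dists)
            for cond in free_dists:
                dists[cond] = start[cond]
            start = ModelParameters(grid, dists)
        theta0 = _pack(start, free_dists)
        res = minimize(
            objective,
            theta0,
            jac=True,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": config.max_iterations, "ftol": config.tolerance},
        )
        nll_start = objective(theta0)[0]
        theta_hat = res.x if np.isfinite(res.fun) and res.fun <= nll_start else theta0
        nll_hat = min(res.fun, nll_start) if np.isfinite(res.fun) else nll_start
        restart_nlls.append(nll_hat)
        success_flags.append(bool(res.success))
        if best is None or nll_hat < best[0]:
            best = (nll_hat, theta_hat, bool(res.success), int(res.nit))

    assert best is not None
    nll_best, theta_best, success, nit = best
    params = _unpack(theta_best, free_dists, base, grid)
    nll_final = negative_log_likelihood(params, counts, floor, conditions)
    # SLSQP frequently exits with "positive directional derivative" AT the
    # optimum; agreement of independent restarts is the practical certificate
    spread = float(np.max(restart_nlls) - np.min(restart_nlls))
    agreed = len(restart_nlls) >= 2 and spread <= 1e-6 * max(1.0, abs(nll_best))
    result = FitResult(
        params=params,
        nll=float(nll_final),
        converged=any(success_flags) or agreed,
        restart_nlls=np.asarray(restart_nlls),
        n_iterations=nit,
    )
    if not any(np.isfinite(restart_nlls)):
        raise FitError("optimizer failed on every restart", result)
    return result
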