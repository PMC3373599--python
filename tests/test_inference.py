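"""Likelihood, gradients and the joint constrained fit."""

import numpy as np
import pytest

import racewin as rw
from racewin.binning import BinGrid, BinnedCounts
from racewin.inference import (
    FitConfig,
    ModelParameters,
    fit_model,
    initialize_params,
    negative_log_likelihood,
    nll_gradient,
)


def _uniform_params(grid):
    n = grid.n_bins
    return ModelParameters(grid, {c: np.full(n, 1 / n) for c in rw.CONDITIONS})


def _grid(n):
    return BinGrid(np.concatenate([np.linspace(0.3, 1.0, n), [np.inf]]))


class TestNLL:
    def test_zero_counts_zero_nll(self):
        grid = _grid(4)
        counts = BinnedCounts(grid, {c: np.zeros(4, int) for c in rw.CONDITIONS})
        assert negative_log_likelihood(_uniform_params(grid), counts) == 0.0

    def test_two_bin_value(self):
        # C = (3,1) against (0.5, 0.5) and CO = (2,1) against the race winner
        # (0.875, 0.125) of three fair-coin racers
        grid = _grid(2)
        params = _uniform_params(grid)
        counts = BinnedCounts(
            grid,
            {
                "C": [3, 1], "O": [0, 0], "M": [0, 0],
                "CO": [2, 1], "MO": [0, 0], "CM": [0, 0],
            },
        )
        expected = 4 * np.log(2) + (-2 * np.log(0.875) - np.log(0.125))
        assert negative_log_likelihood(params, counts) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(5.11909, abs=1e-5)

    def test_depends_on_counts_only(self, binned_subject):
        _, grid, counts = binned_subject
        params = initialize_params(counts)
        v1 = negative_log_likelihood(params, counts)
        v2 = negative_log_likelihood(params, BinnedCounts(grid, dict(counts.counts)))
        assert v1 == v2

    def test_negative_counts_rejected(self):
        grid = _grid(2)
        with pytest.raises(ValueError):
            BinnedCounts(grid, {"C": [-1, 2]})


class TestGradient:
    def test_matches_finite_differences_on_simplex(self):
        """Analytic gradient agrees with numeric directional derivatives
        along zero-sum (simplex-tangent) directions."""
        rng = np.random.default_rng(3)
        grid = _grid(5)
        n = grid.n_bins
        counts = BinnedCounts(
            grid, {c: rng.integers(0, 40, size=n) for c in rw.CONDITIONS}
        )
        params = ModelParameters(grid, {c: rng.dirichlet(np.ones(n) * 5) for c in rw.CONDITIONS})
        grad = nll_gradient(params, counts)
        eps = 1e-7
        for cond in rw.CONDITIONS:
            for _ in range(4):
                d = rng.normal(size=n)
                d -= d.mean()  # stay on the simplex
                d /= np.linalg.norm(d)
                dists_p = dict(params.dists)
                dists_m = dict(params.dists)
                dists_p[cond] = params[cond] + eps * d
                dists_m[cond] = params[cond] - eps * d
                pp = object.__new__(ModelParameters)
                object.__setattr__(pp, "grid", grid)
                object.__setattr__(pp, "dists", dists_p)
                pm = object.__new__(ModelParameters)
                object.__setattr__(pm, "grid", grid)
                object.__setattr__(pm, "dists", dists_m)
                num = (
                    negative_log_likelihood(pp, counts)
                    - negative_log_likelihood(pm, counts)
                ) / (2 * eps)
                ana = float(grad[cond] @ d)
                assert ana == pytest.approx(num, rel=1e-5, abs=1e-5)


class TestInit:
    def test_single_init_tracks_empirical(self):
        grid = _grid(3)
        counts = BinnedCounts(grid, {"C": [5, 5, 0], "O": [1, 1, 1], "M": [1, 1, 1],
                                     "CO": [0, 0, 0], "MO": [0, 0, 0], "CM": [0, 0, 0]})
        params = initialize_params(counts)
        assert params["C"] == pytest.approx([0.5, 0.5, 0.0], abs=1e-3)
        assert params["CO"] == pytest.approx([1 / 3] * 3)

    def test_seeded_jitter_reproducible(self):
        grid = _grid(4)
        counts = BinnedCounts(grid, {c: [2, 3, 4, 1] for c in rw.CONDITIONS})
        a = initialize_params(counts, seed=7, jitter_weight=0.3)
        b = initialize_params(counts, seed=7, jitter_weight=0.3)
        for c in rw.CONDITIONS:
            assert np.array_equal(a[c], b[c])


class TestFit:
    def test_fit_beats_start_and_is_feasible(self, fitted_subject):
        _, _, counts, fit = fitted_subject
        start = initialize_params(counts)
        assert fit.nll <= negative_log_likelihood(start, counts) + 1e-9
        for c in rw.CONDITIONS:
            p = fit.params[c]
            assert (p >= -1e-12).all()
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert fit.converged

    def test_reported_nll_consistent(self, fitted_subject):
        _, _, counts, fit = fitted_subject
        assert fit.nll == pytest.approx(
            negative_log_likelihood(fit.params, counts), abs=1e-9
        )

    def test_fit_at_least_as_good_as_truth(self, default_config, binned_subject):
        """On model-generated data the MLE cannot be beaten by the truth."""
        _, grid, counts = binned_subject
        truth_dists = {}
        for c in rw.SINGLE_CONDITIONS:
            truth_dists[c] = default_config.racers[c].bin_probabilities(grid)
        for dc in rw.DOUBLE_CONDITIONS:
            if dc in default_config.racers:
                truth_dists[dc] = default_config.racers[dc].bin_probabilities(grid)
            else:
                p = np.zeros(grid.n_bins)
                p[-1] = 1.0
                truth_dists[dc] = p
        truth = ModelParameters(grid, truth_dists)
        fit = fit_model(counts, FitConfig(seed=0, n_restarts=3))
        assert fit.nll <= negative_log_likelihood(truth, counts) + 1e-6

    def test_single_distributions_shared_across_races(self, binned_subject):
        """Corrupting only the CM counts must perturb the fitted P_C, because
        P_C enters both the CO and CM races jointly."""
        _, grid, counts = binned_subject
        fit1 = fit_model(counts, FitConfig(seed=0, n_restarts=1))
        corrupted = counts.counts["CM"].copy()
        # remove the early CM mass: a deficit of fast double-target RTs is the
        # one corruption the free conjunctive racer cannot absorb, so the
        # likelihood must instead slow down the shared P_C
        moved = corrupted[:4].sum()
        corrupted[:4] = 0
        corrupted[-2] += moved
        counts2 = counts.replace("CM", corrupted)
        fit2 = fit_model(counts2, FitConfig(seed=0, n_restarts=1))
        assert np.abs(fit1.params["C"] - fit2.params["C"]).max() > 1e-3

    def test_parameter_recovery_moderate_n(self):
        """Multinomial draws (n = 5000/condition) from known distributions:
        singles recovered within TV 0.05, double-condition fits consistent
        (k <= 0.02)."""
        from racewin.diagnostics import fit_consistency

        rng = np.random.default_rng(11)
        grid = _grid(8)
        n = grid.n_bins
        truth = {}
        for c in rw.SINGLE_CONDITIONS:
            truth[c] = rng.dirichlet(np.ones(n) * 8)
        for dc in rw.DOUBLE_CONDITIONS:
            p = rng.dirichlet(np.ones(n - 1) * 8)
            truth[dc] = np.concatenate([p * 0.8, [0.2]])  # some reservoir mass
        params = ModelParameters(grid, truth)
        counts = {}
        for c in rw.SINGLE_CONDITIONS:
            counts[c] = rng.multinomial(5000, truth[c])
        for dc in rw.DOUBLE_CONDITIONS:
            counts[dc] = rng.multinomial(5000, params.race_distribution(dc))
        bc = BinnedCounts(grid, counts)
        fit = fit_model(bc, FitConfig(seed=1, n_restarts=3))
        for c in rw.SINGLE_CONDITIONS:
            tv = 0.5 * np.abs(fit.params[c] - truth[c]).sum()
            assert tv < 0.05
        for dc, res in fit_consistency(bc, fit).items():
            if dc in rw.DOUBLE_CONDITIONS:
                assert res.k <= 0.02
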