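"""The generator's calibration, determinism and ground-truth oracle."""

import numpy as np
import pytest
from scipy import stats

import racewin as rw
from racewin.synthetic_data import (
    RacerSpec,
    SyntheticConfig,
    generate_dataset,
    sample_racer_rts,
    true_contributions,
)


class TestRacerSampling:
    def test_seeded_determinism(self):
        spec = RacerSpec()
        assert np.array_equal(sample_racer_rts(spec, 50, 3), sample_racer_rts(spec, 50, 3))

    def test_configured_mean(self):
        x = sample_racer_rts(RacerSpec(location=0.600, scale=0.118), 100_000, 0)
        assert x.mean() == pytest.approx(0.600, abs=0.002)
        assert (x >= 0.2).all()

    def test_tiny_scale_degenerates_to_location(self):
        x = sample_racer_rts(RacerSpec(location=0.6, scale=1e-6), 100, 1)
        assert np.abs(x - 0.6).max() < 1e-4

    def test_unsatisfiable_truncation_raises(self):
        with pytest.raises(RuntimeError):
            sample_racer_rts(RacerSpec(location=0.01, scale=1e-4), 10, 0)

    def test_exgaussian_tail_shifts_mean(self):
        x = sample_racer_rts(RacerSpec(family="exgaussian", tail=0.1), 50_000, 2)
        assert x.mean() == pytest.approx(0.700, abs=0.005)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            RacerSpec(scale=-1)
        with pytest.raises(ValueError):
            RacerSpec(family="lognormal")
        with pytest.raises(ValueError):
            RacerSpec(family="empirical_table")


class TestGenerator:
    def test_single_target_means_around_600ms(self, cleaned_subject):
        """After removing the injected artifact trials the single-target
        means sit at the calibrated 600 ms."""
        ds, _ = cleaned_subject
        for cond in rw.SINGLE_CONDITIONS:
            m = ds.rts(cond).mean()
            assert m == pytest.approx(0.600, abs=0.025)

    def test_double_target_means_around_500ms(self, cleaned_subject):
        """Three matched racers racing: the minimum averages ~500 ms."""
        ds, _ = cleaned_subject
        for cond in ("CO", "MO"):
            assert ds.rts(cond).mean() == pytest.approx(0.500, abs=0.025)

    def test_cm_is_two_racer_race(self):
        """With no CM racer the CM condition matches a directly simulated
        two-racer minimum (two-sample KS)."""
        cfg = SyntheticConfig(seed=6, n_subjects=1, error_rate=0.0, outlier_rate=0.0)
        datasets, _ = generate_dataset(cfg)
        cm = datasets["S01"].rts("CM")
        rng = np.random.default_rng(123)
        ref = np.minimum(
            sample_racer_rts(cfg.racers["C"], 5000, rng),
            sample_racer_rts(cfg.racers["M"], 5000, rng),
        )
        assert stats.ks_2samp(cm, ref).pvalue > 0.01

    def test_dataset_determinism(self):
        cfg = SyntheticConfig(seed=9, n_subjects=2)
        d1, t1 = generate_dataset(cfg)
        d2, t2 = generate_dataset(cfg)
        for sid in d1:
            assert d1[sid].trials.equals(d2[sid].trials)
        assert t1.to_dict() == t2.to_dict()

    def test_all_conditions_and_counts(self, default_subject):
        ds, _ = default_subject
        for cond in rw.CONDITIONS:
            assert len(ds.rts(cond, correct_only=False)) == 320


class TestGroundTruth:
    def test_absent_conjunctive_is_exact_zero(self):
        cfg = SyntheticConfig(seed=1)
        truth = true_contributions(cfg, n_mc=20_000, seed=0)
        assert truth.contributions["CM"]["c_conj"] == 0.0

    def test_symmetric_racers_split_evenly(self):
        cfg = SyntheticConfig(seed=1)
        truth = true_contributions(cfg, n_mc=200_000, seed=0)
        for key in ("c_first", "c_second", "c_conj"):
            assert truth.contributions["CO"][key] == pytest.approx(1 / 3, abs=0.01)

    def test_contributions_sum_to_one(self):
        cfg = SyntheticConfig(seed=1)
        truth = true_contributions(cfg, n_mc=50_000, seed=3)
        for dc in rw.DOUBLE_CONDITIONS:
            assert sum(truth.contributions[dc].values()) == pytest.approx(1.0, abs=1e-9)

    def test_asymmetric_racers_match_larger_mc(self):
        """A slower third racer's contributions agree with an independent
        large-sample brute-force estimate."""
        cfg = SyntheticConfig(
            racers={
                "C": RacerSpec(),
                "O": RacerSpec(),
                "M": RacerSpec(),
                "CO": RacerSpec(location=0.650),
            },
            seed=1,
        )
        truth = true_contributions(cfg, n_mc=100_000, seed=5)
        rng = np.random.default_rng(99)
        n = 1_000_000
        draws = np.vstack(
            [
                rng.normal(0.600, 0.118, n),
                rng.normal(0.600, 0.118, n),
                rng.normal(0.650, 0.118, n),
            ]
        )
        win = np.argmin(draws, axis=0)
        se = 3 * np.sqrt(0.35 * 0.65 / 100_000)
        assert truth.contributions["CO"]["c_first"] == pytest.approx((win == 0).mean(), abs=se)
        assert truth.contributions["CO"]["c_conj"] == pytest.approx((win == 2).mean(), abs=se)

    def test_empirical_table_atoms_rejected(self):
        cfg = SyntheticConfig(
            racers={
                "C": RacerSpec(family="empirical_table", table=(0.5, 0.6, 0.7)),
                "O": RacerSpec(),
                "M": RacerSpec(),
            },
            seed=1,
        )
        with pytest.raises(ValueError, match="atoms"):
            true_contributions(cfg, n_mc=10_000, seed=0)


def test_null_specificity_of_recovered_conjunctive():
    """With no conjunctive racer, the median recovered contribution across
    seeds stays within the chance band (mean + 2 SD of chance values).

    The band comes from the parametric two-racer bootstrap, which
    reproduces both noise sources of the recovered null contribution
    (double-sample noise and single-racer estimation error); the
    double-only convention underestimates the spread by construction.
    """
    from racewin.binning import BinnedCounts, bin_rts, make_bin_grid
    from racewin.inference import FitConfig, fit_model
    from racewin.rt_data import clean_trials
    from racewin.significance import chance_level

    recovered = []
    last = None
    for seed in range(8):
        cfg = SyntheticConfig(
            racers={"C": RacerSpec(), "O": RacerSpec(), "M": RacerSpec()},
            n_subjects=1,
            seed=500 + seed,
        )
        datasets, _ = generate_dataset(cfg)
        cleaned, _ = clean_trials(datasets["S01"])
        grid = make_bin_grid(cleaned.pooled_rts(), 10)
        counts = BinnedCounts(
            grid, {c: bin_rts(cleaned.rts(c), grid) for c in rw.CONDITIONS}
        )
        fit = fit_model(counts, FitConfig(seed=0, n_restarts=2))
        recovered.append(fit.params.contributions("CO").c_conj)
        last = (counts, fit)
    res = chance_level(*last, "CO", n_reps=80, seed=0, null_resample="parametric")
    band = res.mean_chance + 2 * res.chance_values.std()
    assert np.median(recovered) <= band


class TestLatentResponseMode:
    """RTs generated as a monotone decreasing map of a latent neural
    response; the race outcome must depend only on the response ordering."""

    def test_determinism_and_floor(self):
        spec = RacerSpec(family="latent_response")
        a = sample_racer_rts(spec, 100, 3)
        assert np.array_equal(a, sample_racer_rts(spec, 100, 3))
        assert (a >= spec.floor).all()

    def test_contributions_match_response_space(self):
        """With one shared map, the probability a racer wins the RT race
        equals the probability its response is largest."""
        specs = {
            "C": RacerSpec(family="latent_response", resp_mean=10.0),
            "O": RacerSpec(family="latent_response", resp_mean=10.0),
            "M": RacerSpec(family="latent_response", resp_mean=10.0),
            "CO": RacerSpec(family="latent_response", resp_mean=11.0),
        }
        cfg = SyntheticConfig(racers=specs, seed=0)
        truth = true_contributions(cfg, n_mc=200_000, seed=1)
        rng = np.random.default_rng(2)
        n = 500_000
        r = np.vstack([
            rng.normal(10.0, 2.0, n), rng.normal(10.0, 2.0, n), rng.normal(11.0, 2.0, n)
        ])
        resp_win = np.bincount(np.argmax(r, axis=0), minlength=3) / n
        assert truth.contributions["CO"]["c_first"] == pytest.approx(resp_win[0], abs=0.01)
        assert truth.contributions["CO"]["c_conj"] == pytest.approx(resp_win[2], abs=0.01)
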