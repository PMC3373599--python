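"""Shared fixtures: one default synthetic subject, cleaned and fitted once."""

import numpy as np
import pytest

import racewin as rw
from racewin.binning import BinnedCounts, bin_rts, make_bin_grid
from racewin.inference import FitConfig, fit_model
from racewin.rt_data import clean_trials
from racewin.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=42, n_subjects=1)


@pytest.fixture(scope="session")
def default_subject(default_config):
    datasets, truth = generate_dataset(default_config)
    return datasets["S01"], truth


@pytest.fixture(scope="session")
def cleaned_subject(default_subject):
    ds, _ = default_subject
    cleaned, report = clean_trials(ds)
    return cleaned, report


@pytest.fixture(scope="session")
def binned_subject(cleaned_subject):
    cleaned, _ = cleaned_subject
    grid = make_bin_grid(cleaned.pooled_rts(), 10)
    counts = BinnedCounts(grid, {c: bin_rts(cleaned.rts(c), grid) for c in rw.CONDITIONS})
    return cleaned, grid, counts


@pytest.fixture(scope="session")
def fitted_subject(binned_subject):
    cleaned, grid, counts = binned_subject
    fit = fit_model(counts, FitConfig(seed=0, n_restarts=3))
    return cleaned, grid, counts, fit


def random_distributions(rng, n_bins, k=3):
    """k random probability vectors on an n_bins grid."""
    return [rng.dirichlet(np.ones(n_bins)) for _ in range(k)]
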