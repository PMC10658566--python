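"""Shared fixtures: synthetic datasets generated once per session."""

import warnings

import pytest

from mnperm.synthetic_data import GeneratorConfig, data_s1_replica, generate_dataset


@pytest.fixture(scope="session")
def replica_records():
    """The 191-row synthetic permeation database replica."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return data_s1_replica(seed=11)


@pytest.fixture(scope="session")
def noiseless_records():
    """A small noiseless simulator-generated dataset (coarse grid)."""
    cfg = GeneratorConfig(seed=3, noise_sd=0.0, curves_per_drug=2, dx=50.0, dy=50.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        noisy, truth = generate_dataset(cfg)
    return noisy


@pytest.fixture(scope="session")
def noisy_records():
    """A small noisy simulator-generated dataset (coarse grid)."""
    cfg = GeneratorConfig(seed=5, noise_sd=0.15, curves_per_drug=2, dx=50.0, dy=50.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        noisy, truth = generate_dataset(cfg)
    return noisy, truth
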