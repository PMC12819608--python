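import numpy as np
import pytest

from ddikit import generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 24-drug cohort small enough for exhaustive checks."""
    return generate_cohort(n_drugs=24, n_modalities=3, dims=[8, 6, 5],
                           n_clusters=2, noise_sd=0.3, flip_prob=0.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-drug cohort with label noise for training smoke tests."""
    return generate_cohort(n_drugs=60, n_modalities=4, dims=[12, 8, 8, 8],
                           n_clusters=3, noise_sd=0.5, flip_prob=0.05, seed=3)
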