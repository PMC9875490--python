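import numpy as np
import pytest

from cabc import SimConfig, simulate_dataset
from cabc import pipeline


@pytest.fixture(scope="session")
def small_config():
    """A reduced two-condition dataset used by most integration tests."""
    return SimConfig(n_bins=200, n_genes=20, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_run(small_dataset):
    b1, b2, _truth = small_dataset
    return pipeline.analyze_pair(b1, b2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
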