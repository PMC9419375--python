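import numpy as np
import pytest

from spacerscan.simdata import SimConfig, simulate_ancestor


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_817)


@pytest.fixture
def small_config():
    """A genome small enough for fast per-test simulation."""
    return SimConfig(genome_length=30_000, n_initial_spacers=5, seed=11)


@pytest.fixture
def small_genome(small_config):
    return simulate_ancestor(small_config)
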