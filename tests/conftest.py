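import numpy as np
import pytest

from seedvigor import SimConfig, generate_spectra


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Default study conditions at a reduced per-group sample size."""
    return SimConfig(n_per_group=30, rng_seed=123)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ds, truth = generate_spectra(small_config)
    return ds, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
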