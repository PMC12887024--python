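import numpy as np
import pytest

from palmspec import GeneratorConfig, make_wavenumber_grid, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """40 samples x 256 channels: cheap stand-in for the full study dataset."""
    grid = make_wavenumber_grid(256, 500, 2000)
    return simulate_dataset(GeneratorConfig(n_per_market=8, seed=7), grid=grid)


@pytest.fixture(scope="session")
def tiny_grid():
    return make_wavenumber_grid(64, 500, 2000)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
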