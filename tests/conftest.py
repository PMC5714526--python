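import numpy as np
import pytest

from ybm42 import (
    RingDetectorGrid,
    SimulationConfig,
    build_default_m42,
    run_water_phantom,
)


@pytest.fixture(scope="session")
def m42():
    return build_default_m42()


@pytest.fixture(scope="session")
def grid():
    return RingDetectorGrid.default()


@pytest.fixture(scope="session")
def small_water_table(m42, grid):
    """A short water-phantom run shared by transport sanity tests."""
    cfg = SimulationConfig(n_histories=400_000, rng_seed=11, batch_count=10)
    return run_water_phantom(m42, grid, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
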