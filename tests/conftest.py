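import numpy as np
import pytest

from piezolab.synthetic import SyntheticConfig, with_seed


@pytest.fixture
def config():
    return SyntheticConfig()


@pytest.fixture
def small_config():
    """A fast configuration for pipeline round-trips."""
    return SyntheticConfig(
        seed=11,
        depths=(500.0, 1000.0, 2000.0, 4000.0),
        n_stations_per_depth=3,
        n_active_cells=400,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
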