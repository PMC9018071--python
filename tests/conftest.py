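import numpy as np
import pytest

from queenflux import SyntheticConfig


@pytest.fixture
def config():
    """Default generator configuration (the standard study conditions)."""
    return SyntheticConfig()


@pytest.fixture
def small_config():
    """A small, fast configuration for image-level tests."""
    return SyntheticConfig(n_cells=4, n_frames=5, image_size=64, cell_radius=6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
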