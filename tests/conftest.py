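import numpy as np
import pytest

from v1stereo import (ChannelSpec, StereoPair, build_frequency_grid,
                      compose_log_gabor, preprocess)


@pytest.fixture(scope="session")
def grid32():
    return build_frequency_grid(32, 32)


@pytest.fixture(scope="session")
def grid64():
    return build_frequency_grid(64, 64)


@pytest.fixture(scope="session")
def spec8():
    """A channel at f0 = 1/8 cycles/pixel (exact bin of the 32/64 grids)."""
    return ChannelSpec(orientation_deg=0.0, wavelength_px=8.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_pair(rng):
    """A preprocessed identical-left/right pair of filtered-friendly noise."""
    img = preprocess(rng.random((64, 64)))
    return StereoPair(left=img, right=img.copy())
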