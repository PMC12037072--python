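import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_u8(rng):
    """A 32x32 random 8-bit image."""
    return rng.integers(0, 256, (32, 32), dtype=np.uint8)


def smooth_u8(rng, shape=(64, 64), sigma=3.0):
    """Gaussian-smoothed random image spanning [0, 255] (uint8)."""
    f = ndimage.gaussian_filter(rng.uniform(0.0, 255.0, shape), sigma)
    f = (f - f.min()) / (f.max() - f.min()) * 255.0
    return np.round(f).astype(np.uint8)
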