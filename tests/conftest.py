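import numpy as np
import pytest

from patchent import IntensityImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image_8bit(rng):
    return IntensityImage(rng.integers(0, 256, (16, 16)).astype(np.int32), 8)


def make_random_image(rng, shape=(16, 16), bit_depth=8):
    top = (1 << bit_depth) - 1
    return IntensityImage(rng.integers(0, top + 1, shape).astype(np.int32), bit_depth)
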