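import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def complex_image(rng):
    def make(shape=(16, 16), seed=None):
        g = np.random.default_rng(seed) if seed is not None else rng
        return g.standard_normal(shape) + 1j * g.standard_normal(shape)

    return make
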