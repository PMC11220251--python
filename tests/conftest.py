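import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_images(rng):
    """Small random integer-valued images for oracle comparisons."""
    return [
        rng.integers(0, 256, size=(n, m)).astype(float)
        for n, m in [(16, 16), (16, 16), (24, 17), (32, 32), (9, 31)]
    ]
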