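import numpy as np
import pytest

from spheroquant.image import Image2D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_u8(rng):
    """A small random 8-bit image."""
    return Image2D(rng.integers(0, 256, size=(32, 32), dtype=np.uint8).astype(np.uint8))


def make_bimodal_histogram(rng, lo_mu=None, hi_mu=None, lo_n=6000, hi_n=4000):
    """Random well-separated bimodal 8-bit sample for threshold tests."""
    lo_mu = rng.uniform(30, 90) if lo_mu is None else lo_mu
    hi_mu = rng.uniform(150, 220) if hi_mu is None else hi_mu
    v = np.concatenate(
        [
            rng.normal(lo_mu, rng.uniform(5, 15), lo_n),
            rng.normal(hi_mu, rng.uniform(5, 15), hi_n),
        ]
    )
    return np.clip(v, 0, 255).astype(np.uint8)
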