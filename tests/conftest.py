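import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="skimage")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(8, 8), p=0.4, ensure_fg=True):
    """Random binary mask, guaranteed non-empty foreground by default."""
    m = (rng.random(shape) < p).astype(np.uint8)
    if ensure_fg and not m.any():
        m[shape[0] // 2, shape[1] // 2] = 1
    return m


def blob_mask(shape, top, bottom, left, right):
    m = np.zeros(shape, dtype=np.uint8)
    m[top:bottom, left:right] = 1
    return m
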