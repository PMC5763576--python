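import numpy as np
import pytest
from skimage.draw import disk as draw_disk


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_disk_mask(radius: int, pad: int = 10) -> np.ndarray:
    size = 2 * (radius + pad)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw_disk((size // 2, size // 2), radius)
    mask[rr, cc] = True
    return mask


def make_rect_mask(height: int, width: int, pad: int = 10) -> np.ndarray:
    mask = np.zeros((height + 2 * pad, width + 2 * pad), dtype=bool)
    mask[pad : pad + height, pad : pad + width] = True
    return mask


@pytest.fixture
def disk_mask():
    return make_disk_mask(50)


@pytest.fixture
def square_mask():
    return make_rect_mask(100, 100)
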