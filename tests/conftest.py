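import numpy as np
import pytest

from ccmorph.io import Calibration, DEFAULT_CALIBRATION
from ccmorph.segmentation import NerveMask


@pytest.fixture
def cal() -> Calibration:
    return DEFAULT_CALIBRATION


def make_mask(arr: np.ndarray, calibration: Calibration | None = None) -> NerveMask:
    """Wrap a boolean array in a NerveMask with a matching calibration."""
    arr = np.asarray(arr, dtype=bool)
    c = calibration or Calibration(400.0 / 384.0, arr.shape[1], arr.shape[0])
    return NerveMask(arr, c)


def bar_mask(height: int, width: int = 100, shape: tuple[int, int] = (40, 120),
             row: int | None = None, col0: int = 10) -> NerveMask:
    """Solid horizontal bar of the given pixel height inside a small field."""
    m = np.zeros(shape, dtype=bool)
    r = shape[0] // 2 if row is None else row
    top = r - height // 2
    m[top:top + height, col0:col0 + width] = True
    return make_mask(m)
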