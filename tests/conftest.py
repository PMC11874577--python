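import numpy as np
import pytest

from nucleomorph.core_io import Calibration, LabelMask


@pytest.fixture
def calibration():
    return Calibration(0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    """Binary digital disk: pixels whose centers lie within `radius`."""
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return ((yy - c) ** 2 + (xx - c) ** 2 <= radius**2).astype(np.uint8)


def ellipse_mask(a_px: float, b_px: float, pad: int = 3) -> np.ndarray:
    """Binary digital ellipse with semi-axes a (x) and b (y) in pixels."""
    n = 2 * (int(np.ceil(max(a_px, b_px))) + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    return (((xx - c) / a_px) ** 2 + ((yy - c) / b_px) ** 2 <= 1).astype(np.uint8)


@pytest.fixture
def two_square_mask(calibration):
    """Two disjoint labeled squares: 8 px (0.5 µm²·32) and 144 px (9 µm²)."""
    arr = np.zeros((40, 40), dtype=np.int32)
    arr[2:6, 2:6] = 1          # 16 px -> 1.0 µm²
    arr[20:32, 20:32] = 2      # 144 px -> 9.0 µm²
    return LabelMask(arr, calibration)
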