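import numpy as np
import pytest

from epiquant.geometry import PolylineROI
from epiquant.image import IntensityImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def disk_mask():
    """Disk of radius 20 px on a 50x50 grid (area 1257 px)."""
    yy, xx = np.mgrid[0:50, 0:50]
    return (xx - 24.5) ** 2 + (yy - 24.5) ** 2 <= 400


@pytest.fixture
def horizontal_line():
    return PolylineROI(np.array([[0.0, 10.0], [49.0, 10.0]]), closed=False)


@pytest.fixture
def random_image(rng):
    return IntensityImage(rng.random((21, 50)) * 100.0)
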