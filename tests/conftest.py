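import numpy as np
import pytest

from intensify3d import ImageStack, TissueDetectorConfig
from intensify3d.tissue_detector import TissueMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_stack():
    """Three constant planes at 50 ADU, 16-bit."""
    planes = [np.full((32, 32), 50, dtype=np.uint16) for _ in range(3)]
    return ImageStack(planes=planes, bit_depth=16)


@pytest.fixture
def all_tissue():
    def _make(shape):
        return TissueMask(grid=np.ones(shape, bool))

    return _make


@pytest.fixture
def disk_plane(rng):
    """Bright disk (mean 2000) on a dark surround (mean 100), mild noise."""
    h = w = 128
    yy, xx = np.mgrid[0:h, 0:w]
    truth = (xx - 64) ** 2 + (yy - 64) ** 2 <= 30**2
    plane = np.where(truth, 2000.0, 100.0) + rng.normal(0, 20, size=(h, w))
    return np.clip(plane, 0, 65535), truth


@pytest.fixture
def tissue_cfg():
    """Detector settings sized for the 128x128 test planes."""
    return TissueDetectorConfig(method="kmeans", downsample_factor=2, seed=0)
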