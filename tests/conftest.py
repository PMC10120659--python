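import numpy as np
import pytest

from stwarp.raster import PointSet, RasterImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cloud(rng):
    """~100 cells with features and labels on a ~2 mm domain."""
    coords = rng.uniform(0, 2000, size=(100, 2))
    feats = rng.poisson(5.0, size=(100, 6)).astype(float)
    labels = rng.integers(0, 4, size=100)
    return PointSet(coords, feats, labels, [f"g{i}" for i in range(6)])


@pytest.fixture
def smooth_image():
    """Single-channel smooth 2D test image on a physical grid."""
    dx = 40.0
    ax = [dx * (np.arange(24) + 0.5), dx * (np.arange(30) + 0.5)]
    yy, xx = np.meshgrid(*ax, indexing="ij")
    vals = np.exp(-((yy - 500) ** 2 + (xx - 620) ** 2) / (2 * 220**2))
    return RasterImage(vals[None], ax)
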