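import numpy as np
import pytest

from interactiveseg.imaging import SegmentationMask, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_cuboid_mask(shape, lo, hi, spacing=(1.0, 1.0, 1.0)):
    """Solid axis-aligned cuboid spanning [lo, hi] inclusive per axis."""
    labels = np.zeros(shape, dtype=np.uint8)
    labels[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = 1
    return SegmentationMask(labels, spacing)


def make_ellipsoid_mask(shape, center, semiaxes, spacing=(1.0, 1.0, 1.0)):
    """Analytic ellipsoid mask: voxel centers inside the ellipsoid (mm)."""
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    rel = np.stack(grids, axis=-1) - np.asarray(center, dtype=float)
    rho = ((rel / np.asarray(semiaxes, dtype=float)) ** 2).sum(axis=-1)
    return SegmentationMask((rho <= 1.0).astype(np.uint8), spacing)


@pytest.fixture
def cuboid_mask():
    return make_cuboid_mask((40, 40, 24), (10, 10, 5), (30, 30, 15))


@pytest.fixture
def random_volume(rng):
    return VolumeImage(rng.normal(size=(12, 14, 10)), (1.0, 1.0, 2.5))
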