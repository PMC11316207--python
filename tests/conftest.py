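import numpy as np
import pytest

from epvs.features import FilterBankConfig
from epvs.geometry import VoxelGeometry
from epvs.phantom import PhantomConfig, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return VoxelGeometry((0.6, 0.6, 1.5))


@pytest.fixture(scope="session")
def small_bank():
    """Reduced filter bank used by pipeline-level tests."""
    return FilterBankConfig(
        sf_sigmas_mm=(0.5, 1.0),
        ff_sigmas_mm=(0.6, 1.0, 1.8),
        oof_radii_mm=(0.6, 1.0, 1.8),
    )


@pytest.fixture(scope="session")
def phantom():
    """One deterministic small phantom shared across read-only tests."""
    return make_phantom(PhantomConfig(shape=(48, 48, 24)), np.random.default_rng(42))


def tube_volume(shape=(32, 32, 16), spacing=(0.6, 0.6, 1.5), radius_mm=1.0,
                axis=0, contrast=1.0, background=0.0):
    """A straight bright tube along a grid axis with Gaussian cross-section."""
    geometry = VoxelGeometry(spacing)
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    center = [n * s / 2 for n, s in zip(shape, spacing)]
    d2 = sum(
        (grids[i] - center[i]) ** 2 for i in range(3) if i != axis
    )
    img = background + contrast * np.exp(-d2 / (2 * radius_mm**2))
    return np.broadcast_to(img, shape).astype(np.float64).copy(), geometry
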