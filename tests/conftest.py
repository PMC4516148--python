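import numpy as np
import pytest

from fibroid3d.contour_segmentation import cross_plane_correct, propagate_segmentation
from fibroid3d.phantom import PhantomConfig, generate_phantom, simulate_key_slice_tracing


@pytest.fixture(scope="session")
def default_phantom():
    """Default anisotropic phantom (1.5 x 1.5 x 2 mm): volume + truth."""
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def iso_config():
    """1 mm isotropic phantom configuration (for sub-voxel-sensitive tests)."""
    return PhantomConfig(shape=(110, 80, 90), spacing=(1.0, 1.0, 1.0), seed=1)


@pytest.fixture(scope="session")
def iso_phantom(iso_config):
    return generate_phantom(iso_config)


@pytest.fixture(scope="session")
def iso_segmentation_step5(iso_phantom):
    """Corrected segmentation of the isotropic phantom traced every 5th slice."""
    _, truth = iso_phantom
    keyset = simulate_key_slice_tracing(truth, slice_step=5, jitter=0.0, seed=1)
    labelmap = propagate_segmentation(
        keyset, truth.labelmap.shape, truth.labelmap.spacing, truth.labelmap.origin
    )
    return keyset, cross_plane_correct(labelmap)


def voxelized_ball(radius: int, pad: int = 3) -> np.ndarray:
    """Binary ball of the given radius (voxels) on a unit grid."""
    n = radius + pad
    x, y, z = np.meshgrid(*[np.arange(-n, n + 1)] * 3, indexing="ij")
    return (x**2 + y**2 + z**2 <= radius**2).astype(float)
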