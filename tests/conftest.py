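import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from segcal.volumes import VolumeGrid

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_grid():
    """Small isotropic 1-mm grid for hand-checkable cases."""
    return VolumeGrid((9, 9, 9), (1.0, 1.0, 1.0))


@pytest.fixture
def aniso_grid():
    """Anisotropic grid with thick slices, (1, 1, 3) mm."""
    return VolumeGrid((12, 12, 8), (1.0, 1.0, 3.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_mask(rng, shape, p=0.3):
    return rng.random(shape) < p


def brute_force_distance_to_set(points_idx, grid, query_shape=None):
    """O(N * |S|) nearest-neighbour distances in mm from every voxel centre
    to a set of voxel centres; the independent oracle for distance fields."""
    shape = query_shape or grid.shape
    spacing = np.asarray(grid.spacing)
    pts = np.asarray(points_idx, dtype=float) * spacing  # (|S|, 3)
    out = np.empty(shape, dtype=float)
    for idx in np.ndindex(*shape):
        q = np.asarray(idx, dtype=float) * spacing
        out[idx] = np.sqrt(((pts - q) ** 2).sum(axis=1)).min()
    return out
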