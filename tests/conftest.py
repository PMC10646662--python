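import numpy as np
import pytest

from petrep import ImageVolume, LesionMask, PhantomConfig, generate_subject


def random_level_volume(rng, max_voxels=100, n_levels=5):
    """A random blob of discretised grey levels (0 = outside the region)."""
    shape = tuple(rng.integers(3, 6, size=3))
    levels = np.zeros(shape, dtype=np.int64)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    assert mask.sum() <= max_voxels
    return levels, n_levels


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_phantom():
    """One noisy textured subject on a reduced grid (shared, read-only)."""
    cfg = PhantomConfig(grid_shape=(64, 64, 48), n_lesions=2,
                        lesion_radius_range_mm=(8.0, 11.0), seed=42)
    image, masks, truth = generate_subject(cfg)
    return cfg, image, masks, truth


@pytest.fixture
def uniform_lesion():
    """A cuboid lesion of uniform SUV 4 in background 1 on a 2 mm grid."""
    values = np.ones((12, 12, 12))
    support = np.zeros((12, 12, 12), bool)
    support[3:9, 3:9, 3:9] = True
    values[support] = 4.0
    img = ImageVolume(values, (2.0, 2.0, 2.0))
    mask = LesionMask(support, "uniform", (2.0, 2.0, 2.0))
    return img, mask
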