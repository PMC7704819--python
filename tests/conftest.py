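import numpy as np
import pytest

from muscleseg import PhantomSpec, generate_phantom


TINY_GRID = (32, 64, 6)
TINY_RADII = dict(thigh_radius=13.0, skin_thickness=1.5, subcut_fat_thickness=3.0, bone_radius=2.5)


@pytest.fixture
def tiny_spec() -> PhantomSpec:
    """Small bilateral phantom spec (32 x 64 x 6 grid) for fast tests."""
    return PhantomSpec(grid_shape=TINY_GRID, voxel_spacing=(1.0, 1.0, 6.0), **TINY_RADII)


@pytest.fixture
def noise_free_phantom(tiny_spec):
    spec = tiny_spec
    spec.noise_sigma = 0.0
    spec.roi_fat_fraction = {1: 0.30, 2: 0.10, 3: 0.20, 4: 0.05}
    return generate_phantom(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
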