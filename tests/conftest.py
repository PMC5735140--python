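import numpy as np
import pytest

from limbquant import SceneConfig


@pytest.fixture
def small_scene() -> SceneConfig:
    """A compact scene used where geometry, not scale, is under test."""
    return SceneConfig(
        volume_extent=(120.0, 120.0, 48.0),
        fov_diameter=120.0,
        voxel_size=(1.0, 1.0, 2.0),
        n_frames=4,
        seed=11,
    )


@pytest.fixture
def validation_scene() -> SceneConfig:
    """The desk-scale vessel validation scene (1x1x3 µm voxels)."""
    return SceneConfig(
        volume_extent=(220.0, 220.0, 72.0),
        fov_diameter=220.0,
        voxel_size=(1.0, 1.0, 3.0),
        n_frames=2,
        seed=1,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
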