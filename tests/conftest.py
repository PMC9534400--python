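import numpy as np
import pytest

from tch import MEDIAN_CONSTANTS, SceneSpec, PatchSpec, CrownClass


@pytest.fixture(scope="session")
def constants():
    """Median global constants (c_g=5, c_r=5, c_y=1e7, c_d=1e4, t=0.1)."""
    return MEDIAN_CONSTANTS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene_spec():
    """64x64 scene at 1 m pixels: one patch per class on blue background."""
    return SceneSpec(width=64, height=64, pixel_size=1.0, seed=7, patches=(
        PatchSpec(CrownClass.GREEN, 4, 4, 16, 16),
        PatchSpec(CrownClass.RED, 28, 8, 3, 3),
        PatchSpec(CrownClass.GRAY, 40, 28, 4, 5),
        PatchSpec(CrownClass.SHADOW, 8, 40, 10, 10),
    ))
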