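import numpy as np
import pytest

from meaningmaps.geometry import Condition, GridLevel, Patch, RegionBox, ScreenGeometry
from meaningmaps.synth import make_scene_specs


@pytest.fixture(scope="session")
def study_geometry():
    """Full-scale display geometry of the emulated study."""
    return ScreenGeometry(688, 524, 19.7, 15.0)


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced raster with the same field of view, for fast pipeline runs."""
    return ScreenGeometry(96, 72, 19.7, 15.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_specs(small_geometry):
    """Four synthetic scene specs on the reduced raster."""
    return make_scene_specs(4, geometry=small_geometry, seed=7)


def make_patch(
    cx, cy, diameter, scene="s0", cond=Condition.CONSISTENT, level=GridLevel.COARSE
):
    return Patch(
        patch_id=f"{scene}_{cx}_{cy}_{diameter}",
        scene_id=scene,
        condition=cond,
        level=level,
        center=(float(cx), float(cy)),
        diameter_px=int(diameter),
    )
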