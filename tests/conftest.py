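import numpy as np
import pytest

from petprecision.grids import GridSpec
from petprecision.imaging import blur
from petprecision.phantoms import build_iq_scene, build_mini_iq_scene, voxelize_scene


@pytest.fixture(scope="session")
def iq_scene():
    """Full NEMA IQ analog at 10:1 contrast (20 / 2 kBq/mL)."""
    return build_iq_scene(20.0, 2.0)


@pytest.fixture(scope="session")
def single_sphere_image():
    """10 mm sphere (S=10, B=1) voxelized at 1 mm, supersampling 4."""
    scene = build_mini_iq_scene(10.0, 1.0, sphere_diameters=(10.0,), box_half_mm=30.0)
    grid = GridSpec((1.0, 1.0, 1.0), (61, 61, 61), (-30.0, -30.0, -30.0))
    return scene, voxelize_scene(scene, grid, 4)


@pytest.fixture(scope="session")
def blurred_sphere_image(single_sphere_image):
    """The same sphere after a 7 mm FWHM resolution blur."""
    scene, img = single_sphere_image
    return scene, blur(img, 7.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20171119)
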