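import numpy as np
import pytest

from nightshift.lamps import load_lamp_library, mixture_library
from nightshift.raster import GridGeometry
from nightshift.scene import DistortionConfig, make_lamp_maps
from nightshift.spectra import CameraResponse


@pytest.fixture(scope="session")
def camera():
    return CameraResponse.default()


@pytest.fixture(scope="session")
def lamp_library():
    return load_lamp_library()


@pytest.fixture(scope="session")
def spd_library():
    return mixture_library()


@pytest.fixture(scope="session")
def small_geometry():
    return GridGeometry.study_grid(shape=(120, 120))


@pytest.fixture(scope="session")
def small_maps(small_geometry):
    """Two-epoch 120x120 scene with a 50% sodium-to-LED conversion."""
    return make_lamp_maps(
        5, (120, 120), epoch_shift=0.5, seed=7, geometry=small_geometry
    )


@pytest.fixture()
def clean_distortions():
    return DistortionConfig.none()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
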