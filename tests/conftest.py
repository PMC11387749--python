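import numpy as np
import pytest

from autolia import CameraModel, RigPose, default_camera


@pytest.fixture
def cam() -> CameraModel:
    return default_camera()


@pytest.fixture
def small_cam() -> CameraModel:
    """A tiny camera for hand-constructed depth grids."""
    return CameraModel(
        focal_px=100.0, principal_point=(15.5, 11.5), baseline_m=0.1, image_size=(32, 24)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
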