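import numpy as np
import pytest

from headposture import (
    CameraModel,
    EstimatorConfig,
    LandmarkObservation,
    canonical_model,
    default_camera,
    project,
)


@pytest.fixture(scope="session")
def model():
    return canonical_model()


@pytest.fixture(scope="session")
def camera():
    return default_camera()


@pytest.fixture(scope="session")
def camera_f1000():
    return CameraModel(focal_px=1000.0, principal_point_px=(960.0, 540.0),
                       image_size_px=(1920, 1080))


@pytest.fixture(scope="session")
def cfg():
    return EstimatorConfig()


def noisy_observation(model, pose, camera, sd_px, rng, frame_id=0):
    """Project a pose and add i.i.d. Gaussian pixel noise."""
    clean = project(model, pose, camera, frame_id=frame_id)
    pts = clean.points_px + sd_px * rng.normal(size=(68, 2))
    return LandmarkObservation(frame_id=frame_id, points_px=pts,
                               visible=np.ones(68, dtype=bool))
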