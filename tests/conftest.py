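import datetime

import numpy as np
import pytest

from gaitscore.config import StepDetectionConfig
from gaitscore.io_types import WalkingBout, MPII_JOINTS
from gaitscore.synthetic_data import GaitParams, simulate_bout


@pytest.fixture(scope="session")
def det_cfg():
    return StepDetectionConfig()


@pytest.fixture(scope="session")
def clean_walk_2d():
    """Noise-free 10-step 2D bout with its ground truth."""
    params = GaitParams(cadence=105, n_steps=10, step_time_cv=0.0, keypoint_noise_sd=0.0)
    return simulate_bout(params, "2d", seed=7)


@pytest.fixture(scope="session")
def clean_walk_3d():
    params = GaitParams(cadence=105, n_steps=10, step_time_cv=0.0, keypoint_noise_sd=0.0)
    return simulate_bout(params, "3d", seed=7)


def make_static_bout_2d(n_frames=60, hip_half=50.0, frame_rate=30.0, ankle_du=0.0):
    """A stationary 2D pose: hips ``2*hip_half`` px apart, ankles below them.

    ``ankle_du`` shifts both ankles horizontally by the same amount
    (pixels) relative to the hip centre.
    """
    centre = np.array([960.0, 540.0])
    data = {}
    for name in MPII_JOINTS:
        data[name] = np.tile(centre, (n_frames, 1)).astype(float)
    data["l_hip"] = np.tile(centre + [hip_half, 0.0], (n_frames, 1))
    data["r_hip"] = np.tile(centre + [-hip_half, 0.0], (n_frames, 1))
    data["l_ankle"] = np.tile(centre + [hip_half + ankle_du, 300.0], (n_frames, 1))
    data["r_ankle"] = np.tile(centre + [-hip_half + ankle_du, 300.0], (n_frames, 1))
    return WalkingBout(
        bout_id="static",
        participant_id="p0",
        date=datetime.date(2020, 1, 1),
        frame_rate=frame_rate,
        ndim=2,
        data=data,
    )


@pytest.fixture()
def static_bout_2d():
    return make_static_bout_2d()
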