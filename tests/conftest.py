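import logging

import numpy as np
import pytest

from mvfruit.geometry import CameraIntrinsics, Pose
from mvfruit.synthetic import OrchardSpec, simulate_scene

logging.getLogger("mvfruit").setLevel(logging.ERROR)
logging.getLogger("mvfruit.tracking").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def survey_cam() -> CameraIntrinsics:
    """Pinhole camera with the survey sensor's geometry (no distortion)."""
    return CameraIntrinsics(fx=1000.0, fy=1000.0, cx=1648.0, cy=1236.0, width=3296, height=2472)


@pytest.fixture()
def identity_pose() -> Pose:
    return Pose(0.0, np.zeros(3), np.array([0.0, 0.0, 0.0, 1.0]))


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, occlusion-free small orchard: every fruit detectable in
    every frame that images it, detections exactly at projected centres."""
    spec = OrchardSpec(
        trees_per_row=5,
        fruit_per_tree_fixed=12,
        occlusion_window_deg=360.0,
        miss_rate=0.0,
        transient_miss_rate=0.0,
        fp_rate=0.0,
        centroid_noise_px=0.0,
        attitude_oscillation_deg=0.0,
        seed=11,
    )
    return simulate_scene(spec)


@pytest.fixture(scope="session")
def clean_pass(clean_scene):
    """Frames of the first (single-side) pass of the clean scene."""
    row, side, t0, t1 = clean_scene.passes[0]
    return clean_scene.frames_in_window(t0, t1)
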