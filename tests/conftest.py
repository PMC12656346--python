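import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dmsm.io_pose import PoseSequence
from dmsm.synth import SwingStyle, generate_swing

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

MINIMAL_JOINTS = (
    "left_shoulder",
    "right_shoulder",
    "left_hip",
    "right_hip",
    "left_wrist",
    "right_wrist",
)

#: address-pose coordinates (body-scale units, y down, mid-hip at origin)
ADDRESS_POSE = {
    "left_shoulder": (-0.5, -1.4),
    "right_shoulder": (0.5, -1.4),
    "left_elbow": (-0.3, -0.5),
    "right_elbow": (0.3, -0.5),
    "left_hip": (-0.35, 0.0),
    "right_hip": (0.35, 0.0),
    "left_wrist": (-0.05, 0.4),
    "right_wrist": (0.05, 0.4),
}


def make_static_sequence(
    n: int = 30,
    fps: float = 30.0,
    pose: dict | None = None,
    units: str = "body_scale",
    scale: float = 1.0,
    offset: tuple[float, float] = (0.0, 0.0),
    clip_id: str = "static",
) -> PoseSequence:
    """A motionless skeleton holding one pose — handy for geometry tests."""
    pose = pose or ADDRESS_POSE
    joints = tuple(pose)
    coords = np.zeros((n, len(joints), 2))
    for k, j in enumerate(joints):
        coords[:, k] = pose[j]
    coords = coords * scale + np.asarray(offset)
    return PoseSequence(
        times=np.arange(n) / fps,
        coords=coords,
        joints=joints,
        fps=fps,
        units=units,
        clip_id=clip_id,
    )


@pytest.fixture(scope="session")
def default_clip():
    """One deterministic synthetic swing at the default style."""
    return generate_swing(SwingStyle(seed=11), clip_id="default", player_id="p0")


@pytest.fixture(scope="session")
def noiseless_clip():
    return generate_swing(SwingStyle(noise_sigma=0.0, seed=0), clip_id="clean", player_id="p0")
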