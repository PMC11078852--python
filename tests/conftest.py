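import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from endopolyp.camera import CameraIntrinsics, CameraPose, RigConfig


@pytest.fixture
def simple_rig() -> RigConfig:
    """500 px focal length, 500x500 image, zero distortion, identity hand-eye."""
    return RigConfig(
        CameraIntrinsics(fx=500.0, fy=500.0, cx=250.0, cy=250.0,
                         image_width=500, image_height=500)
    )


@pytest.fixture
def identity_pose() -> CameraPose:
    return CameraPose(np.zeros(3), np.array([1.0, 0.0, 0.0, 0.0]), frame_id="origin")


def random_pose(rng: np.random.Generator, frame_id: str = "") -> CameraPose:
    """Uniformly random orientation, position in a 200 mm box."""
    q = Rotation.random(rng=rng).as_quat()  # (x, y, z, w)
    return CameraPose(
        rng.uniform(-100, 100, size=3),
        np.array([q[3], q[0], q[1], q[2]]),
        frame_id=frame_id,
    )
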