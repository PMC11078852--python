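"""Pinhole camera model and pose algebra in tracker (world) coordinates.

The electromagnetic tracker reports the 6-DoF pose of a small sensor fixed
to the endoscope tip.  A rigid hand--eye transform (sensor frame -> camera
optical frame) relates the sensor pose to the camera pose; with the default
identity hand--eye the two coincide.  All lengths are millimetres, angles at
the interface are degrees.

Camera convention: right handed, optical axis +z (into the scene), image x
right / y down, pixel coordinates 0-based with (0, 0) the centre of the
top-left pixel.  Quaternions are scalar-first (w, x, y, z) and encode the
tracker-from-frame rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import (
    BehindCameraError,
    DegenerateGeometryError,
    GeometryError,
    UndistortionError,
)

_QUAT_NORM_TOL = 1e-9
_ROT_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics with optional Brown--Conrady distortion.

    ``distortion`` follows the common (k1, k2, p1, p2, k3) ordering; an
    empty tuple means an ideal pinhole.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    image_width: int
    image_height: int
    distortion: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise GeometryError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if not (0 <= self.cx < self.image_width and 0 <= self.cy < self.image_height):
            raise GeometryError(
                f"principal point ({self.cx}, {self.cy}) outside image "
                f"{self.image_width}x{self.image_height}"
            )
        if len(self.distortion) > 5:
            raise GeometryError("at most 5 distortion coefficients (k1,k2,p1,p2,k3) supported")
        object.__setattr__(self, "distortion", tuple(float(d) for d in self.distortion))

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class CameraPose:
    """Rigid pose of the tracked frame in tracker coordinates at one frame.

    ``orientation`` is the unit quaternion (w, x, y, z) rotating frame
    coordinates into tracker coordinates; ``position`` is the frame origin
    in mm.  Pose logs carry the *sensor* pose; the camera pose follows via
    the rig's hand--eye transform.
    """

    position: np.ndarray
    orientation: np.ndarray
    frame_id: str = ""
    timestamp: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        quat = np.asarray(self.orientation, dtype=float).reshape(4)
        if not np.all(np.isfinite(pos)):
            raise GeometryError(f"non-finite position in pose {self.frame_id!r}")
        norm = np.linalg.norm(quat)
        if abs(norm - 1.0) > 1e-6:
            raise GeometryError(
                f"quaternion norm {norm:.9f} != 1 in pose {self.frame_id!r}"
            )
        quat = quat / norm  # clean up residual <=1e-6 drift from file round trips
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", quat)

    @property
    def rotation(self) -> Rotation:
        w, x, y, z = self.orientation
        return Rotation.from_quat([x, y, z, w])  # scipy is scalar-last

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous tracker-from-frame transform."""
        T = np.eye(4)
        T[:3, :3] = self.rotation.as_matrix()
        T[:3, 3] = self.position
        return T

    @staticmethod
    def from_matrix(T: np.ndarray, frame_id: str = "", timestamp: float | None = None) -> "CameraPose":
        R = Rotation.from_matrix(T[:3, :3])
        x, y, z, w = R.as_quat()
        return CameraPose(T[:3, 3].copy(), np.array([w, x, y, z]), frame_id, timestamp)


def _identity_hand_eye() -> np.ndarray:
    return np.eye(3)


@dataclass(frozen=True)
class RigConfig:
    """Calibrated rig: intrinsics plus the sensor-to-camera rigid transform."""

    intrinsics: CameraIntrinsics
    hand_eye_rotation: np.ndarray = field(default_factory=_identity_hand_eye)
    hand_eye_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.hand_eye_rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.hand_eye_translation, dtype=float).reshape(3)
        if np.linalg.norm(R @ R.T - np.eye(3)) > 1e-6 or np.linalg.det(R) < 0:
            raise GeometryError("hand_eye rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "hand_eye_rotation", R)
        object.__setattr__(self, "hand_eye_translation", t)


@dataclass(frozen=True)
class Ray:
    """Half-line in tracker coordinates: origin (mm) + unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise GeometryError(f"ray direction norm {n} != 1")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


def camera_extrinsics(pose: CameraPose, rig: RigConfig) -> tuple[np.ndarray, np.ndarray]:
    """World-from-camera rotation matrix and camera centre in tracker coords.

    Composes the tracked sensor pose with the inverse hand--eye (camera-from-
    sensor) transform: T_world_camera = T_world_sensor @ inv(T_camera_sensor).
    """
    R_ws = pose.rotation.as_matrix()
    R_cs = rig.hand_eye_rotation
    t_cs = rig.hand_eye_translation
    R_wc = R_ws @ R_cs.T
    centre = pose.position - R_wc @ t_cs
    return R_wc, centre


def optical_axis(pose: CameraPose, rig: RigConfig) -> np.ndarray:
    """Unit vector of the camera's +z (viewing) axis in tracker coordinates."""
    R_wc, _ = camera_extrinsics(pose, rig)
    return R_wc[:, 2]


def _distort(x: np.ndarray, y: np.ndarray, coeffs: tuple[float, ...]):
    k1, k2, p1, p2, k3 = (tuple(coeffs) + (0.0,) * 5)[:5]
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2 * r2 + k3 * r2 * r2 * r2
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return xd, yd


def _undistort(xd: float, yd: float, coeffs: tuple[float, ...], max_iter: int = 50, tol: float = 1e-12):
    # fixed-point iteration; exact identity when there is no distortion
    if not coeffs or not any(coeffs):
        return xd, yd
    x, y = xd, yd
    for _ in range(max_iter):
        xe, ye = _distort(np.asarray(x), np.asarray(y), coeffs)
        x_new = x + (xd - float(xe))
        y_new = y + (yd - float(ye))
        if abs(x_new - x) < tol and abs(y_new - y) < tol:
            return x_new, y_new
        x, y = x_new, y_new
    raise UndistortionError(f"undistortion did not converge for normalized point ({xd}, {yd})")


def project(point3d: np.ndarray, pose: CameraPose, rig: RigConfig) -> np.ndarray:
    """Project a tracker-frame 3D point (mm) to pixel coordinates."""
    return project_many(np.asarray(point3d, float).reshape(1, 3), pose, rig)[0]


def project_many(points3d: np.ndarray, pose: CameraPose, rig: RigConfig) -> np.ndarray:
    """Vectorised projection of an (n, 3) array of tracker-frame points."""
    pts = np.asarray(points3d, dtype=float).reshape(-1, 3)
    R_wc, centre = camera_extrinsics(pose, rig)
    cam = (pts - centre) @ R_wc  # == R_wc.T @ (p - C) per point
    z = cam[:, 2]
    if np.any(z <= 0):
        bad = np.nonzero(z <= 0)[0]
        raise BehindCameraError(
            f"{bad.size} point(s) at or behind the camera plane (first index {bad[0]})"
        )
    x = cam[:, 0] / z
    y = cam[:, 1] / z
    xd, yd = _distort(x, y, rig.intrinsics.distortion)
    intr = rig.intrinsics
    return np.column_stack([intr.fx * xd + intr.cx, intr.fy * yd + intr.cy])


def backproject_ray(pixel: np.ndarray, pose: CameraPose, rig: RigConfig) -> Ray:
    """Back-project a pixel to its viewing ray in tracker coordinates.

    The ray origin is the camera centre; the direction points into the scene.
    """
    u, v = np.asarray(pixel, dtype=float).reshape(2)
    intr = rig.intrinsics
    xd = (u - intr.cx) / intr.fx
    yd = (v - intr.cy) / intr.fy
    x, y = _undistort(xd, yd, intr.distortion)
    R_wc, centre = camera_extrinsics(pose, rig)
    d_cam = np.array([x, y, 1.0])
    d_world = R_wc @ d_cam
    return Ray(centre, d_world / np.linalg.norm(d_world))


def relative_motion(
    pose_a: CameraPose, pose_b: CameraPose, rig: RigConfig | None = None
) -> tuple[float, float, float]:
    """Relative motion scalars between two views.

    Returns ``(translation_mm, rotation_deg, translation_axis_angle_deg)``:
    the distance between camera centres, the axis-angle magnitude of the
    relative rotation in [0, 180], and the angle in [0, 90] between the
    inter-centre translation and the mean optical axis of the two views
    (small values flag near pure forward--backward motion).  For identical
    centres the axis angle is reported as 0 by convention.
    """
    if rig is None:
        rig = RigConfig(
            CameraIntrinsics(fx=1.0, fy=1.0, cx=0.0, cy=0.0, image_width=1, image_height=1)
        )
    R_a, C_a = camera_extrinsics(pose_a, rig)
    R_b, C_b = camera_extrinsics(pose_b, rig)
    t_vec = C_b - C_a
    translation = float(np.linalg.norm(t_vec))
    rel = Rotation.from_matrix(R_a.T @ R_b)
    rotation_deg = float(np.degrees(rel.magnitude()))
    if translation < 1e-12:
        axis_angle = 0.0
    else:
        mean_axis = R_a[:, 2] + R_b[:, 2]
        n = np.linalg.norm(mean_axis)
        if n < 1e-12:  # opposing views: fall back to view a's axis
            mean_axis = R_a[:, 2]
        else:
            mean_axis = mean_axis / n
        cos = abs(float(np.dot(t_vec / translation, mean_axis)))
        axis_angle = float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
    return translation, rotation_deg, axis_angle


def triangulate_pair(ray_a: Ray, ray_b: Ray, min_sin: float = 1e-6) -> tuple[np.ndarray, float]:
    """Midpoint of the common perpendicular between two rays.

    Returns the 3D point (mm) and the residual: the length of the shortest
    segment joining the rays (0 when they intersect exactly).  Raises
    :class:`DegenerateGeometryError` for (near-)parallel rays.
    """
    d1, d2 = ray_a.direction, ray_b.direction
    cross = np.cross(d1, d2)
    sin_angle = float(np.linalg.norm(cross))
    if sin_angle < min_sin:
        angle_deg = float(np.degrees(np.arcsin(np.clip(sin_angle, 0.0, 1.0))))
        raise DegenerateGeometryError(
            f"rays nearly parallel: angle {angle_deg:.3e} deg (sin {sin_angle:.3e} < {min_sin})"
        )
    b = ray_b.origin - ray_a.origin
    d12 = float(np.dot(d1, d2))
    denom = 1.0 - d12 * d12
    t1 = (np.dot(b, d1) - np.dot(b, d2) * d12) / denom
    t2 = (np.dot(b, d1) * d12 - np.dot(b, d2)) / denom
    p1 = ray_a.point_at(t1)
    p2 = ray_b.point_at(t2)
    return 0.5 * (p1 + p2), float(np.linalg.norm(p1 - p2))


def look_at_pose(
    position: np.ndarray,
    target: np.ndarray,
    up: np.ndarray = (0.0, 0.0, 1.0),
    frame_id: str = "",
) -> CameraPose:
    """Camera pose at ``position`` with optical axis toward ``target``.

    ``up`` resolves the roll; it must not be parallel to the viewing
    direction.  Returned pose assumes an identity hand--eye (sensor ==
    camera frame).
    """
    position = np.asarray(position, dtype=float).reshape(3)
    z = np.asarray(target, dtype=float).reshape(3) - position
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise GeometryError("look_at target coincides with camera position")
    z = z / nz
    up = np.asarray(up, dtype=float).reshape(3)
    x = np.cross(up, z)
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise GeometryError("up vector parallel to viewing direction")
    x = x / nx
    y = np.cross(z, x)
    T = np.eye(4)
    T[:3, 0], T[:3, 1], T[:3, 2], T[:3, 3] = x, y, z, position
    return CameraPose.from_matrix(T, frame_id=frame_id)
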