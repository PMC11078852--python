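"""Synthetic endoscopic scenes with ground truth.

Stands in for a bench experiment: closed 3D polyp border curves of known
longest length (5–20 mm covers the common clinical range), endoscope-like
pose sets that respect (or deliberately violate) the capture
recommendations, rendered segmentation masks / border contours, and
Gaussian pose and pixel noise.  Everything is deterministic under a seed.

Default camera: 640x640 px, fx = fy = 330 (about 88 degrees horizontal
field of view, endoscope-like), zero distortion, identity hand--eye.
Default noise sigmas — 0.3 mm tracker position, 0.3 degree orientation,
0.5 px contour jitter — are plausible EM-tracker and segmentation
magnitudes; they are configuration, not estimates of any specific device.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation
from skimage.draw import polygon as draw_polygon

from .camera import CameraIntrinsics, CameraPose, RigConfig, look_at_pose, project_many
from .contours import BorderContour, SegmentationMask
from .exceptions import GeometryError, PoseGenerationError
from .motion import MotionThresholds, check_pair


def default_rig() -> RigConfig:
    return RigConfig(
        CameraIntrinsics(fx=330.0, fy=330.0, cx=320.0, cy=320.0, image_width=640, image_height=640)
    )


@dataclass
class SyntheticPolyp:
    """Ground-truthed 3D polyp border curve."""

    border3d: np.ndarray
    true_major_axis_mm: float
    true_minor_axis_mm: float
    centre: np.ndarray
    normal: np.ndarray
    perturbation_amp_mm: float = 0.0


@dataclass
class NoiseModel:
    pose_pos_sigma_mm: float = 0.3
    pose_rot_sigma_deg: float = 0.3
    pixel_sigma_px: float = 0.5


@dataclass
class SyntheticScene:
    polyp: SyntheticPolyp
    poses: list[CameraPose]
    rig: RigConfig
    landmark: np.ndarray
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0


@dataclass
class RenderedViews:
    masks: list[SegmentationMask]
    contours: list[BorderContour]
    noisy_poses: list[CameraPose]


def make_polyp(
    major_mm: float,
    minor_mm: float,
    orientation: Rotation | None = None,
    centre: np.ndarray = (0.0, 0.0, 0.0),
    waviness_mm: float = 0.0,
    n_points: int = 200,
    seed: int = 0,
) -> SyntheticPolyp:
    """Planar (optionally wavy) elliptical border of known longest length.

    ``waviness_mm`` adds a smooth periodic out-of-plane displacement of
    that amplitude — a stand-in for asymmetric, non-rigid real polyps.  The
    stored ground truth is the generating major axis.
    """
    if not (major_mm >= minor_mm > 0):
        raise GeometryError(f"need major >= minor > 0, got {major_mm}, {minor_mm}")
    rng = np.random.default_rng(seed)
    if orientation is None:
        orientation = Rotation.random(rng=rng)
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    border = np.column_stack(
        [0.5 * major_mm * np.cos(t), 0.5 * minor_mm * np.sin(t), np.zeros_like(t)]
    )
    if waviness_mm > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        border[:, 2] = waviness_mm * np.sin(3.0 * t + phase)
    R = orientation.as_matrix()
    centre = np.asarray(centre, dtype=float).reshape(3)
    return SyntheticPolyp(
        border3d=border @ R.T + centre,
        true_major_axis_mm=float(major_mm),
        true_minor_axis_mm=float(minor_mm),
        centre=centre,
        normal=R[:, 2],
        perturbation_amp_mm=float(waviness_mm),
    )


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(normal, u)


def make_pose_set(
    polyp: SyntheticPolyp,
    n_views: int = 5,
    working_distance_mm: float = 60.0,
    baseline_mm: tuple[float, float] = (5.0, 25.0),
    seed: int = 0,
    rig: RigConfig | None = None,
    thresholds: MotionThresholds = MotionThresholds(),
    max_retries: int = 200,
) -> list[CameraPose]:
    """Endoscope-like poses looking at the polyp from ~working distance.

    Cameras sit on a spherical cap facing the polyp, with lateral spread
    chosen so that *every* pose pair (not just consecutive ones) satisfies
    the motion recommendations and the translations fall inside
    ``baseline_mm``; every pose must see the full border inside the image.
    Deterministic under ``seed``; raises :class:`PoseGenerationError` when
    the constraints cannot be met within the retry budget.
    """
    if n_views < 2:
        raise PoseGenerationError(f"need >= 2 views, got {n_views}")
    rig = rig or default_rig()
    rng = np.random.default_rng(seed)
    u, v = _tangent_basis(polyp.normal)
    lo, hi = baseline_mm
    # angular offsets (radians) on the viewing sphere produce pairwise
    # translations ~ working_distance * |direction difference|
    rho_lo = max(lo / working_distance_mm * 0.7, 0.02)
    rho_hi = min(hi / working_distance_mm * 0.7, 0.35)
    if rho_lo >= rho_hi:
        rho_lo, rho_hi = rho_hi * 0.5, rho_hi
    for _ in range(max_retries):
        poses: list[CameraPose] = []
        base_angle = rng.uniform(0.0, 2.0 * np.pi)
        ok = True
        for k in range(n_views):
            psi = base_angle + 2.0 * np.pi * k / n_views + rng.normal(0.0, 0.25)
            rho = rng.uniform(rho_lo, rho_hi)
            direction = polyp.normal + rho * (np.cos(psi) * u + np.sin(psi) * v)
            direction /= np.linalg.norm(direction)
            dist = working_distance_mm * (1.0 + rng.uniform(-0.03, 0.03))
            position = polyp.centre + dist * direction
            # shared up vector (plus a little roll jitter) keeps relative
            # rotations dominated by the viewing-direction change, well
            # below the 30 degree gate
            roll = rng.normal(0.0, np.radians(3.0))
            up = np.cos(roll) * u + np.sin(roll) * v
            try:
                pose = look_at_pose(position, polyp.centre, up=up, frame_id=f"view{k:02d}")
                pix = project_many(polyp.border3d, pose, rig)
            except GeometryError:
                ok = False
                break
            intr = rig.intrinsics
            if not (
                np.all(pix[:, 0] >= 0)
                and np.all(pix[:, 0] <= intr.image_width - 1)
                and np.all(pix[:, 1] >= 0)
                and np.all(pix[:, 1] <= intr.image_height - 1)
            ):
                ok = False
                break
            poses.append(pose)
        if not ok:
            continue
        if all(
            check_pair(poses[i], poses[j], thresholds, rig).passed
            for i in range(n_views)
            for j in range(i + 1, n_views)
        ):
            return poses
    raise PoseGenerationError(
        f"could not generate {n_views} views satisfying the motion recommendations "
        f"within {max_retries} attempts (baseline range {baseline_mm} mm)"
    )


def _perturb_pose(pose: CameraPose, noise: NoiseModel, rng: np.random.Generator) -> CameraPose:
    if noise.pose_pos_sigma_mm == 0 and noise.pose_rot_sigma_deg == 0:
        return pose
    position = pose.position + rng.normal(0.0, noise.pose_pos_sigma_mm, size=3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.normal(0.0, noise.pose_rot_sigma_deg))
    R = Rotation.from_rotvec(angle * axis) * pose.rotation
    x, y, z, w = R.as_quat()
    return CameraPose(position, np.array([w, x, y, z]), pose.frame_id, pose.timestamp)


def render_views(scene: SyntheticScene, out_dir: str | Path | None = None) -> RenderedViews:
    """Project the border into every view; rasterise masks, jitter contours.

    Masks are the filled projected polygon; contours are the exact
    projected border points plus isotropic Gaussian pixel noise; poses are
    perturbed by Gaussian position / axis-angle rotation noise.  All
    randomness flows from ``scene.seed``.  When ``out_dir`` is given the
    fixture directory (masks/*.png, poses.csv, rig.yaml, landmark.json,
    truth.json) is also written.
    """
    rng = np.random.default_rng(scene.seed)
    intr = scene.rig.intrinsics
    masks, contours, noisy_poses = [], [], []
    for pose in scene.poses:
        pix = project_many(scene.polyp.border3d, pose, scene.rig)
        if not (
            np.all(pix >= 0)
            and np.all(pix[:, 0] <= intr.image_width - 1)
            and np.all(pix[:, 1] <= intr.image_height - 1)
        ):
            raise GeometryError(f"polyp out of frame in view {pose.frame_id!r}")
        rr, cc = draw_polygon(pix[:, 1], pix[:, 0], shape=(intr.image_height, intr.image_width))
        grid = np.zeros((intr.image_height, intr.image_width), dtype=bool)
        grid[rr, cc] = True
        masks.append(SegmentationMask(grid, frame_id=pose.frame_id))
        jitter = rng.normal(0.0, scene.noise.pixel_sigma_px, size=pix.shape) \
            if scene.noise.pixel_sigma_px > 0 else 0.0
        contours.append(BorderContour(pix + jitter, closed=True, frame_id=pose.frame_id))
        noisy_poses.append(_perturb_pose(pose, scene.noise, rng))
    views = RenderedViews(masks=masks, contours=contours, noisy_poses=noisy_poses)
    if out_dir is not None:
        from . import io as _io

        _io.write_scene_fixture(Path(out_dir), scene, views)
    return views


def simulate_scene(
    major_mm: float = 12.0,
    minor_mm: float = 7.0,
    n_views: int = 5,
    working_distance_mm: float = 60.0,
    waviness_mm: float = 0.0,
    landmark_distance_mm: tuple[float, float] = (150.0, 250.0),
    noise: NoiseModel | None = None,
    seed: int = 0,
    rig: RigConfig | None = None,
) -> SyntheticScene:
    """Convenience constructor: polyp + poses + landmark in one call."""
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]
    rig = rig or default_rig()
    polyp = make_polyp(major_mm, minor_mm, waviness_mm=waviness_mm, seed=sub[0])
    poses = make_pose_set(
        polyp, n_views=n_views, working_distance_mm=working_distance_mm, seed=sub[1], rig=rig
    )
    lm_dir = rng.normal(size=3)
    lm_dir /= np.linalg.norm(lm_dir)
    landmark = polyp.centre + rng.uniform(*landmark_distance_mm) * lm_dir
    return SyntheticScene(
        polyp=polyp,
        poses=poses,
        rig=rig,
        landmark=landmark,
        noise=noise if noise is not None else NoiseModel(),
        seed=sub[2],
    )


def run_accuracy_cohort(
    n_polyps: int = 30,
    base_seed: int = 1,
    noise: NoiseModel | None = None,
    size_range_mm: tuple[float, float] = (5.0, 20.0),
    n_views: int = 5,
    correspondence: str = "shape_context",
    waviness_mm: float = 0.0,
):
    """Simulate-and-measure a cohort of polyps; returns per-polyp records.

    Each record holds true/estimated size and landmark distance, ready for
    RMSE summaries.  Major axes are uniform over ``size_range_mm``; the
    aspect ratio is uniform in [0.55, 0.9]; every pose pair satisfies the
    capture recommendations by construction.
    """
    from .reconstruction import MeasureOptions, measure_polyp

    noise = noise if noise is not None else NoiseModel()
    records = []
    for i in range(n_polyps):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, i]))
        major = rng.uniform(*size_range_mm)
        minor = major * rng.uniform(0.55, 0.9)
        scene_seed = int(rng.integers(0, 2**31 - 1))
        scene = simulate_scene(
            major_mm=major,
            minor_mm=minor,
            n_views=n_views,
            waviness_mm=waviness_mm,
            noise=noise,
            seed=scene_seed,
        )
        views = render_views(scene)
        frames = list(zip(views.contours, views.noisy_poses))
        options = MeasureOptions(correspondence=correspondence)
        result = measure_polyp(frames, scene.rig, scene.landmark, options)
        true_location = float(np.linalg.norm(scene.polyp.centre - scene.landmark))
        records.append(
            {
                "polyp": i,
                "true_size_mm": scene.polyp.true_major_axis_mm,
                "est_size_mm": result.final_size_mm,
                "true_location_mm": true_location,
                "est_location_mm": result.final_location_mm,
                "n_pairs_used": result.n_pairs_used,
            }
        )
    return records


def cohort_rmse(records: list[dict]) -> tuple[float, float]:
    """(size RMSE, location RMSE) in mm over cohort records."""
    size_err = np.array([r["est_size_mm"] - r["true_size_mm"] for r in records])
    loc_err = np.array([r["est_location_mm"] - r["true_location_mm"] for r in records])
    return float(np.sqrt(np.mean(size_err**2))), float(np.sqrt(np.mean(loc_err**2)))
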