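"""File formats and run manifests.

Pose log CSV (v1): columns ``frame_id, t, x_mm, y_mm, z_mm, qw, qx, qy, qz``
— sensor pose in the tracker frame, quaternion scalar-first.  The header
comment line states the convention to avoid the classic ordering trap.

Rig YAML: an ``intrinsics`` block (fx, fy, cx, cy, image_width,
image_height, distortion) and a ``hand_eye`` block (3x3 rotation rows +
translation_mm).  Masks are single-channel PNG/TIFF, 0 background / 255
foreground.  Every CLI run writes a manifest (config hash, seed, input
hashes, version) sufficient to reproduce its output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .camera import CameraIntrinsics, CameraPose, RigConfig
from .contours import BorderContour, SegmentationMask
from .exceptions import ConfigError

POSE_LOG_HEADER = (
    "# endopolyp pose log v1: sensor pose in tracker frame, mm; "
    "quaternion scalar-first (qw,qx,qy,qz), tracker-from-sensor\n"
)
POSE_COLUMNS = ["frame_id", "t", "x_mm", "y_mm", "z_mm", "qw", "qx", "qy", "qz"]


def write_pose_log(path: str | Path, poses: list[CameraPose]) -> None:
    rows = []
    for p in poses:
        rows.append(
            [p.frame_id, p.timestamp if p.timestamp is not None else ""]
            + [repr(float(v)) for v in p.position]
            + [repr(float(v)) for v in p.orientation]
        )
    df = pd.DataFrame(rows, columns=POSE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(POSE_LOG_HEADER)
        df.to_csv(fh, index=False)


def read_pose_log(path: str | Path) -> list[CameraPose]:
    try:
        df = pd.read_csv(path, comment="#", dtype={"frame_id": str})
    except Exception as exc:  # malformed CSV is a named, catchable error
        raise ConfigError(f"malformed pose log {path}: {exc}") from exc
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"pose log {path} missing columns {missing}")
    poses = []
    for _, row in df.iterrows():
        t = row["t"]
        poses.append(
            CameraPose(
                position=np.array([row["x_mm"], row["y_mm"], row["z_mm"]]),
                orientation=np.array([row["qw"], row["qx"], row["qy"], row["qz"]]),
                frame_id=str(row["frame_id"]),
                timestamp=None if pd.isna(t) or t == "" else float(t),
            )
        )
    return poses


def write_rig_yaml(path: str | Path, rig: RigConfig) -> None:
    intr = rig.intrinsics
    payload = {
        "intrinsics": {
            "fx": intr.fx,
            "fy": intr.fy,
            "cx": intr.cx,
            "cy": intr.cy,
            "image_width": intr.image_width,
            "image_height": intr.image_height,
            "distortion": list(intr.distortion),
        },
        "hand_eye": {
            "rotation": [[float(v) for v in row] for row in rig.hand_eye_rotation],
            "translation_mm": [float(v) for v in rig.hand_eye_translation],
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_rig_yaml(path: str | Path) -> RigConfig:
    try:
        payload = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed rig YAML {path}: {exc}") from exc
    try:
        ib = payload["intrinsics"]
        intr = CameraIntrinsics(
            fx=float(ib["fx"]),
            fy=float(ib["fy"]),
            cx=float(ib["cx"]),
            cy=float(ib["cy"]),
            image_width=int(ib["image_width"]),
            image_height=int(ib["image_height"]),
            distortion=tuple(ib.get("distortion", ())),
        )
        he = payload.get("hand_eye", {})
        return RigConfig(
            intrinsics=intr,
            hand_eye_rotation=np.array(he.get("rotation", np.eye(3).tolist())),
            hand_eye_translation=np.array(he.get("translation_mm", [0.0, 0.0, 0.0])),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid rig YAML {path}: {exc}") from exc


def write_mask(path: str | Path, mask: SegmentationMask) -> None:
    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def read_mask(path: str | Path, frame_id: str | None = None) -> SegmentationMask:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return SegmentationMask(arr > 0, frame_id=frame_id or Path(path).stem)


def write_contour_csv(path: str | Path, contours: list[BorderContour]) -> None:
    rows = [
        (c.frame_id, i, float(x), float(y))
        for c in contours
        for i, (x, y) in enumerate(c.points)
    ]
    pd.DataFrame(rows, columns=["frame_id", "index", "x_px", "y_px"]).to_csv(path, index=False)


def read_contour_csv(path: str | Path) -> list[BorderContour]:
    df = pd.read_csv(path, dtype={"frame_id": str})
    return [
        BorderContour(g.sort_values("index")[["x_px", "y_px"]].to_numpy(), frame_id=fid)
        for fid, g in df.groupby("frame_id", sort=True)
    ]


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed JSON {path}: {exc}") from exc


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, config: dict, seed: int | None, inputs: list[Path]) -> None:
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {str(p): sha256_file(p) for p in inputs if Path(p).is_file()},
    }
    write_json(path, manifest)


def write_scene_fixture(out_dir: Path, scene, views) -> None:
    """Write a rendered synthetic scene in the formats the CLI reads."""
    out_dir = Path(out_dir)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    for mask in views.masks:
        write_mask(out_dir / "masks" / f"{mask.frame_id}.png", mask)
    write_pose_log(out_dir / "poses.csv", views.noisy_poses)
    write_rig_yaml(out_dir / "rig.yaml", scene.rig)
    write_contour_csv(out_dir / "contours.csv", views.contours)
    write_json(
        out_dir / "landmark.json",
        {"name": "oesophago-gastric junction", "position_mm": scene.landmark.tolist()},
    )
    write_json(
        out_dir / "truth.json",
        {
            "true_major_axis_mm": scene.polyp.true_major_axis_mm,
            "true_minor_axis_mm": scene.polyp.true_minor_axis_mm,
            "centre_mm": scene.polyp.centre.tolist(),
            "true_landmark_distance_mm": float(
                np.linalg.norm(scene.polyp.centre - scene.landmark)
            ),
            "waviness_mm": scene.polyp.perturbation_amp_mm,
            "seed": scene.seed,
            "noise": {
                "pose_pos_sigma_mm": scene.noise.pose_pos_sigma_mm,
                "pose_rot_sigma_deg": scene.noise.pose_rot_sigma_deg,
                "pixel_sigma_px": scene.noise.pixel_sigma_px,
            },
        },
    )


_RUN_CONFIG_KEYS = {
    "n_samples": int,
    "n_r": int,
    "n_theta": int,
    "r_inner": float,
    "r_outer": float,
    "iqr_k": float,
    "residual_cap_mm": float,
    "min_region_px": int,
    "opening_radius": int,
    "max_translation_mm": float,
    "max_rotation_deg": float,
    "min_translation_mm": float,
    "forward_angle_deg": float,
    "correspondence": str,
    "seed": int,
}


def load_run_config(path: str | Path | None) -> dict:
    """Strict measurement-config loader: unknown keys are rejected."""
    if path is None:
        return {}
    try:
        payload = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config YAML {path}: {exc}") from exc
    unknown = set(payload) - set(_RUN_CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)} in {path}")
    out = {}
    for key, value in payload.items():
        try:
            out[key] = _RUN_CONFIG_KEYS[key](value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid value for {key!r} in {path}: {value!r}") from exc
    return out
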