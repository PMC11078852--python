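"""Pair-level motion-quality gate for endoscopic image capture.

Triangulation accuracy degrades for view pairs with large relative motion
(tracking error and tissue movement accumulate), negligible motion (tiny
baseline, ill-conditioned rays) or pure forward--backward motion (rays
nearly collinear with the translation).  This module classifies a pose pair
against those capture recommendations and names every violated rule, so an
operator can be told exactly what to change.

Boundary semantics are strict: translation of exactly 30 mm or exactly
3 mm passes (the rules are "> 30 mm" and "< 3 mm").
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .camera import CameraPose, RigConfig, relative_motion

RULE_LARGE_TRANSLATION = "large_translation"
RULE_LARGE_ROTATION = "large_rotation"
RULE_MINIMAL_MOVEMENT = "minimal_movement"
RULE_FORWARD_BACKWARD = "forward_backward"


@dataclass(frozen=True)
class MotionThresholds:
    """Capture-recommendation thresholds (mm / degrees)."""

    max_translation_mm: float = 30.0
    max_rotation_deg: float = 30.0
    min_translation_mm: float = 3.0
    min_forward_angle_deg: float = 15.0


@dataclass
class PairQualityReport:
    """Outcome of the motion-quality check for one view pair."""

    translation_mm: float
    rotation_deg: float
    forward_angle_deg: float
    failed_rules: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def check_pair(
    pose_a: CameraPose,
    pose_b: CameraPose,
    thresholds: MotionThresholds = MotionThresholds(),
    rig: RigConfig | None = None,
) -> PairQualityReport:
    """Evaluate every capture rule on a view pair; never short-circuits.

    Rules, in fixed order: ``large_translation`` (> max), ``large_rotation``
    (> max), ``minimal_movement`` (< min), ``forward_backward`` (angle
    between the translation and the mean optical axis below the forward
    threshold).
    """
    translation, rotation, forward_angle = relative_motion(pose_a, pose_b, rig)
    failed: list[str] = []
    if translation > thresholds.max_translation_mm:
        failed.append(RULE_LARGE_TRANSLATION)
    if rotation > thresholds.max_rotation_deg:
        failed.append(RULE_LARGE_ROTATION)
    if translation < thresholds.min_translation_mm:
        failed.append(RULE_MINIMAL_MOVEMENT)
    if forward_angle < thresholds.min_forward_angle_deg:
        failed.append(RULE_FORWARD_BACKWARD)
    return PairQualityReport(
        translation_mm=translation,
        rotation_deg=rotation,
        forward_angle_deg=forward_angle,
        failed_rules=failed,
    )
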