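"""Measurement core: triangulate matched border points, fit a 3D ellipse,
report polyp size and landmark distance, aggregate multiple view pairs.

The clinically reported quantity is the polyp's longest length: the major
axis of an ellipse fitted to the reconstructed 3D border.  Location is the
Euclidean distance (mm, tracker frame) from the fitted ellipse centre to an
anatomical landmark such as the oesophago-gastric junction.  With five
captured frames, all C(5,2) quality-passing pairs are measured
independently; pairs whose reconstructed centre is a quartile outlier
(Tukey fence on distance to the component-wise median centre) are excluded
and the remaining estimates averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import CameraPose, RigConfig, backproject_ray, triangulate_pair
from .contours import BorderContour, SegmentationMask, extract_border, refine_mask, resample_contour
from .exceptions import (
    DegenerateGeometryError,
    EllipseFitError,
    QualityGateError,
    ReconstructionError,
)
from .motion import MotionThresholds, PairQualityReport, check_pair
from .shape_context import CorrespondenceSet, ShapeContextParams, match_points, match_shapes

_MIN_BORDER_POINTS = 6


@dataclass
class Border3D:
    """Reconstructed 3D border points (mm, tracker frame) for one pair."""

    points: np.ndarray
    residuals_mm: np.ndarray
    source_pair: tuple[str, str]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.residuals_mm = np.asarray(self.residuals_mm, dtype=float).reshape(-1)
        if len(self.points) != len(self.residuals_mm):
            raise ReconstructionError("points / residuals length mismatch")
        if len(self.points) < _MIN_BORDER_POINTS:
            raise ReconstructionError(
                f"border needs >= {_MIN_BORDER_POINTS} points, got {len(self.points)}"
            )


@dataclass
class EllipseFit3D:
    """Planar ellipse fitted to a reconstructed border."""

    centre: np.ndarray
    normal: np.ndarray
    major_axis_mm: float
    minor_axis_mm: float
    major_direction: np.ndarray
    rms_fit_error_mm: float


@dataclass
class PairEstimate:
    """Size/location estimate from a single view pair."""

    source_pair: tuple[str, str]
    size_mm: float
    centre: np.ndarray
    location_mm: float
    n_points: int
    median_residual_mm: float
    rms_fit_error_mm: float
    quality: PairQualityReport | None = None
    outlier: bool = False


@dataclass
class PolypMeasurement:
    """Aggregated measurement over all usable view pairs."""

    per_pair: list[PairEstimate]
    outlier_flags: list[bool]
    final_size_mm: float
    final_location_mm: float
    n_pairs_used: int
    rejected_pairs: list[tuple[tuple[str, str], list[str]]] = field(default_factory=list)


def reconstruct_border(
    corr: CorrespondenceSet,
    pose_a: CameraPose,
    pose_b: CameraPose,
    rig: RigConfig,
    residual_cap_mm: float = 2.0,
    quality: PairQualityReport | None = None,
    allow_poor_motion: bool = False,
) -> Border3D:
    """Triangulate each correspondence into tracker-frame 3D.

    Correspondences whose two viewing rays miss each other by more than
    ``residual_cap_mm`` (length of the common perpendicular) are treated as
    mismatches and dropped.  Raises :class:`QualityGateError` when the pair
    failed the motion check and ``allow_poor_motion`` is not set, and
    :class:`ReconstructionError` when fewer than 6 points survive.
    """
    if quality is not None and not quality.passed and not allow_poor_motion:
        raise QualityGateError(
            f"pair ({pose_a.frame_id}, {pose_b.frame_id}) failed motion rules: "
            f"{quality.failed_rules}"
        )
    if len(corr.pairs) < _MIN_BORDER_POINTS:
        raise ReconstructionError(
            f"need >= {_MIN_BORDER_POINTS} correspondences, got {len(corr.pairs)}"
        )
    points, residuals = [], []
    n_degenerate = 0
    for i, j in corr.pairs:
        ray_a = backproject_ray(corr.points_p[i], pose_a, rig)
        ray_b = backproject_ray(corr.points_q[j], pose_b, rig)
        try:
            p, res = triangulate_pair(ray_a, ray_b)
        except DegenerateGeometryError:
            n_degenerate += 1
            continue
        if res <= residual_cap_mm:
            points.append(p)
            residuals.append(res)
    if len(points) < _MIN_BORDER_POINTS:
        kept = len(points)
        raise ReconstructionError(
            f"reconstruction failed for pair ({pose_a.frame_id}, {pose_b.frame_id}): "
            f"{kept}/{len(corr.pairs)} points under the {residual_cap_mm} mm residual cap "
            f"({n_degenerate} degenerate ray pairs)"
        )
    return Border3D(np.array(points), np.array(residuals), (pose_a.frame_id, pose_b.frame_id))


def _fit_conic_2d(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct least-squares ellipse-specific conic fit (Halir–Flusser).

    Returns (a, b, c, d, e, f) of a x^2 + b xy + c y^2 + d x + e y + f = 0
    with the ellipse constraint b^2 - 4ac < 0 built into the eigenproblem.
    """
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError(f"rank-deficient design matrix: {exc}") from exc
    M = S1 + S2 @ T
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    # ellipse solution: the eigenvector with 4ac - b^2 > 0
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    idx = np.nonzero(np.isreal(eigval) & (np.real(cond) > 0))[0]
    if idx.size == 0:
        raise EllipseFitError("conic fit did not yield an ellipse (hyperbola/parabola)")
    a1 = np.real(eigvec[:, idx[0]])
    return np.concatenate([a1, T @ a1])


def _conic_to_geometric(conic: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Centre, semi-major, semi-minor and major-axis angle from a conic."""
    a, b, c, d, e, f = conic
    M = np.array([[a, b / 2.0], [b / 2.0, c]])
    if np.linalg.det(M) <= 0:
        raise EllipseFitError("conic is not an ellipse (non-definite quadratic form)")
    centre = np.linalg.solve(2.0 * M, -np.array([d, e]))
    k = -(centre @ M @ centre + np.array([d, e]) @ centre + f)
    eigval, eigvec = np.linalg.eigh(M)
    ratios = k / eigval
    if np.any(ratios <= 0):
        raise EllipseFitError("degenerate ellipse (non-positive axis length)")
    semi = np.sqrt(ratios)
    order = np.argsort(semi)[::-1]  # conic sign is arbitrary, sort axes explicitly
    semi = semi[order]
    major_vec = eigvec[:, order[0]]
    angle = float(np.arctan2(major_vec[1], major_vec[0]))
    return centre, float(semi[0]), float(semi[1]), angle


def _ellipse_rms_error(xy: np.ndarray, centre: np.ndarray, a: float, b: float, angle: float) -> float:
    """RMS in-plane distance of points to the fitted ellipse (radial gauge)."""
    ca, sa = np.cos(angle), np.sin(angle)
    R = np.array([[ca, sa], [-sa, ca]])
    u = (xy - centre) @ R.T
    phi = np.arctan2(u[:, 1] / b, u[:, 0] / a)
    on_ellipse = np.column_stack([a * np.cos(phi), b * np.sin(phi)])
    return float(np.sqrt(np.mean(np.sum((u - on_ellipse) ** 2, axis=1))))


def fit_ellipse_3d(border: Border3D | np.ndarray) -> EllipseFit3D:
    """Fit a planar ellipse to 3D border points.

    The best-fit plane comes from the centroid plus the two leading
    principal directions; points are projected orthogonally into it and an
    ellipse-constrained direct least-squares conic fit is solved in 2D.
    ``major_axis_mm`` (full length) is the polyp's longest length.
    """
    pts = border.points if isinstance(border, Border3D) else np.asarray(border, float).reshape(-1, 3)
    if len(pts) < _MIN_BORDER_POINTS:
        raise EllipseFitError(f"need >= {_MIN_BORDER_POINTS} points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, S, Vt = np.linalg.svd(centred, full_matrices=False)
    if S[1] < 1e-9 * max(S[0], 1e-30):
        raise EllipseFitError("points are collinear; no plane can be fitted")
    e1, e2, normal = Vt[0], Vt[1], Vt[2]
    xy = centred @ np.column_stack([e1, e2])
    conic = _fit_conic_2d(xy[:, 0], xy[:, 1])
    centre2d, semi_major, semi_minor, angle = _conic_to_geometric(conic)
    centre3d = centroid + centre2d[0] * e1 + centre2d[1] * e2
    major_dir = np.cos(angle) * e1 + np.sin(angle) * e2
    major_dir /= np.linalg.norm(major_dir)
    return EllipseFit3D(
        centre=centre3d,
        normal=normal / np.linalg.norm(normal),
        major_axis_mm=2.0 * semi_major,
        minor_axis_mm=2.0 * semi_minor,
        major_direction=major_dir,
        rms_fit_error_mm=_ellipse_rms_error(xy, centre2d, semi_major, semi_minor, angle),
    )


def landmark_distance(fit: EllipseFit3D, landmark: np.ndarray) -> float:
    """Euclidean distance (mm) from the ellipse centre to a landmark."""
    landmark = np.asarray(landmark, dtype=float).reshape(3)
    if not (np.all(np.isfinite(landmark)) and np.all(np.isfinite(fit.centre))):
        raise ValueError("non-finite centre or landmark")
    return float(np.linalg.norm(fit.centre - landmark))


def aggregate_pairs(estimates: list[PairEstimate], iqr_k: float = 1.5) -> PolypMeasurement:
    """Combine per-pair estimates with quartile outlier rejection.

    A stationary polyp should give the same reconstructed centre from every
    pair; pairs whose centre lies beyond Q3 + ``iqr_k``*IQR of the distances
    to the component-wise median centre are flagged and excluded, and the
    final size/location are the arithmetic means over the rest.  If every
    estimate would be flagged, the single one nearest the median centre is
    kept.
    """
    if not estimates:
        raise ReconstructionError("aggregate_pairs needs at least one estimate")
    centres = np.array([e.centre for e in estimates], dtype=float)
    median_centre = np.median(centres, axis=0)
    d = np.linalg.norm(centres - median_centre, axis=1)
    q1, q3 = np.percentile(d, [25.0, 75.0])
    fence = q3 + iqr_k * (q3 - q1)
    flags = d > fence
    if flags.all():
        keep = np.zeros(len(estimates), dtype=bool)
        keep[int(np.argmin(d))] = True
        flags = ~keep
    for e, flag in zip(estimates, flags):
        e.outlier = bool(flag)
    kept = [e for e in estimates if not e.outlier]
    return PolypMeasurement(
        per_pair=estimates,
        outlier_flags=[bool(f) for f in flags],
        final_size_mm=float(np.mean([e.size_mm for e in kept])),
        final_location_mm=float(np.mean([e.location_mm for e in kept])),
        n_pairs_used=len(kept),
    )


@dataclass
class MeasureOptions:
    """Knobs of the end-to-end measurement pipeline."""

    n_samples: int = 100
    sc_params: ShapeContextParams = field(default_factory=ShapeContextParams)
    residual_cap_mm: float = 2.0
    iqr_k: float = 1.5
    # per-pair screens applied before centre-based aggregation: a pair whose
    # reconstructed border is not well described by an ellipse, or whose size
    # disagrees with the cross-pair consensus, indicates a failed
    # correspondence (cyclic slip along the border reconstructs a smooth
    # phantom curve instead of the polyp)
    max_fit_error_mm: float = 0.5
    fit_error_median_factor: float = 3.0
    size_mad_k: float = 3.0
    thresholds: MotionThresholds = field(default_factory=MotionThresholds)
    correspondence: str = "shape_context"  # or "exact" (index pairing, synthetic data)
    min_region_px: int = 100
    fill_holes: bool = True
    active_contour: bool = False
    opening_radius: int = 2
    allow_poor_motion: bool = False


def _frame_contour(frame, options: MeasureOptions) -> BorderContour:
    if isinstance(frame, BorderContour):
        return frame
    if isinstance(frame, SegmentationMask):
        refined = refine_mask(
            frame,
            min_region_px=options.min_region_px,
            fill_holes=options.fill_holes,
            active_contour=False,
            opening_radius=options.opening_radius,
        )
        return extract_border(refined)
    raise TypeError(f"frame must be SegmentationMask or BorderContour, got {type(frame)}")


def measure_polyp(
    frames: list[tuple[SegmentationMask | BorderContour, CameraPose]],
    rig: RigConfig,
    landmark: np.ndarray,
    options: MeasureOptions = MeasureOptions(),
) -> PolypMeasurement:
    """End-to-end measurement from segmented frames with tracked poses.

    Pipeline: clean masks -> extract borders -> enumerate all frame pairs ->
    motion-quality gate -> shape-context matching -> triangulation ->
    3D ellipse fit -> landmark distance -> quartile aggregation.

    ``frames`` may carry masks or pre-extracted contours.  With
    ``correspondence="exact"`` both contours must have equal point counts
    and are paired index-to-index (synthetic ground-truth mode).
    """
    if len(frames) < 2:
        raise QualityGateError(f"need >= 2 frames, got {len(frames)}")
    contours = [_frame_contour(f, options) for f, _ in frames]
    poses = [p for _, p in frames]

    estimates: list[PairEstimate] = []
    rejected: list[tuple[tuple[str, str], list[str]]] = []
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            pair_id = (poses[i].frame_id, poses[j].frame_id)
            quality = check_pair(poses[i], poses[j], options.thresholds, rig)
            if not quality.passed and not options.allow_poor_motion:
                rejected.append((pair_id, list(quality.failed_rules)))
                continue
            try:
                if options.correspondence == "exact":
                    ci, cj = contours[i].points, contours[j].points
                    if len(ci) != len(cj):
                        raise ReconstructionError(
                            f"exact correspondence needs equal point counts, "
                            f"got {len(ci)} vs {len(cj)} for pair {pair_id}"
                        )
                    corr = CorrespondenceSet(
                        pairs=[(k, k) for k in range(len(ci))],
                        total_cost=0.0,
                        per_pair_cost=np.zeros(len(ci)),
                        points_p=ci,
                        points_q=cj,
                    )
                else:
                    corr = match_shapes(
                        contours[i], contours[j], options.n_samples, options.sc_params
                    )
                border = reconstruct_border(
                    corr,
                    poses[i],
                    poses[j],
                    rig,
                    residual_cap_mm=options.residual_cap_mm,
                    quality=quality,
                    allow_poor_motion=options.allow_poor_motion,
                )
                fit = fit_ellipse_3d(border)
            except (ReconstructionError, EllipseFitError) as exc:
                rejected.append((pair_id, [f"reconstruction: {exc}"]))
                continue
            estimates.append(
                PairEstimate(
                    source_pair=pair_id,
                    size_mm=fit.major_axis_mm,
                    centre=fit.centre,
                    location_mm=landmark_distance(fit, landmark),
                    n_points=len(border.points),
                    median_residual_mm=float(np.median(border.residuals_mm)),
                    rms_fit_error_mm=fit.rms_fit_error_mm,
                    quality=quality,
                )
            )
    if not estimates:
        detail = "; ".join(f"{pid}: {rules}" for pid, rules in rejected)
        raise QualityGateError(f"no valid view pair survived: {detail}")
    kept = _screen_estimates(estimates, options, rejected)
    result = aggregate_pairs(kept, iqr_k=options.iqr_k)
    flags = {id(e): e.outlier for e in kept}
    for e in estimates:
        e.outlier = flags.get(id(e), True)
    return PolypMeasurement(
        per_pair=estimates,
        outlier_flags=[e.outlier for e in estimates],
        final_size_mm=result.final_size_mm,
        final_location_mm=result.final_location_mm,
        n_pairs_used=result.n_pairs_used,
        rejected_pairs=rejected,
    )


def _screen_estimates(
    estimates: list[PairEstimate],
    options: MeasureOptions,
    rejected: list[tuple[tuple[str, str], list[str]]],
) -> list[PairEstimate]:
    """Drop pairs with failed correspondences before aggregation.

    A coherent tangential slip of the matched points along the border
    triangulates to the intersection curve of the two viewing cones — a
    smooth curve that is generally not an ellipse and has the wrong size
    while sharing the true centre, so the centre-based quartile rule cannot
    catch it.  Two screens target it: (1) ellipse-fit goodness — RMS fit
    error above max(``max_fit_error_mm``, ``fit_error_median_factor`` x the
    cohort median); (2) a median ± ``size_mad_k`` x MAD fence on the
    per-pair sizes (MAD rather than quartiles: it stays robust when phantom
    pairs approach half of the set).  If a screen would drop everything it
    is skipped.
    """
    fit_errors = np.array([e.rms_fit_error_mm for e in estimates])
    threshold = max(options.max_fit_error_mm,
                    options.fit_error_median_factor * float(np.median(fit_errors)))
    kept = [e for e in estimates if e.rms_fit_error_mm <= threshold]
    if not kept:
        kept = [min(estimates, key=lambda e: e.rms_fit_error_mm)]
    for e in estimates:
        if e not in kept:
            rejected.append(
                (e.source_pair, [f"ellipse_fit_error: {e.rms_fit_error_mm:.2f} mm > {threshold:.2f} mm"])
            )
    if len(kept) >= 4:
        sizes = np.array([e.size_mm for e in kept])
        med = float(np.median(sizes))
        mad = float(np.median(np.abs(sizes - med)))
        half_width = max(options.size_mad_k * mad, 0.5)
        consistent = [e for e in kept if abs(e.size_mm - med) <= half_width]
        if consistent:
            for e in kept:
                if e not in consistent:
                    rejected.append(
                        (e.source_pair,
                         [f"size_consistency: {e.size_mm:.2f} mm outside "
                          f"{med:.2f} ± {half_width:.2f} mm"])
                    )
            kept = consistent
    return kept
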