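"""Triangulated border reconstruction, 3D ellipse fitting and aggregation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from endopolyp.camera import CameraPose, project_many
from endopolyp.exceptions import (
    EllipseFitError,
    QualityGateError,
    ReconstructionError,
)
from endopolyp.reconstruction import (
    Border3D,
    MeasureOptions,
    PairEstimate,
    aggregate_pairs,
    fit_ellipse_3d,
    landmark_distance,
    measure_polyp,
    reconstruct_border,
)
from endopolyp.shape_context import CorrespondenceSet
from endopolyp.simulate import (
    NoiseModel,
    default_rig,
    make_polyp,
    make_pose_set,
    render_views,
    simulate_scene,
)


def _ellipse_points_3d(major=12.0, minor=7.0, n=40, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([0.5 * major * np.cos(t), 0.5 * minor * np.sin(t), np.zeros(n)])
    R = Rotation.random(rng=rng).as_matrix()
    centre = rng.uniform(-50, 50, 3)
    return pts @ R.T + centre, centre, R[:, 2]


def _exact_corr(polyp, pose_a, pose_b, rig):
    pa = project_many(polyp.border3d, pose_a, rig)
    pb = project_many(polyp.border3d, pose_b, rig)
    n = len(pa)
    return CorrespondenceSet(
        pairs=[(i, i) for i in range(n)],
        total_cost=0.0,
        per_pair_cost=np.zeros(n),
        points_p=pa,
        points_q=pb,
    )


class TestFitEllipse3D:
    def test_exact_recovery_arbitrary_orientation(self):
        pts, centre, normal = _ellipse_points_3d()
        fit = fit_ellipse_3d(pts)
        assert fit.major_axis_mm == pytest.approx(12.0, abs=1e-6)
        assert fit.minor_axis_mm == pytest.approx(7.0, abs=1e-6)
        assert fit.rms_fit_error_mm < 1e-9
        np.testing.assert_allclose(fit.centre, centre, atol=1e-6)
        assert abs(np.dot(fit.normal, normal)) == pytest.approx(1.0, abs=1e-9)

    def test_circle_diameter(self):
        pts, _, _ = _ellipse_points_3d(major=10.0, minor=10.0, seed=3)
        fit = fit_ellipse_3d(pts)
        assert fit.major_axis_mm == pytest.approx(10.0, abs=1e-6)
        assert fit.minor_axis_mm == pytest.approx(10.0, abs=1e-6)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        with pytest.raises(EllipseFitError, match="collinear"):
            fit_ellipse_3d(pts)

    def test_normal_perpendicular_to_major_direction(self):
        pts, _, _ = _ellipse_points_3d(seed=9)
        fit = fit_ellipse_3d(pts)
        assert abs(np.dot(fit.normal, fit.major_direction)) < 1e-9

    def test_agrees_with_skimage_ellipse_model_in_plane(self):
        # independent oracle: skimage's EllipseModel on noisy planar points
        from skimage.measure import EllipseModel

        rng = np.random.default_rng(17)
        t = rng.uniform(0, 2 * np.pi, 80)
        xy = np.column_stack([6.0 * np.cos(t), 3.5 * np.sin(t)]) + rng.normal(0, 0.05, (80, 2))
        model = EllipseModel.from_estimate(xy)
        assert model
        a, b = sorted(model.axis_lengths, reverse=True)
        pts3 = np.column_stack([xy, np.zeros(len(xy))])
        fit = fit_ellipse_3d(pts3)
        assert fit.major_axis_mm == pytest.approx(2 * a, rel=0.02)
        assert fit.minor_axis_mm == pytest.approx(2 * b, rel=0.02)


class TestLandmarkDistance:
    def test_zero_and_pythagorean(self):
        pts, centre, _ = _ellipse_points_3d(seed=2)
        fit = fit_ellipse_3d(pts)
        assert landmark_distance(fit, fit.centre) == 0.0
        fit.centre = np.zeros(3)
        assert landmark_distance(fit, np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0)

    def test_rigid_invariance(self):
        pts, _, _ = _ellipse_points_3d(seed=5)
        fit = fit_ellipse_3d(pts)
        landmark = np.array([100.0, -40.0, 20.0])
        d0 = landmark_distance(fit, landmark)
        g = Rotation.from_euler("xyz", [0.3, -0.8, 1.2])
        t = np.array([5.0, 6.0, -7.0])
        fit2 = fit_ellipse_3d(pts @ g.as_matrix().T + t)
        d1 = landmark_distance(fit2, g.as_matrix() @ landmark + t)
        assert d1 == pytest.approx(d0, abs=1e-6)


def _estimate(size, centre, location=100.0):
    return PairEstimate(
        source_pair=("a", "b"),
        size_mm=size,
        centre=np.asarray(centre, dtype=float),
        location_mm=location,
        n_points=50,
        median_residual_mm=0.1,
        rms_fit_error_mm=0.05,
    )


class TestAggregatePairs:
    def test_identical_estimates_no_outliers(self):
        ests = [_estimate(12.0, [1.0, 2.0, 3.0]) for _ in range(5)]
        out = aggregate_pairs(ests)
        assert out.outlier_flags == [False] * 5
        assert out.final_size_mm == 12.0
        assert out.n_pairs_used == 5

    def test_displaced_centre_flagged_against_quartile_oracle(self):
        rng = np.random.default_rng(6)
        centres = [rng.uniform(-0.25, 0.25, 3) for _ in range(9)]
        centres.append(np.array([50.0, 0.0, 0.0]))
        ests = [_estimate(10.0 + 0.01 * i, c) for i, c in enumerate(centres)]
        out = aggregate_pairs(ests)
        assert out.outlier_flags == [False] * 9 + [True]
        # independent quartile oracle: sorted-interpolation quartiles
        med = np.median(np.array(centres), axis=0)
        d = sorted(np.linalg.norm(np.array(centres) - med, axis=1))

        def quantile(sorted_vals, q):
            pos = q * (len(sorted_vals) - 1)
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            return sorted_vals[lo] + (pos - lo) * (sorted_vals[hi] - sorted_vals[lo])

        q1, q3 = quantile(d, 0.25), quantile(d, 0.75)
        fence = q3 + 1.5 * (q3 - q1)
        expected_flags = [
            float(np.linalg.norm(c - med)) > fence for c in centres
        ]
        assert out.outlier_flags == expected_flags

    def test_single_estimate_returned(self):
        out = aggregate_pairs([_estimate(8.0, [0.0, 0.0, 0.0], location=55.0)])
        assert out.final_size_mm == 8.0
        assert out.final_location_mm == 55.0
        assert out.n_pairs_used == 1

    def test_all_inlier_input_equals_plain_mean(self):
        rng = np.random.default_rng(13)
        ests = [
            _estimate(10.0 + rng.normal(0, 0.1), rng.normal(0, 0.2, 3), 100 + rng.normal(0, 0.1))
            for _ in range(8)
        ]
        out = aggregate_pairs(ests)
        if not any(out.outlier_flags):
            assert out.final_size_mm == pytest.approx(np.mean([e.size_mm for e in ests]))
            assert out.final_location_mm == pytest.approx(np.mean([e.location_mm for e in ests]))

    def test_empty_input_rejected(self):
        with pytest.raises(ReconstructionError):
            aggregate_pairs([])


class TestReconstructBorder:
    def test_noiseless_exact(self):
        rig = default_rig()
        polyp = make_polyp(12.0, 7.0, seed=2)
        poses = make_pose_set(polyp, seed=2, rig=rig)
        corr = _exact_corr(polyp, poses[0], poses[1], rig)
        border = reconstruct_border(corr, poses[0], poses[1], rig)
        assert np.max(border.residuals_mm) < 1e-6
        np.testing.assert_allclose(border.points, polyp.border3d, atol=1e-6)

    def test_failed_quality_check_blocks_without_override(self):
        rig = default_rig()
        polyp = make_polyp(12.0, 7.0, seed=2)
        poses = make_pose_set(polyp, seed=2, rig=rig)
        corr = _exact_corr(polyp, poses[0], poses[1], rig)
        from endopolyp.motion import PairQualityReport

        bad = PairQualityReport(1.0, 0.5, 45.0, failed_rules=["minimal_movement"])
        with pytest.raises(QualityGateError):
            reconstruct_border(corr, poses[0], poses[1], rig, quality=bad)
        border = reconstruct_border(
            corr, poses[0], poses[1], rig, quality=bad, allow_poor_motion=True
        )
        assert len(border.points) == len(polyp.border3d)

    def test_noisy_reconstruction_stays_below_half_mm(self):
        # 0.5 px pixel noise at ~60 mm working distance, ~20 mm baseline
        rig = default_rig()
        polyp = make_polyp(12.0, 7.0, seed=4)
        poses = make_pose_set(polyp, baseline_mm=(15.0, 25.0), seed=4, rig=rig)
        corr = _exact_corr(polyp, poses[0], poses[1], rig)
        rng = np.random.default_rng(99)
        corr.points_p = corr.points_p + rng.normal(0, 0.5, corr.points_p.shape)
        corr.points_q = corr.points_q + rng.normal(0, 0.5, corr.points_q.shape)
        border = reconstruct_border(corr, poses[0], poses[1], rig)
        assert np.median(border.residuals_mm) > 0
        rms = np.sqrt(np.mean(np.sum((border.points - polyp.border3d[: len(border.points)]) ** 2, axis=1)))
        # residual-capped points stay in registration with the true border
        assert rms < 0.5


class TestMeasurePolyp:
    def test_noiseless_end_to_end_exact_mode(self):
        scene = simulate_scene(seed=3, noise=NoiseModel(0, 0, 0))
        views = render_views(scene)
        frames = list(zip(views.contours, views.noisy_poses))
        res = measure_polyp(
            frames, scene.rig, scene.landmark, MeasureOptions(correspondence="exact")
        )
        true_loc = float(np.linalg.norm(scene.polyp.centre - scene.landmark))
        assert res.final_size_mm == pytest.approx(12.0, abs=1e-3)
        assert res.final_location_mm == pytest.approx(true_loc, abs=1e-3)

    def test_two_frames_use_exactly_one_pair(self):
        scene = simulate_scene(seed=5, n_views=2, noise=NoiseModel(0, 0, 0))
        views = render_views(scene)
        res = measure_polyp(
            list(zip(views.contours, views.noisy_poses)),
            scene.rig,
            scene.landmark,
            MeasureOptions(correspondence="exact"),
        )
        assert len(res.per_pair) == 1
        assert res.n_pairs_used == 1

    def test_all_pairs_too_close_raises_listing_rules(self):
        scene = simulate_scene(seed=3, noise=NoiseModel(0, 0, 0))
        views = render_views(scene)
        # collapse all camera positions to within 1 mm of the first
        rng = np.random.default_rng(0)
        squeezed = [
            CameraPose(
                views.noisy_poses[0].position + rng.uniform(-0.4, 0.4, 3),
                pose.orientation,
                pose.frame_id,
            )
            for pose in views.noisy_poses
        ]
        with pytest.raises(QualityGateError, match="minimal_movement"):
            measure_polyp(
                list(zip(views.contours, squeezed)),
                scene.rig,
                scene.landmark,
                MeasureOptions(correspondence="exact"),
            )

    def test_rigid_invariance_of_estimates(self):
        scene = simulate_scene(seed=8, noise=NoiseModel(0, 0, 0))
        views = render_views(scene)
        frames = list(zip(views.contours, views.noisy_poses))
        opts = MeasureOptions(correspondence="exact")
        res0 = measure_polyp(frames, scene.rig, scene.landmark, opts)

        g = Rotation.from_euler("zyx", [0.4, -0.9, 0.2])
        t = np.array([30.0, -10.0, 55.0])
        T = np.eye(4)
        T[:3, :3] = g.as_matrix()
        T[:3, 3] = t
        moved = [
            (c, CameraPose.from_matrix(T @ p.matrix, frame_id=p.frame_id)) for c, p in frames
        ]
        res1 = measure_polyp(moved, scene.rig, g.as_matrix() @ scene.landmark + t, opts)
        assert res1.final_size_mm == pytest.approx(res0.final_size_mm, abs=1e-6)
        assert res1.final_location_mm == pytest.approx(res0.final_location_mm, abs=1e-6)

    def test_size_rmse_degrades_monotonically_with_pixel_noise(self):
        # exact-correspondence mode isolates geometric noise propagation;
        # the full matcher is non-monotone at low sigma because a little
        # pixel noise dithers away systematic correspondence slip
        from endopolyp.simulate import cohort_rmse, run_accuracy_cohort

        rmses = []
        for sigma in (0.0, 0.5, 1.0, 2.0):
            recs = run_accuracy_cohort(
                n_polyps=30, base_seed=77, noise=NoiseModel(0.0, 0.0, sigma),
                correspondence="exact",
            )
            rmses.append(cohort_rmse(recs)[0])
        assert all(b >= a - 1e-9 for a, b in zip(rmses, rmses[1:])), rmses
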