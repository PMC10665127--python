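"""Rig calibration: corner detection, poses, circle/axis fits, virtual views."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from seedhull.calibration import (
    BoardSpec,
    CornerTrajectory,
    Intrinsics,
    RigidPose,
    RotationAxis,
    board_points,
    build_projection,
    calibrate_intrinsics,
    calibrate_rig,
    decompose_projection,
    detect_corners,
    estimate_board_pose,
    fit_rotation_axis,
    fit_trajectory_center,
    generate_virtual_views,
    rotate_pose,
)
from seedhull.errors import (
    DegenerateConfiguration,
    DegenerateTrajectory,
    IllConditionedAxisWarning,
    InsufficientCenters,
    InvalidIntrinsics,
    NoBoardFound,
)
from seedhull.synthetic import render_checkerboard, simulate_corner_trajectories


class TestDetectCorners:
    def test_all_81_corners_within_subpixel_tolerance(self, board_image, board):
        img, gt = board_image
        det = detect_corners(img, board)
        assert det.shape == (81, 2)
        err = np.linalg.norm(det - gt, axis=1)
        assert err.max() < 0.2

    def test_uniform_image_has_no_board(self, board):
        with pytest.raises(NoBoardFound):
            detect_corners(np.full((200, 200), 0.5), board)

    def test_inplane_rotation_reorders_same_physical_corners(self, rig, board):
        intr, base_pose, _ = rig
        c = np.array(
            [(board.cols - 1) * board.pitch / 2, (board.rows - 1) * board.pitch / 2, 0.0]
        )
        R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        pose90 = RigidPose(
            R=base_pose.R @ R90, T=base_pose.T + base_pose.R @ c - base_pose.R @ R90 @ c
        )
        img, gt = render_checkerboard(board, pose90, intr, (480, 480))
        det = detect_corners(img, board)
        # every detection matches some physical corner, bijectively
        d = np.linalg.norm(det[:, None, :] - gt[None, :, :], axis=2)
        match = d.argmin(axis=1)
        assert len(np.unique(match)) == 81
        assert d.min(axis=1).max() < 0.2
        # canonical origin: detection 0 is the extreme corner nearest top-left
        extremes = gt[[0, board.cols - 1, -board.cols, -1]]
        origin = extremes[np.argmin(np.linalg.norm(extremes, axis=1))]
        assert np.linalg.norm(det[0] - origin) < 0.2


class TestBoardPose:
    def test_noiseless_recovery_to_machine_precision(self, rig, board):
        intr, base_pose, _ = rig
        uv, _ = build_projection(intr, base_pose).project(board_points(board))
        pose = estimate_board_pose(uv, board, intr)
        rot_err = Rotation.from_matrix(pose.R.T @ base_pose.R).magnitude()
        assert rot_err < 1e-6
        assert np.linalg.norm(pose.T - base_pose.T) < 1e-6
        assert pose.residual < 1e-8

    def test_frontoparallel_board_recovers_distance(self, board):
        intr = Intrinsics(alpha_u=2000, alpha_v=2000, u0=240, v0=240)
        d = 30.0
        true = RigidPose(R=np.eye(3), T=np.array([-2.0, -2.0, d]))
        uv, _ = build_projection(intr, true).project(board_points(board))
        pose = estimate_board_pose(uv, board, intr)
        assert abs(pose.T[2] - d) < 1e-8
        assert np.allclose(pose.R, np.eye(3), atol=1e-8)

    def test_three_points_are_degenerate(self, board):
        intr = Intrinsics(alpha_u=2000, alpha_v=2000, u0=240, v0=240)
        with pytest.raises(DegenerateConfiguration):
            estimate_board_pose(np.array([[0.0, 0], [10, 0], [0, 10]]), board, intr)

    def test_collinear_points_are_degenerate(self, board):
        intr = Intrinsics(alpha_u=2000, alpha_v=2000, u0=240, v0=240)
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(DegenerateConfiguration):
            estimate_board_pose(pts, board, intr)


class TestIntrinsicsCalibration:
    def test_planar_calibration_recovers_rig(self, detected_sequence, board, rig):
        intr_true, _, _ = rig
        intr, poses = calibrate_intrinsics(detected_sequence, board)
        assert abs(intr.alpha_u - intr_true.alpha_u) / intr_true.alpha_u < 5e-3
        assert abs(intr.alpha_v - intr_true.alpha_v) / intr_true.alpha_v < 5e-3
        assert abs(intr.u0 - intr_true.u0) < 3.0
        assert abs(intr.v0 - intr_true.v0) < 3.0
        assert np.mean([p.residual for p in poses]) < 0.1


class TestCircleFit:
    @staticmethod
    def _circle(center, radius, normal, n=12, phase=0.0):
        normal = np.asarray(normal, float) / np.linalg.norm(normal)
        a = np.array([1.0, 0, 0])
        if abs(normal @ a) > 0.9:
            a = np.array([0, 1.0, 0])
        e1 = np.cross(normal, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        th = phase + np.linspace(0, 2 * np.pi, n, endpoint=False)
        return center + radius * (np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2)

    def test_exact_circle_is_fit_exactly(self):
        pts = self._circle(np.array([1.0, 2, 3]), 5.0, [0, 0, 1])
        fit = fit_trajectory_center(pts)
        assert np.allclose(fit.center, [1, 2, 3], atol=1e-9)
        assert abs(fit.radius - 5.0) < 1e-9
        assert fit.rms_residual < 1e-9
        assert abs(abs(fit.plane_normal[2]) - 1) < 1e-9

    def test_noisy_center_recovery_monte_carlo(self):
        # sigma = 0.01 mm isotropic noise: centre within 0.02 mm in >= 95%
        rng = np.random.default_rng(42)
        base = self._circle(np.array([1.0, 2, 3]), 5.0, [0, 0, 1])
        hits = 0
        for _ in range(500):
            noisy = base + rng.normal(scale=0.01, size=base.shape)
            fit = fit_trajectory_center(noisy)
            hits += np.linalg.norm(fit.center - [1, 2, 3]) < 0.02
        assert hits >= 475

    def test_collinear_points_raise(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 0.5])
        with pytest.raises(DegenerateTrajectory):
            fit_trajectory_center(pts)

    def test_too_few_points_raise(self):
        with pytest.raises(DegenerateTrajectory):
            fit_trajectory_center(np.array([[0.0, 0, 0], [1, 0, 0]]))


class TestAxisFit:
    def test_exact_line_of_centers(self):
        axis = fit_rotation_axis(np.array([[0.0, 0, 0], [0, 0, 1], [0, 0, 2]]))
        assert np.allclose(axis.point, [0, 0, 1])
        assert np.allclose(np.abs(axis.direction), [0, 0, 1])
        assert axis.direction[2] > 0  # tie toward +z when orthogonal to "up"

    def test_brute_force_scatter_oracle(self):
        rng = np.random.default_rng(3)
        centers = rng.normal(size=(50, 3)) * [0.01, 0.01, 2.0]
        axis = fit_rotation_axis(centers)
        # independent summation oracle for mean and scatter matrix
        m = np.zeros(3)
        for c in centers:
            m += c
        m /= len(centers)
        lam = np.zeros((3, 3))
        for c in centers:
            lam += np.outer(c - m, c - m)
        assert np.allclose(axis.point, m, atol=1e-12)
        # power iteration for the dominant eigenvector
        v = np.ones(3)
        for _ in range(200):
            v = lam @ v
            v /= np.linalg.norm(v)
        assert abs(abs(v @ axis.direction) - 1) < 1e-12

    def test_synthetic_trajectories_recover_skew_axis(self, rig, board):
        intr, base_pose, axis_true = rig
        trajs = simulate_corner_trajectories(
            board, intr, base_pose, axis_true, n_views=9, step_deg=9.0, n_corners=28
        )
        centers = np.array([fit_trajectory_center(t).center for t in trajs])
        axis = fit_rotation_axis(centers)
        ang = np.arccos(np.clip(abs(axis.direction @ axis_true.direction), -1, 1))
        assert np.degrees(ang) < 0.1

    def test_single_center_raises(self):
        with pytest.raises(InsufficientCenters):
            fit_rotation_axis(np.array([[1.0, 2, 3]]))

    def test_isotropic_centers_warn(self):
        rng = np.random.default_rng(0)
        with pytest.warns(IllConditionedAxisWarning):
            fit_rotation_axis(rng.normal(size=(500, 3)))


class TestProjection:
    def test_optical_axis_point_hits_principal_point(self):
        intr = Intrinsics(alpha_u=2000, alpha_v=2100, u0=320, v0=240, s_uv=0.5)
        P = build_projection(intr, RigidPose(R=np.eye(3), T=np.zeros(3)))
        uv, z = P.project(np.array([[0.0, 0, 10]]))
        assert z[0] > 0
        assert np.allclose(uv[0], [320, 240], atol=1e-9)

    def test_rq_decomposition_round_trip(self):
        rng = np.random.default_rng(1)
        intr = Intrinsics(alpha_u=1500.0, alpha_v=1600.0, u0=300.0, v0=250.0, s_uv=2.0)
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        T = rng.normal(size=3) + [0, 0, 60]
        P = build_projection(intr, RigidPose(R=R, T=T))
        intr2, pose2 = decompose_projection(P)
        assert np.allclose(intr2.K, intr.K, atol=1e-9)
        assert np.allclose(pose2.R, R, atol=1e-9)
        assert np.allclose(pose2.T, T, atol=1e-9)

    def test_nonpositive_focal_scale_is_invalid(self):
        with pytest.raises(InvalidIntrinsics):
            Intrinsics(alpha_u=0.0, alpha_v=2000, u0=0, v0=0)


class TestVirtualViews:
    def test_full_turn_closure(self, rig):
        intr, base_pose, axis = rig
        P0 = build_projection(intr, base_pose).P
        P360 = build_projection(intr, rotate_pose(base_pose, axis, 360.0)).P
        assert np.abs(P360 - P0).max() < 1e-9

    def test_axis_points_project_identically_in_all_views(self, rig):
        intr, base_pose, axis = rig
        projs = generate_virtual_views(base_pose, axis, intr, 9.0, 40)
        assert len(projs) == 40  # 9-degree steps over one revolution
        for s in (-1.0, 0.0, 2.0):
            w = base_pose.R.T @ (axis.point + s * axis.direction - base_pose.T)
            uv = np.array([P.project(w[None, :])[0][0] for P in projs])
            assert np.ptp(uv, axis=0).max() < 1e-9

    def test_input_validation(self, rig):
        intr, base_pose, axis = rig
        with pytest.raises(ValueError):
            generate_virtual_views(base_pose, axis, intr, 0.0, 40)
        with pytest.raises(ValueError):
            generate_virtual_views(base_pose, axis, intr, 9.0, 0)


class TestFullRigCalibration:
    def test_reprojection_consistency_through_virtual_views(
        self, detected_sequence, board, rig
    ):
        intr_true, _, axis_true = rig
        res = calibrate_rig(detected_sequence, board, step_deg=9.0, n_views=40)
        ang = np.arccos(np.clip(abs(res.axis.direction @ axis_true.direction), -1, 1))
        assert np.degrees(ang) < 0.1
        world = board_points(board)
        for k, det in enumerate(detected_sequence):
            P = build_projection(res.intrinsics, rotate_pose(res.poses[0], res.axis, k * 9.0))
            uv, _ = P.project(world)
            assert np.linalg.norm(uv - det, axis=1).max() < 0.5

    def test_json_round_trip(self, detected_sequence, board, tmp_path):
        res = calibrate_rig(detected_sequence[:4], board, step_deg=9.0, n_views=8)
        path = tmp_path / "calib.json"
        res.save(path)
        from seedhull.calibration import CalibrationResult

        back = CalibrationResult.load(path)
        assert np.allclose(back.projections[3].P, res.projections[3].P)
        assert np.allclose(back.axis.direction, res.axis.direction)
        assert back.intrinsics.alpha_u == pytest.approx(res.intrinsics.alpha_u)


class TestNoiseRobustness:
    def test_axis_recovery_with_pixel_noise(self, rig, board):
        intr, base_pose, axis_true = rig
        trajs = simulate_corner_trajectories(
            board, intr, base_pose, axis_true,
            n_views=9, step_deg=9.0, pixel_noise=0.1, n_corners=28,
            rng=np.random.default_rng(5),
        )
        centers = np.array([fit_trajectory_center(t).center for t in trajs])
        axis = fit_rotation_axis(centers)
        ang = np.arccos(np.clip(abs(axis.direction @ axis_true.direction), -1, 1))
        assert np.degrees(ang) < 0.5

    def test_trajectory_radius_equals_distance_to_axis(self, rig, board):
        intr, base_pose, axis = rig
        trajs = simulate_corner_trajectories(
            board, intr, base_pose, axis, n_views=9, step_deg=9.0, n_corners=5
        )
        for t in trajs:
            fit = fit_trajectory_center(t)
            p = t.points[0] - axis.point
            dist = np.linalg.norm(p - (p @ axis.direction) * axis.direction)
            assert fit.radius == pytest.approx(dist, abs=1e-8)
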