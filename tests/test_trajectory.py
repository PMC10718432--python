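import warnings

import numpy as np
import pytest

from reachdyn.trajectory import (
    ELBOW_EXTENSION_MARGIN,
    PROXIMAL_CLEARANCE,
    JointTrajectory,
    MovementSpec,
    differentiate_joint_trajectory,
    enumerate_movements,
    minimum_jerk_endpoint_trajectory,
    smooth_joint_trajectory,
    solve_inverse_kinematics,
    synthesize_movement,
)


def _vertex_map(grid):
    return {v.index: v for v in grid}


class TestMinimumJerk:
    @pytest.fixture()
    def traj(self, grid):
        vm = _vertex_map(grid)
        spec = MovementSpec(vm[(2, 0, 1)], vm[(0, 2, 0)], 1.0)
        return spec, minimum_jerk_endpoint_trajectory(spec)

    def test_boundary_conditions(self, traj):
        spec, ep = traj
        np.testing.assert_allclose(ep.position[0], spec.start.endpoint, atol=1e-12)
        np.testing.assert_allclose(ep.position[-1], spec.end.endpoint, atol=1e-12)
        np.testing.assert_allclose(ep.velocity[[0, -1]], 0.0, atol=1e-12)
        np.testing.assert_allclose(ep.acceleration[[0, -1]], 0.0, atol=1e-12)

    def test_sample_count(self, traj):
        spec, ep = traj
        assert len(ep.times) == round(spec.duration / spec.dt) + 1

    def test_path_is_straight(self, traj):
        spec, ep = traj
        d = spec.end.endpoint - spec.start.endpoint
        rel = ep.position - spec.start.endpoint
        cross = np.cross(rel, d)
        assert np.abs(cross).max() < 1e-12

    def test_peak_speed_value_and_time(self, traj):
        spec, ep = traj
        D = np.linalg.norm(spec.end.endpoint - spec.start.endpoint)
        speed = np.linalg.norm(ep.velocity, axis=1)
        assert speed.max() == pytest.approx(1.875 * D / spec.duration, rel=1e-9)
        assert ep.times[speed.argmax()] == pytest.approx(spec.duration / 2, abs=1e-9)

    def test_speed_profile_symmetric_and_unimodal(self, traj):
        _, ep = traj
        speed = np.linalg.norm(ep.velocity, axis=1)
        np.testing.assert_allclose(speed, speed[::-1], atol=1e-9)
        k = speed.argmax()
        assert np.all(np.diff(speed[: k + 1]) >= -1e-12)
        assert np.all(np.diff(speed[k:]) <= 1e-12)

    def test_speed_integral_equals_distance(self, traj):
        spec, ep = traj
        D = np.linalg.norm(spec.end.endpoint - spec.start.endpoint)
        speed = np.linalg.norm(ep.velocity, axis=1)
        assert np.trapezoid(speed, ep.times) == pytest.approx(D, abs=1e-6)


class TestWorkspaceGrid:
    def test_27_vertices(self, grid):
        assert len(grid) == 27
        assert len({v.index for v in grid}) == 27

    def test_j_vertex_posture(self, grid, arm_model):
        # middle-height lateral vertex: shoulder flexion-extension exactly
        # horizontal, elbow effectively extended
        v = _vertex_map(grid)[(2, 0, 1)]
        assert v.anchor_posture[arm_model.dof_index("shoulder_fe")] == 0.0
        assert v.anchor_posture[arm_model.dof_index("elbow_fe")] <= ELBOW_EXTENSION_MARGIN + 1e-12

    def test_lateral_column_elevations(self, grid):
        vm = _vertex_map(grid)
        z = [vm[(2, 0, k)].endpoint[2] for k in range(3)]
        assert z[0] < z[1] < z[2]
        assert z[0] == pytest.approx(-z[2] + 2 * z[1], abs=0.05)

    def test_proximal_vertices_at_clearance(self, grid):
        for v in grid:
            if v.index[0] == 0:
                assert v.endpoint[0] == pytest.approx(PROXIMAL_CLEARANCE)

    def test_medial_column_toward_contralateral_shoulder(self, grid, arm_model):
        vm = _vertex_map(grid)
        for k in range(3):
            assert vm[(0, 2, k)].endpoint[1] > vm[(0, 0, k)].endpoint[1] + 0.12
            assert vm[(0, 2, k)].endpoint[1] <= arm_model.shoulder_separation + 1e-9
        # middle column midway in the medio-lateral direction
        y0, y1, y2 = (vm[(0, j, 1)].endpoint[1] for j in range(3))
        assert y1 == pytest.approx(0.5 * (y0 + y2), abs=1e-9)

    def test_anchor_postures_reach_their_endpoints(self, grid, arm_model):
        for v in grid:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = arm_model.forward_kinematics(v.anchor_posture)
            assert np.linalg.norm(p - v.endpoint) < 1e-6, v.index

    def test_static_dofs_at_neutral_in_anchors(self, grid, arm_model):
        neutral = arm_model.neutral_q()
        stat = arm_model.static_dofs
        for v in grid:
            np.testing.assert_allclose(v.anchor_posture[stat], neutral[stat], atol=1e-12)


class TestEnumerateMovements:
    def test_full_grid_one_duration(self, grid):
        assert len(enumerate_movements(grid, durations=(1.0,))) == 351

    def test_full_grid_three_durations(self, grid):
        assert len(enumerate_movements(grid, durations=(0.5, 1.0, 2.0))) == 1053

    def test_two_vertices(self, grid):
        assert len(enumerate_movements(grid[:2], durations=(1.0,))) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            enumerate_movements([], durations=(1.0,))


class TestInverseKinematics:
    def test_constant_trajectory_is_fixed_point(self, grid, arm_model):
        from reachdyn.trajectory import EndpointTrajectory

        v = _vertex_map(grid)[(1, 1, 1)]
        T = 50
        ep = EndpointTrajectory(
            times=np.arange(T) * 1e-3,
            position=np.tile(v.endpoint, (T, 1)),
            velocity=np.zeros((T, 3)),
            acceleration=np.zeros((T, 3)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            jt = solve_inverse_kinematics(arm_model, ep, v.anchor_posture)
        np.testing.assert_allclose(jt.q, np.tile(v.anchor_posture, (T, 1)), atol=1e-9)

    def test_roundtrip_residual_on_well_conditioned_movement(self, grid, arm_model):
        # a mid-workspace movement that stays clear of the singular sheets
        vm = _vertex_map(grid)
        spec = MovementSpec(vm[(1, 0, 1)], vm[(1, 2, 1)], 1.0)
        ep = minimum_jerk_endpoint_trajectory(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            jt = solve_inverse_kinematics(arm_model, ep, spec.start.anchor_posture)
            worst = max(
                np.linalg.norm(arm_model.forward_kinematics(jt.q[i]) - ep.position[i])
                for i in range(len(ep.times))
            )
        assert worst < 1e-6

    def test_interstep_continuity(self, grid, arm_model):
        vm = _vertex_map(grid)
        spec = MovementSpec(vm[(0, 0, 0)], vm[(2, 2, 2)], 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            jt = synthesize_movement(arm_model, spec)
        assert np.abs(np.diff(jt.q, axis=0)).max() < 0.05

    def test_distant_initialization_rejected(self, grid, arm_model):
        vm = _vertex_map(grid)
        spec = MovementSpec(vm[(2, 0, 1)], vm[(0, 0, 0)], 1.0)
        ep = minimum_jerk_endpoint_trajectory(spec)
        with pytest.raises(Exception, match="1 cm"):
            solve_inverse_kinematics(arm_model, ep, vm[(0, 0, 0)].anchor_posture)

    def test_static_dofs_pinned(self, grid, arm_model):
        vm = _vertex_map(grid)
        spec = MovementSpec(vm[(1, 1, 0)], vm[(1, 1, 2)], 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            jt = synthesize_movement(arm_model, spec)
        stat = arm_model.static_dofs
        assert np.ptp(jt.q[:, stat], axis=0).max() == 0.0
        assert np.abs(jt.qd[:, stat]).max() == 0.0
        assert np.abs(jt.qdd[:, stat]).max() == 0.0


class TestDifferentiation:
    def test_constant_gives_exact_zeros(self):
        q = np.ones((50, 4))
        jt = differentiate_joint_trajectory(JointTrajectory(np.arange(50) * 1e-3, q), 1e-3)
        assert np.all(jt.qd == 0.0) and np.all(jt.qdd == 0.0)

    def test_linear_ramp_exact_interior(self):
        t = np.arange(100) * 1e-3
        q = np.outer(t, [2.0, -0.5])
        jt = differentiate_joint_trajectory(JointTrajectory(t, q), 1e-3)
        np.testing.assert_allclose(jt.qd[1:-1], np.tile([2.0, -0.5], (98, 1)), atol=1e-9)
        np.testing.assert_allclose(jt.qdd[2:-2], 0.0, atol=1e-6)

    def test_quadratic_curvature_exact_interior(self):
        t = np.arange(200) * 1e-3
        a = 3.7
        q = (a * t**2)[:, None]
        jt = differentiate_joint_trajectory(JointTrajectory(t, q), 1e-3)
        np.testing.assert_allclose(jt.qdd[2:-2], 2 * a, rtol=1e-7)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            differentiate_joint_trajectory(JointTrajectory(np.arange(2), np.zeros((2, 3))), 1e-3)

    def test_smoothing_preserves_static_columns(self):
        # moving channel: a quintic ramp (band-limited well below cutoff)
        t = np.arange(400) * 1e-3
        u = t / t[-1]
        ramp = 10 * u**3 - 15 * u**4 + 6 * u**5
        q = np.column_stack([ramp, np.full_like(t, 0.7)])
        sm = smooth_joint_trajectory(JointTrajectory(t, q), 1e-3, 10.0)
        assert np.all(sm.q[:, 1] == 0.7)
        np.testing.assert_allclose(sm.q[:, 0], ramp, atol=2e-3)
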