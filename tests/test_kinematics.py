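"""Inverse/forward kinematics, planning, and numerical differentiation."""

import numpy as np
import pytest

import trunkreach as tr
from trunkreach.kinematics import differentiate_series


class TestInverseKinematics:
    def test_near_full_extension_reference_posture(self, body):
        eps = 1e-6
        th1, th2 = tr.inverse_kinematics(
            (body.L1 + body.L2 - eps, 0.0), body.L1, body.L2
        )
        assert abs(th1) < 5e-3 and 0 < th2 < 5e-3

    def test_right_angle_elbow_on_y_axis(self):
        # L1 = L2 = L, hand at (0, sqrt(2) L): elbow bent 90 deg, shoulder
        # at 45 deg (verified by forward kinematics:
        # L u(pi/4) + L u(3 pi/4) = (0, sqrt(2) L))
        L = 0.3
        th1, th2 = tr.inverse_kinematics((0.0, np.sqrt(2.0) * L), L, L)
        assert th2 == pytest.approx(np.pi / 2)
        assert th1 == pytest.approx(np.pi / 4)

    def test_printed_initial_posture_roundtrips(self, body):
        hand = np.array([-0.228, 0.25])
        th1, th2 = tr.inverse_kinematics(hand, body.L1, body.L2)
        assert 0 < th2 < np.pi  # elbow-flexed branch
        # forward kinematics in the shoulder frame reproduces the point
        x = body.L1 * np.cos(th1) + body.L2 * np.cos(th1 + th2)
        y = body.L1 * np.sin(th1) + body.L2 * np.sin(th1 + th2)
        np.testing.assert_allclose([x, y], hand, atol=1e-12)

    @pytest.mark.parametrize("elbow_sign", [+1, -1])
    def test_fk_ik_roundtrip_on_random_interior_points(self, body, rng, elbow_sign):
        """IK(FK) = identity on 1000 random workspace-interior points."""
        lo, hi = abs(body.L1 - body.L2), body.reach
        r = rng.uniform(lo + 0.01, hi - 0.01, 1000)
        ang = rng.uniform(-np.pi, np.pi, 1000)
        pts = np.stack([r * np.cos(ang), r * np.sin(ang)], axis=-1)
        th1, th2 = tr.inverse_kinematics(pts, body.L1, body.L2, elbow_sign=elbow_sign)
        assert np.all(elbow_sign * th2 > 0)
        x = body.L1 * np.cos(th1) + body.L2 * np.cos(th1 + th2)
        y = body.L1 * np.sin(th1) + body.L2 * np.sin(th1 + th2)
        np.testing.assert_allclose(np.stack([x, y], axis=-1), pts, atol=1e-10)

    def test_outside_workspace_raises(self, body):
        with pytest.raises(tr.UnreachableError):
            tr.inverse_kinematics((body.reach + 0.01, 0.0), body.L1, body.L2)
        with pytest.raises(tr.UnreachableError):
            tr.inverse_kinematics((0.05, 0.0), body.L1, body.L2)

    def test_boundary_raises_singular(self, body):
        with pytest.raises(tr.SingularConfigurationError):
            tr.inverse_kinematics((body.reach, 0.0), body.L1, body.L2)


class TestForwardKinematics:
    def test_reference_posture(self, body):
        hand = tr.forward_kinematics(tr.JointState(0.0, 0.0, 0.0), body)
        np.testing.assert_allclose(hand, [body.s + body.reach, 0.0], atol=1e-15)

    def test_trunk_rotation_moves_hand_on_circle(self, body, rng):
        """With the arm frozen, varying the trunk angle keeps the hand on a
        circle about the trunk axis."""
        th1, th2 = 0.9, 1.8
        th3 = rng.uniform(-np.pi, np.pi, 50)
        pos = tr.forward_kinematics(np.full(50, th1), body, np.full(50, th2), th3)
        radii = np.linalg.norm(pos, axis=1)
        np.testing.assert_allclose(radii, radii[0], atol=1e-12)


class TestDifferentiateSeries:
    def test_exact_on_linear(self):
        t = np.arange(0, 1, 1e-3)
        d1, d2 = differentiate_series(3.7 * t, 1e-3)
        np.testing.assert_allclose(d1, 3.7, atol=1e-9)
        np.testing.assert_allclose(d2, 0.0, atol=1e-6)

    def test_exact_on_quadratic(self):
        t = np.arange(0, 1, 1e-3)
        d1, d2 = differentiate_series(t**2, 1e-3)
        np.testing.assert_allclose(d2, 2.0, atol=1e-6)
        np.testing.assert_allclose(d1, 2 * t, atol=1e-9)

    def test_truncation_error_on_sine(self):
        t = np.arange(0, 1, 1e-3)
        d1, _ = differentiate_series(np.sin(t), 1e-3)
        assert np.max(np.abs(d1 - np.cos(t))) < 1e-6

    def test_too_few_samples_rejected(self):
        with pytest.raises(tr.GridError):
            differentiate_series(np.zeros(4), 1e-3)


def _space_path_and_zero_torso(body, amplitude=0.0, direction=tr.CCW):
    shift = np.array([body.s, 0.0])
    path = tr.min_jerk_path(
        np.array([-0.228, 0.25]) + shift, np.array([-0.2258, 0.65]) + shift,
        0.4, 1e-3,
    )
    torso = tr.torso_profile(amplitude, direction, 0.4, 1e-3)
    return path, torso


class TestPlanJointSeries:
    def test_zero_rotation_plan_equals_raw_inverse_kinematics(self, body):
        path, torso = _space_path_and_zero_torso(body)
        plan = tr.plan_joint_series(path, torso, body)
        th1, th2 = tr.inverse_kinematics(path.pos - [body.s, 0.0], body.L1, body.L2)
        np.testing.assert_allclose(plan.th[:, 0], th1, atol=1e-12)
        np.testing.assert_allclose(plan.th[:, 1], th2, atol=1e-12)
        np.testing.assert_allclose(plan.th[:, 2], 0.0, atol=1e-15)

    def test_space_plan_reproduces_desired_path_under_rotation(self, body):
        """Planning a space-fixed line under the accurate rotation, forward
        kinematics of the plan returns the line to 1e-9 m."""
        path, _ = _space_path_and_zero_torso(body)
        torso = tr.torso_profile(np.deg2rad(40.0), tr.CCW, 0.4, 1e-3)
        plan = tr.plan_joint_series(path, torso, body)
        got = tr.forward_kinematics(plan.th[:, 0], body, plan.th[:, 1], plan.th[:, 2])
        np.testing.assert_allclose(got, path.pos, atol=1e-9)

    def test_trunk_frame_plan_is_rotation_independent(self, body):
        """For a trunk-fixed target the shoulder/elbow plan must not depend
        on the believed rotation at all."""
        shift = np.array([body.s, 0.0])
        path = tr.min_jerk_path(
            np.array([-0.228, 0.25]) + shift, np.array([-0.2258, 0.65]) + shift,
            0.4, 1e-3, frame="trunk",
        )
        small = tr.torso_profile(0.1, tr.CCW, 0.4, 1e-3)
        large = tr.torso_profile(1.0, tr.CW, 0.4, 1e-3)
        a = tr.plan_joint_series(path, small, body)
        b = tr.plan_joint_series(path, large, body)
        np.testing.assert_allclose(a.th[:, :2], b.th[:, :2], atol=1e-14)
        np.testing.assert_allclose(a.om[:, :2], b.om[:, :2], atol=1e-14)
        np.testing.assert_allclose(a.th[:, 2], small.value)
        np.testing.assert_allclose(b.th[:, 2], large.value)

    def test_elbow_extends_monotonically_during_reach(self, body):
        path, torso = _space_path_and_zero_torso(body)
        plan = tr.plan_joint_series(path, torso, body)
        assert np.all(np.diff(plan.th[:, 1]) < 0)  # theta2 shrinks: extension

    def test_numeric_derivatives_agree_with_analytic(self, body):
        path, _ = _space_path_and_zero_torso(body)
        torso = tr.torso_profile(np.deg2rad(40.0), tr.CCW, 0.4, 1e-3)
        a = tr.plan_joint_series(path, torso, body, method="analytic")
        n = tr.plan_joint_series(path, torso, body, method="numeric")
        # stencil truncation: ~dt^2 * max|theta''''| / 6 ~ 3e-4 rad/s on
        # this trajectory; the acceleration stencil is an order worse
        np.testing.assert_allclose(n.om[:, :2], a.om[:, :2], atol=1e-3)
        np.testing.assert_allclose(n.al[:, :2], a.al[:, :2], atol=0.5)

    def test_unreachable_sample_names_the_time(self, body):
        shift = np.array([body.s, 0.0])
        path = tr.min_jerk_path(
            np.array([-0.228, 0.25]) + shift, np.array([0.0, 0.68]) + shift,
            0.4, 1e-3,
        )
        # a large clockwise rotation carries the shoulder away from the
        # space-fixed target until it is out of reach
        torso = tr.torso_profile(np.deg2rad(60.0), tr.CW, 0.4, 1e-3)
        with pytest.raises(tr.UnreachableError, match="t="):
            tr.plan_joint_series(path, torso, body)
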