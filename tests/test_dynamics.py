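"""Closed-form dynamics vs independent numerics, decomposition structure,
and the forward integrator."""

import numpy as np
import pytest
from scipy.integrate import simpson

import trunkreach as tr
from trunkreach.dynamics import (
    coefficients,
    inertia_matrix,
    kinetic_energy,
)
from trunkreach.validation import (
    _smooth_test_series,
    oracle_discrepancy,
    random_states,
)


class TestCoefficients:
    def test_inertia_matrix_symmetric(self, body, rng):
        th1 = rng.uniform(-np.pi, np.pi, 200)
        th2 = rng.uniform(0.05, np.pi - 0.05, 200)
        H = inertia_matrix(coefficients(th1, th2, body))
        np.testing.assert_allclose(H, np.swapaxes(H, -1, -2), atol=1e-15)

    def test_inertia_matrix_positive_definite_across_workspace(self, body, rng):
        th1 = rng.uniform(-np.pi, np.pi, 1000)
        th2 = rng.uniform(0.05, np.pi - 0.05, 1000)
        H = inertia_matrix(coefficients(th1, th2, body))
        np.linalg.cholesky(H)  # raises LinAlgError if any is not PD

    def test_diagonal_entries_positive(self, body, rng):
        th1 = rng.uniform(-np.pi, np.pi, 500)
        th2 = rng.uniform(0.0, np.pi, 500)
        co = coefficients(th1, th2, body)
        assert np.all(co.H4 > 0) and np.all(co.H6 > 0) and np.all(co.H1 > 0)

    def test_hessian_of_kinetic_energy(self, body, rng):
        """H equals the velocity Hessian of the kinetic energy, obtained
        independently from the geometric energy function."""
        from trunkreach.dynamics import _mass_matrix_numeric

        for _ in range(25):
            q = np.array(
                [rng.uniform(-np.pi, np.pi), rng.uniform(0.05, np.pi - 0.05),
                 rng.uniform(-np.pi, np.pi)]
            )
            H = inertia_matrix(coefficients(q[0], q[1], body))
            np.testing.assert_allclose(H, _mass_matrix_numeric(q, body), atol=1e-8)


class TestInverseDynamics:
    def test_static_posture_has_zero_torque(self, body):
        grid = tr.TimeGrid(0.01, 1e-3)
        n = grid.n
        series = tr.KinematicSeries(
            grid, np.tile([0.8, 1.9, 0.3], (n, 1)), np.zeros((n, 3)), np.zeros((n, 3))
        )
        dec = tr.inverse_dynamics(series, body)
        np.testing.assert_allclose(dec.net, 0.0, atol=1e-15)

    def test_matches_lagrangian_oracle_on_random_states(self, body, rng):
        """Closed forms agree with the numerically evaluated Euler-Lagrange
        equations to well below 1e-7 N m."""
        states = random_states(150, rng)
        assert oracle_discrepancy(states, body) < 1e-7

    def test_two_link_limit_matches_textbook_equations(self, rng):
        """With the trunk frozen and the shoulder on the axis, the
        shoulder/elbow rows reduce to the standard planar two-link model."""
        body = tr.build_body_model(1.78, 80.0, {"s": 1e-30})
        a1 = body.I1 + body.m1 * body.r1**2 + body.m2 * body.L1**2
        a2 = body.I2 + body.m2 * body.r2**2
        k = body.L1 * body.m2 * body.r2
        for _ in range(50):
            t1, t2 = rng.uniform(-np.pi, np.pi), rng.uniform(0.05, np.pi - 0.05)
            w1, w2 = rng.uniform(-10, 10, 2)
            al1, al2 = rng.uniform(-100, 100, 2)
            c2, s2 = np.cos(t2), np.sin(t2)
            tau1 = (a1 + a2 + 2 * k * c2) * al1 + (a2 + k * c2) * al2 \
                - k * s2 * (2 * w1 * w2 + w2**2)
            tau2 = (a2 + k * c2) * al1 + a2 * al2 + k * s2 * w1**2
            grid = tr.TimeGrid(0.01, 1e-3)
            n = grid.n
            series = tr.KinematicSeries(
                grid,
                np.tile([t1, t2, 0.0], (n, 1)),
                np.tile([w1, w2, 0.0], (n, 1)),
                np.tile([al1, al2, 0.0], (n, 1)),
            )
            dec = tr.inverse_dynamics(series, body)
            np.testing.assert_allclose(dec.net[0, :2], [tau1, tau2], atol=1e-10)

    def test_components_sum_to_net(self, body, rng):
        grid = tr.TimeGrid(0.2, 1e-3)
        n = grid.n
        series = tr.KinematicSeries(
            grid,
            rng.uniform(-2, 2, (n, 3)),
            rng.uniform(-8, 8, (n, 3)),
            rng.uniform(-60, 60, (n, 3)),
        )
        dec = tr.inverse_dynamics(series, body)
        total = (
            dec.normal_inertial + dec.inertial_interaction
            + dec.centripetal + dec.coriolis
        )
        np.testing.assert_allclose(total, dec.net, atol=1e-10)

    def test_normal_inertial_unaffected_by_trunk_kinematics(self, body, rng):
        """The own-joint acceleration term of shoulder and elbow must not
        change when only the trunk kinematics change."""
        grid = tr.TimeGrid(0.2, 1e-3)
        n = grid.n
        th = rng.uniform(-2, 2, (n, 3))
        om = rng.uniform(-8, 8, (n, 3))
        al = rng.uniform(-60, 60, (n, 3))
        a = tr.inverse_dynamics(tr.KinematicSeries(grid, th, om, al), body)
        om2, al2 = om.copy(), al.copy()
        om2[:, 2] = rng.uniform(-8, 8, n)
        al2[:, 2] = rng.uniform(-60, 60, n)
        b = tr.inverse_dynamics(tr.KinematicSeries(grid, th, om2, al2), body)
        np.testing.assert_allclose(
            a.normal_inertial[:, :2], b.normal_inertial[:, :2], atol=1e-15
        )

    def test_power_balance_along_trajectory(self, body):
        """d(kinetic energy)/dt = sum tau_j omega_j, checked in integrated
        form; validates H and A jointly against the geometric energy."""
        series = _smooth_test_series(body)
        tau = tr.inverse_dynamics(series, body).net
        P = np.sum(tau * series.om, axis=1)
        T_kin = kinetic_energy(series, body)
        t = series.grid.t
        work = np.array(
            [0.0] + [simpson(P[: i + 1], x=t[: i + 1]) for i in range(1, t.size)]
        )
        resid = np.max(np.abs(T_kin - T_kin[0] - work))
        assert resid / np.max(np.abs(T_kin - T_kin[0])) < 1e-6


class TestCorruptedCommands:
    @pytest.fixture(scope="class")
    def plan_and_torso(self, body):
        shift = np.array([body.s, 0.0])
        path = tr.min_jerk_path(
            np.array([-0.228, 0.25]) + shift, np.array([-0.2258, 0.65]) + shift,
            0.4, 1e-3, frame="trunk",
        )
        torso = tr.torso_profile(np.deg2rad(40.0), tr.CCW, 0.4, 1e-3)
        plan = tr.plan_joint_series(path, torso, body)
        return plan, torso

    def test_veridical_belief_reproduces_accurate_commands(self, body, plan_and_torso):
        plan, torso = plan_and_torso
        believed, _ = tr.scale_torso(torso, 1.0)
        np.testing.assert_allclose(
            tr.corrupted_commands(plan, believed, body).net,
            tr.inverse_dynamics(plan, body).net,
            atol=1e-12,
        )

    def test_total_neglect_equals_norotation_dynamics(self, body, plan_and_torso):
        """Believing the trunk is still must reproduce the torques of the
        same arm motion computed with zero trunk kinematics."""
        plan, torso = plan_and_torso
        zero = tr.torso_profile(0.0, tr.CCW, 0.4, 1e-3)
        got = tr.corrupted_commands(plan, zero, body)
        still = tr.KinematicSeries(plan.grid, plan.th, plan.om.copy(), plan.al.copy())
        still.om[:, 2] = 0.0
        still.al[:, 2] = 0.0
        want = tr.inverse_dynamics(still, body)
        np.testing.assert_allclose(got.net, want.net, atol=1e-12)

    def test_underestimation_perturbs_shoulder_more_than_elbow(self, body, plan_and_torso):
        plan, torso = plan_and_torso
        believed, _ = tr.scale_torso(torso, 1.5)
        acc = tr.inverse_dynamics(plan, body)
        cor = tr.corrupted_commands(plan, believed, body)
        rms = tr.rms_torque_change(cor, acc)
        assert rms[0] > rms[1]


class TestForwardDynamics:
    def test_id_fd_round_trip(self, body):
        """Torques from inverse dynamics, integrated forward, recover the
        original joint trajectory to 1e-6 rad."""
        res = tr.run_condition(tr.Condition(G=1.0))
        drift = np.max(np.abs(res.executed.th[:, :2] - res.plan.th[:, :2]))
        assert drift < 1e-6

    def test_round_trip_reproduces_commanded_torques(self, body):
        """ID -> FD -> ID returns the commanded torques to 1e-6 N m."""
        res = tr.run_condition(tr.Condition(G=1.0))
        back = tr.inverse_dynamics(res.executed, body)
        # executed accelerations come from the dynamics itself, so comparing
        # net torques closes the loop
        np.testing.assert_allclose(
            back.net[:, :2], res.commands.net[:, :2], atol=1e-6
        )

    def test_convergence_under_grid_refinement(self):
        e1 = tr.run_condition(tr.Condition(G=1.5, dt=1e-3)).final_error
        e2 = tr.run_condition(tr.Condition(G=1.5, dt=5e-4)).final_error
        assert abs(e2 - e1) / e1 < 1e-3

    def test_linear_interpolation_fallback_close_to_cubic(self):
        a = tr.run_condition(tr.Condition(G=1.5)).final_error
        b = tr.run_condition(tr.Condition(G=1.5, torque_interp="linear")).final_error
        assert b == pytest.approx(a, rel=1e-3)
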