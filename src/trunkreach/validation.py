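"""Mechanical self-consistency checks of the simulator.

These checks validate the hard-coded closed-form dynamics against
independent numerics and the pipeline against its own inverse:

* closed-form inverse dynamics vs the numerical Euler-Lagrange oracle on
  random states;
* positive definiteness of the inertia matrix across the workspace;
* power balance d(KE)/dt = sum tau_j * omega_j along a smooth trajectory
  (checked in integrated form with Simpson quadrature);
* inverse-dynamics -> forward-dynamics round trip on the planned reach;
* zero final hand error at G = 1;
* left/right mirror symmetry of the final hand error;
* grid-refinement convergence of the final hand error.

The CLI ``validate`` subcommand and the test suite both call
:func:`run_validation`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import simpson

from .anthropometry import BodyModel, build_body_model
from .dynamics import (
    coefficients,
    forward_dynamics,
    inertia_matrix,
    inverse_dynamics,
    kinetic_energy,
    lagrangian_oracle,
)
from .experiment import Condition, final_hand_error, run_condition
from .kinematics import JointState, KinematicSeries
from .trajectory import TimeGrid

__all__ = ["Check", "run_validation", "random_states", "oracle_discrepancy"]


@dataclass
class Check:
    name: str
    value: float
    tol: float

    @property
    def passed(self) -> bool:
        return self.value <= self.tol

    def __str__(self) -> str:
        flag = "PASS" if self.passed else "FAIL"
        return f"[{flag}] {self.name}: {self.value:.3e} (tol {self.tol:.1e})"


def random_states(n: int, rng: np.random.Generator) -> list[JointState]:
    """Random dynamic states across the elbow-flexed workspace with
    physiologically-scaled velocities and accelerations."""
    th1 = rng.uniform(-np.pi, np.pi, n)
    th2 = rng.uniform(0.05, np.pi - 0.05, n)
    th3 = rng.uniform(-np.pi, np.pi, n)
    om = rng.uniform(-10, 10, (n, 3))
    al = rng.uniform(-100, 100, (n, 3))
    return [
        JointState(th1[i], th2[i], th3[i], *om[i], *al[i]) for i in range(n)
    ]


def oracle_discrepancy(
    states: list[JointState], body: BodyModel, *, corrupt_h3: float = 0.0
) -> float:
    """Max |closed-form torque - Lagrangian-oracle torque| over states (N m).

    ``corrupt_h3`` adds a deliberate offset to the closed-form h3
    coefficient's contribution (a negative-control hook: any nonzero value
    must make this check fail).
    """
    worst = 0.0
    for st in states:
        th = th_arr = np.array([[st.th1, st.th2, st.th3]])
        om = np.array([[st.w1, st.w2, st.w3]])
        al = np.array([[st.a1, st.a2, st.a3]])
        from .dynamics import _decompose

        grid = None
        dec = _decompose(th_arr, om, al, body, grid)
        tau = dec.net[0].copy()
        if corrupt_h3:
            # h3 multiplies w3^2 in the shoulder row
            tau[0] += corrupt_h3 * st.w3**2
        ref = lagrangian_oracle(st, body)
        worst = max(worst, float(np.max(np.abs(tau - ref))))
    return worst


def _smooth_test_series(body: BodyModel, T: float = 0.4, dt: float = 1e-3) -> KinematicSeries:
    """Analytic quintic joint trajectory (exact derivatives) spanning a
    realistic chunk of the workspace, for energy/round-trip checks."""
    grid = TimeGrid(T, dt)
    u = grid.t / T
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    ds = (30 * u**2 - 60 * u**3 + 30 * u**4) / T
    dds = (60 * u - 180 * u**2 + 120 * u**3) / T**2
    start = np.array([1.9, 2.3, 0.0])
    delta = np.array([-0.6, -1.3, 0.7])
    th = start + np.multiply.outer(s, delta)
    om = np.multiply.outer(ds, delta)
    al = np.multiply.outer(dds, delta)
    return KinematicSeries(grid, th, om, al)


def run_validation(
    body: BodyModel | None = None,
    *,
    n_states: int = 1000,
    seed: int = 0,
    corrupt_h3: float = 0.0,
) -> list[Check]:
    """Run the full self-consistency suite; returns one :class:`Check` per
    property."""
    body = body or build_body_model(1.78, 80.0)
    rng = np.random.default_rng(seed)
    checks: list[Check] = []

    # 1. closed forms vs Euler-Lagrange oracle
    states = random_states(n_states, rng)
    checks.append(
        Check("inverse dynamics vs Lagrangian oracle (max |dtau|, N m)",
              oracle_discrepancy(states, body, corrupt_h3=corrupt_h3), 1e-7)
    )

    # 2. inertia matrix positive definite across the workspace
    th1 = rng.uniform(-np.pi, np.pi, 1000)
    th2 = rng.uniform(0.05, np.pi - 0.05, 1000)
    H = inertia_matrix(coefficients(th1, th2, body))
    try:
        np.linalg.cholesky(H)
        pd_fail = 0.0
    except np.linalg.LinAlgError:
        pd_fail = 1.0
    checks.append(Check("inertia matrix positive definite (fraction failing)", pd_fail, 0.0))

    # 3. power balance along a smooth trajectory (integrated form)
    series = _smooth_test_series(body)
    tau = inverse_dynamics(series, body).net
    P = np.sum(tau * series.om, axis=1)
    T_kin = kinetic_energy(series, body)
    t = series.grid.t
    work = np.array([0.0] + [simpson(P[: i + 1], x=t[: i + 1]) for i in range(1, t.size)])
    scale = max(np.max(np.abs(T_kin - T_kin[0])), 1e-12)
    checks.append(
        Check("power balance (max |dKE - work| / max |dKE|)",
              float(np.max(np.abs((T_kin - T_kin[0]) - work)) / scale), 1e-6)
    )

    # 4. ID -> FD round trip on the planned reach (accurate rotation)
    cond = Condition(G=1.0)
    res = run_condition(cond)
    rt = float(np.max(np.abs(res.executed.th[:, :2] - res.plan.th[:, :2])))
    checks.append(Check("ID->FD round trip (max |dtheta|, rad)", rt, 1e-6))

    # 5. final hand error at G=1, against the analytic plan's target
    target = np.asarray(cond.reach_end)
    # reach endpoints are shoulder-frame at zero trunk angle; after the
    # rotation the space-fixed target is the same point (target fixed in
    # space): compare executed endpoint with planned endpoint
    from .kinematics import forward_kinematics

    planned_end = forward_kinematics(res.plan.state(-1), cond.body)
    got_end = res.executed_hand.pos[-1]
    checks.append(
        Check("final hand error at G=1 (m)", float(np.linalg.norm(got_end - planned_end)), 1e-5)
    )

    # 6. mirror symmetry: left arm, directions swapped
    c_r = Condition(G=1.5)
    c_l = c_r.mirrored()
    e_r = run_condition(c_r).final_error
    e_l = run_condition(c_l).final_error
    checks.append(Check("left/right mirror symmetry (|de|, m)", abs(e_r - e_l), 1e-6))

    # 7. convergence: halving dt changes the G=1.5 final error by < 0.1 %
    drifts = []
    for direction in (+1, -1):
        e1 = run_condition(Condition(direction=direction, G=1.5, dt=1e-3)).final_error
        e2 = run_condition(Condition(direction=direction, G=1.5, dt=5e-4)).final_error
        drifts.append(abs(e2 - e1) / e1 * 100)
    checks.append(Check("dt convergence of final error (max % drift)", float(max(drifts)), 0.1))

    return checks
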