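"""Planar kinematics of the two-link arm riding on a rotating trunk.

Frames
------
* **space** — inertial frame; origin at the trunk rotation axis (body
  midline), x along the shoulder line at zero trunk angle, y straight ahead.
* **trunk** — rotates with the trunk by the trunk angle ``theta3``.
* **shoulder** — trunk frame translated to the shoulder joint, which sits at
  ``(s, 0)`` in the trunk frame.

Angle conventions follow the task: ``theta1`` (shoulder) and ``theta2``
(elbow) are zero when the upper arm is collinear with the shoulder line and
the elbow fully extended; counter-clockwise is positive. The elbow-flexed
branch for a right arm has ``theta2`` in (0, pi); a left arm (``elbow_sign =
-1``) uses the mirrored branch in (-pi, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anthropometry import BodyModel
from .errors import (
    GridError,
    InvalidParameterError,
    SingularConfigurationError,
    UnreachableError,
)
from .trajectory import PlanarPath, ScalarProfile, TimeGrid

__all__ = [
    "JointState",
    "KinematicSeries",
    "inverse_kinematics",
    "forward_kinematics",
    "plan_joint_series",
    "differentiate_series",
    "hand_path",
]


@dataclass(frozen=True)
class JointState:
    """Angles (rad), angular velocities (rad/s) and accelerations (rad/s^2)
    of shoulder (1), elbow (2) and trunk (3) at one instant."""

    th1: float
    th2: float
    th3: float
    w1: float = 0.0
    w2: float = 0.0
    w3: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.th1, self.th2, self.th3])

    @property
    def velocities(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3])

    @property
    def accelerations(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3])


@dataclass
class KinematicSeries:
    """Joint-space trajectory on a uniform grid.

    Columns of ``th``/``om``/``al`` are (shoulder, elbow, trunk).
    """

    grid: TimeGrid
    th: np.ndarray  # (n, 3) rad
    om: np.ndarray  # (n, 3) rad/s
    al: np.ndarray  # (n, 3) rad/s^2

    def __post_init__(self) -> None:
        for name in ("th", "om", "al"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.grid.n, 3):
                raise InvalidParameterError(
                    f"{name} must have shape ({self.grid.n}, 3), got {arr.shape}"
                )
            setattr(self, name, arr)

    def state(self, i: int) -> JointState:
        return JointState(*self.th[i], *self.om[i], *self.al[i])

    def to_frame(self):
        import pandas as pd

        cols = {"t": self.grid.t}
        for j, name in enumerate(("1", "2", "3")):
            cols[f"theta{name}"] = self.th[:, j]
            cols[f"omega{name}"] = self.om[:, j]
            cols[f"alpha{name}"] = self.al[:, j]
        return pd.DataFrame(cols)


def inverse_kinematics(hand, L1: float, L2: float, elbow_sign: int = +1, *, boundary_tol: float = 1e-12):
    """Joint angles placing the hand at a shoulder-frame point.

    Returns the elbow-flexed solution: ``theta2 = elbow_sign * arccos(...)``
    with the quadrant-correct shoulder angle from the two-argument
    arctangent (the naive ``atan(y/x)`` breaks for x < 0, which is the
    normal operating region of this task).

    Accepts a single (x, y) pair or an (n, 2) array. Raises
    :class:`UnreachableError` outside the open annulus
    ``|L1-L2| < r < L1+L2`` and :class:`SingularConfigurationError` on its
    boundary.
    """
    if elbow_sign not in (+1, -1):
        raise InvalidParameterError("elbow_sign must be +1 (right arm) or -1 (left arm)")
    p = np.asarray(hand, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    x, y = pts[:, 0], pts[:, 1]
    r2 = x * x + y * y
    r = np.sqrt(r2)
    lo, hi = abs(L1 - L2), L1 + L2
    on_boundary = (np.abs(r - hi) <= boundary_tol * hi) | (np.abs(r - lo) <= boundary_tol * hi)
    if np.any(on_boundary):
        i = int(np.argmax(on_boundary))
        raise SingularConfigurationError(
            f"hand at distance {r[i]:.6f} m lies on the workspace boundary "
            f"[{lo:.6f}, {hi:.6f}]"
        )
    outside = (r >= hi) | (r <= lo)
    if np.any(outside):
        i = int(np.argmax(outside))
        raise UnreachableError(
            f"hand at distance {r[i]:.6f} m outside the open workspace "
            f"({lo:.6f}, {hi:.6f})"
        )
    c2 = (r2 - L1 * L1 - L2 * L2) / (2.0 * L1 * L2)
    c2 = np.clip(c2, -1.0, 1.0)
    th2 = elbow_sign * np.arccos(c2)
    th1 = np.arctan2(y, x) - np.arctan2(L2 * np.sin(th2), L1 + L2 * np.cos(th2))
    if single:
        return float(th1[0]), float(th2[0])
    return th1, th2


def forward_kinematics(state, body: BodyModel, th2=None, th3=None):
    """Space-fixed hand position for joint angles.

    Either pass a :class:`JointState` as the first argument, or three
    array-likes ``(th1, th2, th3)``. The hand point is

    ``R(th3) @ [(s, 0) + L1*u(th1) + L2*u(th1+th2)]``

    with ``u`` the planar unit vector; with ``th3 = 0`` and ``s = 0`` this is
    the standard two-link form.
    """
    if isinstance(state, JointState):
        th1, th2, th3 = state.th1, state.th2, state.th3
    else:
        th1 = state
        if th2 is None or th3 is None:
            raise InvalidParameterError("pass a JointState or all three angle series")
    th1 = np.asarray(th1, dtype=float)
    th2 = np.asarray(th2, dtype=float)
    th3 = np.asarray(th3, dtype=float)
    # hand in the trunk frame
    hx = body.s + body.L1 * np.cos(th1) + body.L2 * np.cos(th1 + th2)
    hy = body.L1 * np.sin(th1) + body.L2 * np.sin(th1 + th2)
    c3, s3 = np.cos(th3), np.sin(th3)
    out = np.stack([c3 * hx - s3 * hy, s3 * hx + c3 * hy], axis=-1)
    return out


def differentiate_series(values, dt: float):
    """First and second time derivatives of a uniformly sampled series.

    Second-order central differences in the interior, second-order one-sided
    stencils at the two ends; exact on quadratics (first derivative also on
    cubics in the interior). ``values`` may be (n,) or (n, k).
    """
    v = np.asarray(values, dtype=float)
    if dt <= 0:
        raise GridError(f"dt must be positive, got {dt}")
    if v.shape[0] < 5:
        raise GridError("need at least 5 samples to differentiate")
    d1 = np.gradient(v, dt, axis=0, edge_order=2)
    d2 = np.empty_like(v)
    d2[1:-1] = (v[2:] - 2 * v[1:-1] + v[:-2]) / dt**2
    d2[0] = (2 * v[0] - 5 * v[1] + 4 * v[2] - v[3]) / dt**2
    d2[-1] = (2 * v[-1] - 5 * v[-2] + 4 * v[-3] - v[-4]) / dt**2
    return d1, d2


def plan_joint_series(
    desired_hand: PlanarPath,
    believed_torso: ScalarProfile,
    body: BodyModel,
    *,
    method: str = "analytic",
    elbow_sign: int = +1,
) -> KinematicSeries:
    """Joint-space plan realising a desired hand path under a believed
    trunk rotation.

    A ``"space"``-frame path is first expressed, per sample, in the shoulder
    frame implied by the believed trunk angle (rotate by -theta3, subtract
    the shoulder offset) — the plan then compensates the believed rotation
    kinematically so the hand tracks the space-fixed line. A ``"trunk"``-
    frame path rotates with the trunk, so the shoulder/elbow plan is the
    plain two-link inverse kinematics of the path and is independent of the
    believed rotation, which only fills the trunk row of the series. Either
    way the path's positions are relative to the trunk axis.

    ``method="analytic"`` (default) propagates the hand path's analytic
    velocities/accelerations through the arm Jacobian
    (``om = J^-1 v``, ``al = J^-1 (a - Jdot om)``);
    ``method="numeric"`` differentiates the angle series with the
    second-order stencils of :func:`differentiate_series`.
    """
    desired_hand.grid.require_match(believed_torso.grid)
    grid = desired_hand.grid
    th3 = believed_torso.value
    w3 = believed_torso.d1
    a3 = believed_torso.d2

    px, py = desired_hand.pos[:, 0], desired_hand.pos[:, 1]
    if desired_hand.frame == "space":
        c3, s3 = np.cos(th3), np.sin(th3)
        # rotate the space point by -theta3 into the trunk frame, shift to
        # the shoulder
        x = c3 * px + s3 * py - body.s
        y = -s3 * px + c3 * py
    else:  # trunk frame: rotation does not move the path
        x = px - body.s
        y = py.copy()
    pts = np.stack([x, y], axis=-1)
    rr = np.hypot(x, y)
    lo, hi = abs(body.L1 - body.L2), body.reach
    bad = (rr >= hi) | (rr <= lo)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise UnreachableError(
            f"desired hand point unreachable at t={grid.t[i]:.4f} s "
            f"(distance {rr[i]:.4f} m, workspace ({lo:.4f}, {hi:.4f}))"
        )
    th1, th2 = inverse_kinematics(pts, body.L1, body.L2, elbow_sign=elbow_sign)

    th = np.stack([th1, th2, th3], axis=-1)
    if method == "numeric":
        d1, d2 = differentiate_series(np.stack([th1, th2], axis=-1), grid.dt)
        om = np.stack([d1[:, 0], d1[:, 1], w3], axis=-1)
        al = np.stack([d2[:, 0], d2[:, 1], a3], axis=-1)
    elif method == "analytic":
        vx_s, vy_s = desired_hand.vel[:, 0], desired_hand.vel[:, 1]
        ax_s, ay_s = desired_hand.acc[:, 0], desired_hand.acc[:, 1]
        if desired_hand.frame == "space":
            # q = R(-th3) p ; qdot = R(-th3) v - w3 S q ; S = [[0,-1],[1,0]]
            c3, s3 = np.cos(th3), np.sin(th3)
            qx, qy = x + body.s, y
            rvx = c3 * vx_s + s3 * vy_s
            rvy = -s3 * vx_s + c3 * vy_s
            vx = rvx + w3 * qy
            vy = rvy - w3 * qx
            # qddot = R(-th3) a - 2 w3 S R(-th3) v - a3 S q - w3^2 q
            ax = (c3 * ax_s + s3 * ay_s) + 2 * w3 * rvy + a3 * qy - w3**2 * qx
            ay = (-s3 * ax_s + c3 * ay_s) - 2 * w3 * rvx - a3 * qx - w3**2 * qy
        else:
            vx, vy = vx_s, vy_s
            ax, ay = ax_s, ay_s

        s1, c1 = np.sin(th1), np.cos(th1)
        s12, c12 = np.sin(th1 + th2), np.cos(th1 + th2)
        J00 = -body.L1 * s1 - body.L2 * s12
        J01 = -body.L2 * s12
        J10 = body.L1 * c1 + body.L2 * c12
        J11 = body.L2 * c12
        det = J00 * J11 - J01 * J10
        w1 = (J11 * vx - J01 * vy) / det
        w2 = (-J10 * vx + J00 * vy) / det
        w12 = w1 + w2
        Jd00 = -body.L1 * c1 * w1 - body.L2 * c12 * w12
        Jd01 = -body.L2 * c12 * w12
        Jd10 = -body.L1 * s1 * w1 - body.L2 * s12 * w12
        Jd11 = -body.L2 * s12 * w12
        bx = ax - (Jd00 * w1 + Jd01 * w2)
        by = ay - (Jd10 * w1 + Jd11 * w2)
        al1 = (J11 * bx - J01 * by) / det
        al2 = (-J10 * bx + J00 * by) / det
        om = np.stack([w1, w2, w3], axis=-1)
        al = np.stack([al1, al2, a3], axis=-1)
    else:
        raise InvalidParameterError(f"unknown differentiation method {method!r}")
    return KinematicSeries(grid, th, om, al)


def hand_path(series: KinematicSeries, body: BodyModel) -> PlanarPath:
    """Space-fixed hand path of a joint-space trajectory (forward
    kinematics per sample; path velocity/acceleration by numerical
    differentiation)."""
    pos = forward_kinematics(series.th[:, 0], body, series.th[:, 1], series.th[:, 2])
    vel, acc = differentiate_series(pos, series.grid.dt)
    return PlanarPath(series.grid, pos, vel, acc, "space")
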