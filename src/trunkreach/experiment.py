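"""End-to-end simulation of reaching during misperceived trunk rotation.

One *condition* is a (rotation direction, underestimation gain G) pair on
top of a body model, a reach, and a trunk rotation profile. The pipeline is
purely feedforward:

1. build the accurate trunk profile and the believed one (divided by G);
2. plan shoulder/elbow angles for the straight reach (inverse kinematics per
   sample). By default the reach is drawn in the trunk frame — the planned
   arm motion relative to the trunk is the same with or without rotation,
   and the rotation is handled purely dynamically; ``target_frame="space"``
   instead plans toward a space-fixed target, compensating the believed
   rotation kinematically;
3. compute the feedforward torque commands with the *believed* trunk
   kinematics substituted into the dynamics (the corrupted commands);
4. execute the commands by forward dynamics while the trunk performs the
   *accurate* rotation;
5. map the executed joint motion to the space-fixed hand path and score it
   against the reference execution at G = 1.

Because the reference is itself produced by the full pipeline (not the
analytic plan), integrator bias cancels out of every error metric and what
remains is the effect of the misperception alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .anthropometry import BodyModel, build_body_model
from .dynamics import (
    JOINTS,
    TorqueDecomposition,
    corrupted_commands,
    forward_dynamics,
    inverse_dynamics,
)
from .errors import FrameError, GridError, InvalidParameterError
from .kinematics import KinematicSeries, hand_path, plan_joint_series
from .trajectory import (
    CCW,
    CW,
    PlanarPath,
    UnderestimationSpec,
    min_jerk_path,
    scale_torso,
    torso_profile,
)

__all__ = [
    "Condition",
    "ExperimentResult",
    "run_condition",
    "final_hand_error",
    "rms_torque_change",
    "torque_error",
    "normalized_net_error",
    "sweep",
]

#: printed task geometry: hand start/end in the shoulder frame (m)
REACH_START = (-0.228, 0.25)
REACH_END = (-0.2258, 0.65)
REACH_DURATION = 0.4  # s

#: default trunk rotation (the source figures show the profile but never
#: print its parameters; every profile-dependent number is relative to this
#: documented default)
DEFAULT_TORSO_AMPLITUDE = np.deg2rad(40.0)
DEFAULT_TORSO_DURATION = 0.4  # s


@dataclass(frozen=True)
class Condition:
    """One simulated condition: direction x underestimation gain G.

    ``direction`` is +1 (counter-clockwise) or -1 (clockwise); ``elbow_sign``
    selects the arm (+1 right, -1 left; a left arm expects a body with
    ``s < 0`` and mirrored reach endpoints). ``target_frame`` selects whether
    the straight reach is drawn in the rotating trunk frame (default; the
    planned arm-relative motion is rotation-independent and the rotation is
    handled purely dynamically) or fixed in space (the plan then compensates
    the believed rotation kinematically). ``plan_with_believed`` re-derives
    the joint plan under the believed rotation instead of the accurate one
    (alternative reading of the command-corruption step; only meaningful for
    a space-fixed target, off by default).
    """

    direction: int = CCW
    G: float = 1.0
    torso_amplitude: float = DEFAULT_TORSO_AMPLITUDE  # rad
    torso_duration: float = DEFAULT_TORSO_DURATION  # s
    body: BodyModel = field(default_factory=lambda: build_body_model(1.78, 80.0))
    reach_start: tuple = REACH_START
    reach_end: tuple = REACH_END
    reach_duration: float = REACH_DURATION  # s
    dt: float = 1e-3  # s
    elbow_sign: int = +1
    target_frame: str = "trunk"
    plan_with_believed: bool = False
    torque_interp: str = "cubic"

    def __post_init__(self) -> None:
        if self.direction not in (CCW, CW):
            raise InvalidParameterError("direction must be +1 (CCW) or -1 (CW)")
        if self.G < 1:
            raise InvalidParameterError(f"G must be >= 1, got {self.G}")
        for name in ("torso_duration", "reach_duration", "dt"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.torso_amplitude < 0:
            raise InvalidParameterError("torso_amplitude must be >= 0")
        if self.target_frame not in ("trunk", "space"):
            raise InvalidParameterError("target_frame must be 'trunk' or 'space'")

    @property
    def duration(self) -> float:
        """Total simulated duration (s): the longer of reach and rotation."""
        return max(self.reach_duration, self.torso_duration)

    def mirrored(self) -> "Condition":
        """Left-arm mirror image of this condition: geometry reflected about
        the body midline and the rotation direction reversed."""
        return replace(
            self,
            direction=-self.direction,
            body=self.body.mirrored(),
            reach_start=(-self.reach_start[0], self.reach_start[1]),
            reach_end=(-self.reach_end[0], self.reach_end[1]),
            elbow_sign=-self.elbow_sign,
        )


@dataclass
class ExperimentResult:
    """Everything one condition produces.

    ``torque_errors`` maps component name ('coriolis', 'centripetal',
    'inertial_interaction', 'normal_inertial', 'net', 'component_sum') to a
    length-3 array over joints (shoulder, elbow, trunk) of signed summed
    differences accurate-minus-corrupted (N m); positive means the corrupted
    command was smaller. ``rms_rotation_change`` compares accurate-rotation
    commands with the no-rotation reach (the G-independent cost of rotating);
    ``rms_underestimation_change`` compares corrupted with accurate commands.
    """

    condition: Condition
    underestimation: UnderestimationSpec
    plan: KinematicSeries
    executed: KinematicSeries
    executed_hand: PlanarPath
    reference_hand: PlanarPath
    commands: TorqueDecomposition
    accurate_commands: TorqueDecomposition
    final_error: float  # m
    deviation_angle: float  # rad, signed (+ = CCW of the reference endpoint)
    rms_rotation_change: np.ndarray  # (3,) N m
    rms_underestimation_change: np.ndarray  # (3,) N m
    torque_errors: Mapping[str, np.ndarray]
    normalized_net_error: np.ndarray | None  # (3,) N m per %, None at G=1

    def summary(self) -> dict:
        """Flat scalar summary (one table row)."""
        out = {
            "direction": "ccw" if self.condition.direction == CCW else "cw",
            "G": self.condition.G,
            "percent": self.underestimation.percent,
            "final_error_m": self.final_error,
            "deviation_angle_rad": self.deviation_angle,
        }
        for j, joint in enumerate(JOINTS[:2]):
            out[f"rms_rotation_change_{joint}_Nm"] = float(self.rms_rotation_change[j])
            out[f"rms_underestimation_change_{joint}_Nm"] = float(
                self.rms_underestimation_change[j]
            )
            for comp in ("coriolis", "centripetal", "inertial_interaction", "net"):
                out[f"torque_error_{comp}_{joint}_Nm"] = float(self.torque_errors[comp][j])
            if self.normalized_net_error is not None:
                out[f"normalized_net_error_{joint}_Nm_per_pct"] = float(
                    self.normalized_net_error[j]
                )
        return out


def final_hand_error(executed: PlanarPath, reference: PlanarPath) -> float:
    """Euclidean distance (m) between the two paths' last samples."""
    if executed.frame != reference.frame:
        raise FrameError(
            f"paths in different frames: {executed.frame!r} vs {reference.frame!r}"
        )
    executed.grid.require_match(reference.grid)
    return float(np.linalg.norm(executed.pos[-1] - reference.pos[-1]))


def rms_torque_change(with_rotation, without_rotation) -> np.ndarray:
    """Per-joint RMS over samples of the net-torque difference between two
    torque series (N m)."""
    a = with_rotation.net if isinstance(with_rotation, TorqueDecomposition) else np.asarray(with_rotation)
    b = without_rotation.net if isinstance(without_rotation, TorqueDecomposition) else np.asarray(without_rotation)
    if a.shape != b.shape:
        raise GridError(f"torque series shapes differ: {a.shape} vs {b.shape}")
    return np.sqrt(np.mean((a - b) ** 2, axis=0))


def torque_error(
    accurate: TorqueDecomposition,
    underestimated: TorqueDecomposition,
    *,
    mode: str = "sum",
) -> dict[str, np.ndarray]:
    """Signed summed torque differences accurate - underestimated, per joint.

    For each component (Coriolis, centripetal, inertial interaction, normal
    inertial) and for the net torque, the per-sample difference is summed
    over the trajectory (``mode="sum"``, the stated rule) or integrated with
    the time step as weight (``mode="integral"``). A positive value means
    the torque commanded under misperception was smaller than the accurate
    one. ``component_sum`` adds the Coriolis, centripetal and
    inertial-interaction errors (the normal-inertial error is identically
    zero: that term never involves the trunk kinematics).
    """
    accurate.grid.require_match(underestimated.grid)
    if mode == "sum":
        w = 1.0
    elif mode == "integral":
        w = accurate.grid.dt
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    out: dict[str, np.ndarray] = {}
    for comp in ("normal_inertial", "inertial_interaction", "centripetal", "coriolis", "net"):
        diff = accurate.component(comp) - underestimated.component(comp)
        out[comp] = w * diff.sum(axis=0)
    out["component_sum"] = (
        out["inertial_interaction"] + out["centripetal"] + out["coriolis"]
    )
    return out


def normalized_net_error(net_error, percent: float):
    """Net torque error divided by the underestimation percentage
    (N m per %). Undefined at percent = 0."""
    if percent <= 0:
        raise InvalidParameterError(
            "normalized net error is undefined at 0% underestimation"
        )
    return np.asarray(net_error) / percent


def _pipeline(cond: Condition):
    """Plan, commands and executed trajectory for one condition.

    Reach endpoints are specified in the shoulder frame at movement onset
    (trunk angle zero); they are shifted by the shoulder offset (s, 0) to be
    expressed relative to the trunk axis, in the frame named by
    ``cond.target_frame``.
    """
    shift = np.array([cond.body.s, 0.0])
    hand = min_jerk_path(
        np.asarray(cond.reach_start) + shift,
        np.asarray(cond.reach_end) + shift,
        cond.reach_duration,
        cond.dt,
        total_duration=cond.duration,
        frame=cond.target_frame,
    )
    accurate = torso_profile(
        cond.torso_amplitude, cond.direction, cond.torso_duration, cond.dt,
        total_duration=cond.duration,
    )
    believed, uspec = scale_torso(accurate, cond.G)
    plan_torso = believed if cond.plan_with_believed else accurate
    plan = plan_joint_series(hand, plan_torso, cond.body, elbow_sign=cond.elbow_sign)
    acc_cmds = inverse_dynamics(plan, cond.body)
    cmds = corrupted_commands(plan, believed, cond.body)
    executed = forward_dynamics(
        cmds, accurate, cond.body, plan.state(0), interp=cond.torque_interp
    )
    exec_hand = hand_path(executed, cond.body)
    return hand, accurate, uspec, plan, acc_cmds, cmds, executed, exec_hand


def run_condition(cond: Condition, reference: ExperimentResult | None = None) -> ExperimentResult:
    """Run one condition end to end and score it.

    ``reference`` may carry the already-computed G=1 result for the same
    direction/profile (as :func:`sweep` does); otherwise it is recomputed
    here. The no-rotation reach enters only the RMS-change metric.
    """
    hand, accurate, uspec, plan, acc_cmds, cmds, executed, exec_hand = _pipeline(cond)

    if cond.G == 1.0:
        ref_hand = exec_hand
    elif reference is not None:
        ref_cond = reference.condition
        if (ref_cond.direction, ref_cond.torso_amplitude) != (
            cond.direction,
            cond.torso_amplitude,
        ) or ref_cond.G != 1.0:
            raise InvalidParameterError(
                "reference must be the G=1 result for the same direction and profile"
            )
        ref_hand = reference.executed_hand
    else:
        ref_hand = run_condition(replace(cond, G=1.0)).executed_hand

    # no-rotation reach (same arm, zero trunk profile) for the RMS metric
    zero_torso = torso_profile(0.0, CCW, cond.torso_duration, cond.dt, total_duration=cond.duration)
    plan0 = plan_joint_series(hand, zero_torso, cond.body, elbow_sign=cond.elbow_sign)
    cmds0 = inverse_dynamics(plan0, cond.body)

    err = final_hand_error(exec_hand, ref_hand)
    # signed angle of the executed endpoint relative to the reference
    # endpoint, about the trunk axis (positive = CCW)
    a, b = ref_hand.pos[-1], exec_hand.pos[-1]
    dev = float(np.arctan2(a[0] * b[1] - a[1] * b[0], a @ b))

    terr = torque_error(acc_cmds, cmds)
    result = ExperimentResult(
        condition=cond,
        underestimation=uspec,
        plan=plan,
        executed=executed,
        executed_hand=exec_hand,
        reference_hand=ref_hand,
        commands=cmds,
        accurate_commands=acc_cmds,
        final_error=err,
        deviation_angle=dev,
        rms_rotation_change=rms_torque_change(acc_cmds, cmds0),
        rms_underestimation_change=rms_torque_change(cmds, acc_cmds),
        torque_errors=terr,
        normalized_net_error=(
            normalized_net_error(terr["net"], uspec.percent)
            if uspec.percent > 0
            else None
        ),
    )
    return result


def sweep(
    directions=(CCW, CW),
    G_grid=(1.0, 1.1, 1.2, 1.3, 1.4, 1.5),
    template: Condition | None = None,
) -> tuple[pd.DataFrame, list[ExperimentResult]]:
    """Run every (direction, G) condition and tabulate the metrics.

    The G=1 execution of each direction serves as that direction's
    reference, computed once. Returns the summary table and the full result
    objects in row order.
    """
    template = template or Condition()
    for g in G_grid:
        if not (1.0 <= g <= 1.5 + 1e-12):
            raise InvalidParameterError(f"G grid must lie within [1, 1.5], got {g}")
    rows = []
    results: list[ExperimentResult] = []
    for direction in directions:
        d = direction if direction in (CCW, CW) else {"ccw": CCW, "cw": CW}[str(direction).lower()]
        ref = run_condition(replace(template, direction=d, G=1.0))
        for g in G_grid:
            res = ref if g == 1.0 else run_condition(replace(template, direction=d, G=float(g)), reference=ref)
            results.append(res)
            rows.append(res.summary())
    return pd.DataFrame(rows), results
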