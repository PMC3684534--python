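"""Segment parameters of the trunk + right-arm model from height and mass.

The arm is two rigid links: the upper arm (shoulder to elbow) and the
forearm+hand treated as one link whose distal endpoint is the hand point.
Proportionality constants are Winter's segment-length fractions of body
height and the Dempster-derived mass / centre-of-mass / radius-of-gyration
fractions (Winter, "Biomechanics and Motor Control of Human Movement",
Table 4.1):

====================  =======================  =============================
quantity              fraction                 of
====================  =======================  =============================
upper-arm length L1   0.186                    body height
forearm length        0.146                    body height
hand length           0.108                    body height
L2 (forearm+hand)     0.146 + 0.108 = 0.254    body height
upper-arm mass m1     0.028                    body mass
forearm+hand mass m2  0.022                    body mass
r1 (COM from shldr)   0.436                    upper-arm length
rog1 (about COM)      0.322                    upper-arm length
r2 (COM from elbow)   0.682                    forearm length (0.146 h)
rog2 (about COM)      0.468                    forearm length (0.146 h)
trunk mass            0.497                    body mass
====================  =======================  =============================

The trunk is approximated as a uniform cylinder of radius 0.085 * height
rotating about its own vertical axis: I_trunk = m_trunk * radius^2 / 2. The
trunk inertia only enters the trunk torque, not the arm dynamics, so this
coarse approximation is harmless; it is configurable through overrides.

The shoulder rides on the trunk at a lateral offset ``s`` from the rotation
axis (body midline). The default s = 0.2258 m is read off the task geometry:
the straight-ahead target sits at x = -0.2258 m in the shoulder frame, so
the midline axis is offset by that amount along the shoulder line. ``s`` is
configurable; a left arm is modelled with s < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import InvalidParameterError, InvariantError

__all__ = ["BodyModel", "build_body_model", "WINTER_FRACTIONS"]

#: Winter/Dempster proportionality constants used by :func:`build_body_model`.
WINTER_FRACTIONS = {
    "upper_arm_length": 0.186,  # of height
    "forearm_length": 0.146,  # of height
    "hand_length": 0.108,  # of height
    "upper_arm_mass": 0.028,  # of mass
    "forearm_hand_mass": 0.022,  # of mass
    "upper_arm_com": 0.436,  # of upper-arm length, from shoulder
    "upper_arm_rog": 0.322,  # of upper-arm length, about COM
    "forearm_hand_com": 0.682,  # of forearm length, from elbow
    "forearm_hand_rog": 0.468,  # of forearm length, about COM
    "trunk_mass": 0.497,  # of mass
    "trunk_radius": 0.085,  # of height (cylinder approximation)
}

#: default lateral shoulder offset from the trunk rotation axis (m)
DEFAULT_SHOULDER_OFFSET = 0.2258


@dataclass(frozen=True)
class BodyModel:
    """Planar rigid-body parameters of the trunk + two-link arm.

    Lengths in m, masses in kg, inertias in kg*m^2 about the vertical axis
    through the segment's centre of mass. ``s`` is the signed shoulder offset
    along the shoulder line from the trunk rotation axis (positive for the
    right shoulder; a left arm is modelled by s < 0).
    """

    height: float
    mass: float
    L1: float
    L2: float
    m1: float
    m2: float
    r1: float
    r2: float
    I1: float
    I2: float
    I_trunk: float
    s: float = DEFAULT_SHOULDER_OFFSET

    def __post_init__(self) -> None:
        positive = (
            "height",
            "mass",
            "L1",
            "L2",
            "m1",
            "m2",
            "r1",
            "r2",
            "I1",
            "I2",
            "I_trunk",
        )
        for name in positive:
            v = getattr(self, name)
            if not (v > 0):
                raise InvariantError(f"{name} must be strictly positive, got {v}")
        if self.r1 > self.L1:
            raise InvariantError(f"r1={self.r1} exceeds L1={self.L1}")
        if self.r2 > self.L2:
            raise InvariantError(f"r2={self.r2} exceeds L2={self.L2}")

    @property
    def reach(self) -> float:
        """Maximum shoulder-to-hand distance L1 + L2 (m)."""
        return self.L1 + self.L2

    def check_reach(self, points) -> None:
        """Raise InvariantError if any shoulder-frame point is beyond L1+L2."""
        import numpy as np

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dist = np.hypot(pts[:, 0], pts[:, 1])
        worst = float(dist.max())
        if worst >= self.reach:
            raise InvariantError(
                f"hand position at distance {worst:.4f} m exceeds reach "
                f"L1+L2={self.reach:.4f} m"
            )

    def mirrored(self) -> "BodyModel":
        """Same body with the shoulder on the other side of the midline
        (left-arm geometry)."""
        return replace(self, s=-self.s)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def build_body_model(height: float, mass: float, overrides: dict | None = None) -> BodyModel:
    """Build a :class:`BodyModel` from total body height (m) and mass (kg).

    Every derived field can be replaced through ``overrides`` (keys are
    BodyModel field names); the resulting model is re-validated, so an
    override that breaks an invariant (e.g. a zero mass) raises
    :class:`~trunkreach.errors.InvariantError`.
    """
    if not (height > 0):
        raise InvalidParameterError(f"height must be positive, got {height}")
    if not (mass > 0):
        raise InvalidParameterError(f"mass must be positive, got {mass}")

    f = WINTER_FRACTIONS
    L1 = f["upper_arm_length"] * height
    forearm = f["forearm_length"] * height
    L2 = (f["forearm_length"] + f["hand_length"]) * height
    m1 = f["upper_arm_mass"] * mass
    m2 = f["forearm_hand_mass"] * mass
    r1 = f["upper_arm_com"] * L1
    r2 = f["forearm_hand_com"] * forearm
    I1 = m1 * (f["upper_arm_rog"] * L1) ** 2
    I2 = m2 * (f["forearm_hand_rog"] * forearm) ** 2
    m_trunk = f["trunk_mass"] * mass
    I_trunk = 0.5 * m_trunk * (f["trunk_radius"] * height) ** 2

    params = dict(
        height=height,
        mass=mass,
        L1=L1,
        L2=L2,
        m1=m1,
        m2=m2,
        r1=r1,
        r2=r2,
        I1=I1,
        I2=I2,
        I_trunk=I_trunk,
        s=DEFAULT_SHOULDER_OFFSET,
    )
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise InvalidParameterError(f"unknown BodyModel overrides: {sorted(unknown)}")
        params.update(overrides)
    return BodyModel(**params)
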