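"""Minimum-jerk planning for the hand and the trunk.

The hand follows a fifth-order (minimum-jerk) polynomial between two planar
points; the trunk rotation reuses the same quintic with angular endpoints.
Underestimated trunk kinematics are produced by dividing the accurate
time-series by a gain G >= 1, and the size of the misperception is quoted as
a percentage of the peak trunk angular acceleration.

All profiles carry analytic first and second derivatives (polynomial
differentiation); the numerical differentiator lives in
:mod:`trunkreach.kinematics` and is reserved for joint-angle series that have
no closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .errors import GridError, InvalidParameterError

__all__ = [
    "TimeGrid",
    "ScalarProfile",
    "PlanarPath",
    "UnderestimationSpec",
    "min_jerk_path",
    "torso_profile",
    "scale_torso",
    "CCW",
    "CW",
]

#: direction constants — counter-clockwise rotation about the vertical axis is
#: positive by convention, clockwise negative.
CCW: int = +1
CW: int = -1


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid from 0 to T with step dt.

    dt must divide T to within a relative tolerance of 1e-9, so the final
    sample lands exactly on T.
    """

    T: float
    dt: float
    t: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise InvalidParameterError(f"duration T must be positive, got {self.T}")
        if self.dt <= 0:
            raise InvalidParameterError(f"step dt must be positive, got {self.dt}")
        n = self.T / self.dt
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise GridError(f"dt={self.dt} does not divide T={self.T}")
        object.__setattr__(self, "t", np.linspace(0.0, self.T, int(round(n)) + 1))

    @property
    def n(self) -> int:
        """Number of samples (len(t))."""
        return self.t.size

    def matches(self, other: "TimeGrid", tol: float = 1e-12) -> bool:
        return self.t.size == other.t.size and abs(self.T - other.T) <= tol

    def require_match(self, other: "TimeGrid") -> None:
        if not self.matches(other):
            raise GridError(
                f"incompatible grids: (T={self.T}, n={self.n}) vs (T={other.T}, n={other.n})"
            )


def _quintic_s(tt: np.ndarray, T: float):
    """Minimum-jerk basis s(t) and its two time derivatives, clamped outside
    [0, T] (profile holds its final value after T)."""
    tt = np.asarray(tt, dtype=float)
    u = np.clip(tt / T, 0.0, 1.0)
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    ds = (30 * u**2 - 60 * u**3 + 30 * u**4) / T
    dds = (60 * u - 180 * u**2 + 120 * u**3) / T**2
    inside = (tt >= 0.0) & (tt <= T)
    ds = np.where(inside, ds, 0.0)
    dds = np.where(inside, dds, 0.0)
    return s, ds, dds


@dataclass
class ScalarProfile:
    """Sampled scalar trajectory with consistent first/second derivatives.

    ``fun`` (optional) evaluates (value, d1, d2) at arbitrary times; planners
    attach the closed form so integrators can sample between grid points
    without interpolation error.
    """

    grid: TimeGrid
    value: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    fun: Callable[[np.ndarray], tuple] | None = None

    def __call__(self, tt):
        if self.fun is not None:
            return self.fun(tt)
        # spline fallback for profiles without a closed form
        from scipy.interpolate import CubicSpline

        cs = CubicSpline(self.grid.t, self.value)
        tt = np.asarray(tt, dtype=float)
        return cs(tt), cs(tt, 1), cs(tt, 2)

    def to_frame(self):
        """CSV-ready view (columns t, value, d1, d2)."""
        import pandas as pd

        return pd.DataFrame(
            {"t": self.grid.t, "value": self.value, "d1": self.d1, "d2": self.d2}
        )


Frame = Literal["space", "trunk"]


@dataclass
class PlanarPath:
    """Planar trajectory (positions, velocities, accelerations) with an
    explicit frame tag: ``"space"`` (inertial, trunk-axis origin) or
    ``"trunk"`` (rotating, shoulder-centred)."""

    grid: TimeGrid
    pos: np.ndarray  # (n, 2) m
    vel: np.ndarray  # (n, 2) m/s
    acc: np.ndarray  # (n, 2) m/s^2
    frame: Frame
    fun: Callable[[np.ndarray], tuple] | None = None

    def __post_init__(self) -> None:
        for name in ("pos", "vel", "acc"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.grid.n, 2):
                raise InvalidParameterError(
                    f"{name} must have shape ({self.grid.n}, 2), got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise InvalidParameterError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if self.frame not in ("space", "trunk"):
            raise InvalidParameterError(f"unknown frame tag {self.frame!r}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.grid.t,
                "x": self.pos[:, 0],
                "y": self.pos[:, 1],
                "vx": self.vel[:, 0],
                "vy": self.vel[:, 1],
                "ax": self.acc[:, 0],
                "ay": self.acc[:, 1],
            }
        )


@dataclass(frozen=True)
class UnderestimationSpec:
    """Gain G >= 1 dividing the trunk kinematics, and the resulting
    underestimation percentage 100*(1 - peak_scaled_acc/peak_acc)."""

    G: float
    percent: float


def min_jerk_path(
    p0,
    pf,
    T: float,
    dt: float,
    total_duration: float | None = None,
    frame: Frame = "space",
) -> PlanarPath:
    """Minimum-jerk straight-line reach from p0 to pf over duration T.

    Velocity and acceleration are the analytic quintic derivatives; both are
    zero at t=0 and t=T. ``frame`` tags whether the line is fixed in space
    or drawn in the rotating trunk frame. If ``total_duration > T`` the grid
    extends beyond the movement and the path holds the final position (zero
    derivatives) afterwards.
    """
    p0 = np.asarray(p0, dtype=float)
    pf = np.asarray(pf, dtype=float)
    if p0.shape != (2,) or pf.shape != (2,):
        raise InvalidParameterError("p0 and pf must be planar points (x, y)")
    if total_duration is not None and total_duration < T:
        raise InvalidParameterError("total_duration must be >= movement duration T")
    grid = TimeGrid(total_duration if total_duration is not None else T, dt)
    if T <= 0:
        raise InvalidParameterError(f"movement duration T must be positive, got {T}")
    d = pf - p0

    def fun(tt):
        s, ds, dds = _quintic_s(tt, T)
        return (
            p0 + np.multiply.outer(s, d),
            np.multiply.outer(ds, d),
            np.multiply.outer(dds, d),
        )

    pos, vel, acc = fun(grid.t)
    return PlanarPath(grid, pos, vel, acc, frame, fun=fun)


def torso_profile(
    amplitude: float, direction: int, T: float, dt: float, total_duration: float | None = None
) -> ScalarProfile:
    """Minimum-jerk trunk rotation from 0 to direction*amplitude (rad).

    direction is +1 (counter-clockwise, positive by convention) or -1
    (clockwise). amplitude = 0 is the explicit no-rotation case. If
    ``total_duration > T`` the profile holds the final angle afterwards.
    """
    if amplitude < 0:
        raise InvalidParameterError(f"amplitude must be >= 0, got {amplitude}")
    if direction not in (CCW, CW):
        raise InvalidParameterError(f"direction must be +1 (CCW) or -1 (CW), got {direction}")
    if total_duration is not None and total_duration < T:
        raise InvalidParameterError("total_duration must be >= rotation duration T")
    if T <= 0:
        raise InvalidParameterError(f"rotation duration T must be positive, got {T}")
    grid = TimeGrid(total_duration if total_duration is not None else T, dt)
    a = direction * amplitude

    def fun(tt):
        s, ds, dds = _quintic_s(tt, T)
        return a * s, a * ds, a * dds

    v, d1, d2 = fun(grid.t)
    return ScalarProfile(grid, v, d1, d2, fun=fun)


def scale_torso(profile: ScalarProfile, G: float) -> tuple[ScalarProfile, UnderestimationSpec]:
    """Divide the trunk kinematic time-series by G (underestimation).

    The quoted percentage follows the peak-acceleration rule
    percent = 100 - 100 * max|scaled d2| / max|d2|, which for a pure 1/G
    scaling reduces to 100*(1 - 1/G) independent of amplitude and duration.
    """
    if G < 1:
        raise InvalidParameterError(
            f"G must be >= 1 (overestimation is out of scope), got {G}"
        )
    inv = 1.0 / G
    base_fun = profile.fun

    def fun(tt):
        if base_fun is None:
            raise RuntimeError("profile has no closed form")
        v, d1, d2 = base_fun(tt)
        return inv * v, inv * d1, inv * d2

    scaled = ScalarProfile(
        profile.grid,
        inv * profile.value,
        inv * profile.d1,
        inv * profile.d2,
        fun=fun if base_fun is not None else None,
    )
    peak = float(np.max(np.abs(profile.d2)))
    if peak == 0.0:
        percent = 0.0
    else:
        percent = 100.0 - 100.0 * float(np.max(np.abs(scaled.d2))) / peak
    return scaled, UnderestimationSpec(G=G, percent=percent)
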