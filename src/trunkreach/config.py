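"""Run configuration: a versioned, strictly-validated YAML schema.

Every headline number of the simulation depends on the trunk-rotation
profile, which is a documented default rather than a printed value — so the
configuration is echoed (with a content hash) into every manifest the CLI
writes, making each results file self-describing.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .anthropometry import BodyModel, build_body_model
from .errors import InvalidParameterError
from .experiment import (
    DEFAULT_TORSO_DURATION,
    REACH_DURATION,
    REACH_END,
    REACH_START,
    Condition,
)
from .trajectory import CCW, CW

__all__ = ["RunConfig", "load_config"]


class BodyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    height: float = Field(1.78, gt=0, description="body height (m)")
    mass: float = Field(80.0, gt=0, description="body mass (kg)")
    shoulder_offset: float = 0.2258  # m, from the trunk rotation axis
    overrides: dict[str, float] = Field(default_factory=dict)

    def build(self) -> BodyModel:
        ov = dict(self.overrides)
        ov.setdefault("s", self.shoulder_offset)
        return build_body_model(self.height, self.mass, ov)


class ReachConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: tuple[float, float] = REACH_START  # m, shoulder frame
    end: tuple[float, float] = REACH_END  # m, shoulder frame
    duration: float = Field(REACH_DURATION, gt=0)  # s


class TorsoConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    amplitude_deg: float = Field(40.0, ge=0, description="rotation amplitude (deg)")
    duration: float = Field(DEFAULT_TORSO_DURATION, gt=0)  # s
    directions: list[Literal["ccw", "cw"]] = ["ccw", "cw"]


class RunConfig(BaseModel):
    """Top-level configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    body: BodyConfig = Field(default_factory=BodyConfig)
    reach: ReachConfig = Field(default_factory=ReachConfig)
    torso: TorsoConfig = Field(default_factory=TorsoConfig)
    G: list[float] = [1.0, 1.1, 1.2, 1.3, 1.4, 1.5]
    dt: float = Field(1e-3, gt=0)  # s
    seed: int = 0  # reserved: the pipeline is deterministic
    plan_with_believed: bool = False
    torque_interp: Literal["cubic", "linear"] = "cubic"
    sum_mode: Literal["sum", "integral"] = "sum"
    report_lengths: Literal["m", "cm"] = "cm"  # hand errors at the CLI boundary

    @field_validator("G")
    @classmethod
    def _g_at_least_one(cls, v: list[float]) -> list[float]:
        for g in v:
            if g < 1:
                raise ValueError(
                    f"G must be >= 1 (underestimation only; got {g})"
                )
        return v

    def conditions(self) -> list[Condition]:
        import numpy as np

        body = self.body.build()
        out = []
        for dname in self.torso.directions:
            d = CCW if dname == "ccw" else CW
            for g in self.G:
                out.append(
                    Condition(
                        direction=d,
                        G=float(g),
                        torso_amplitude=float(np.deg2rad(self.torso.amplitude_deg)),
                        torso_duration=self.torso.duration,
                        body=body,
                        reach_start=tuple(self.reach.start),
                        reach_end=tuple(self.reach.end),
                        reach_duration=self.reach.duration,
                        dt=self.dt,
                        plan_with_believed=self.plan_with_believed,
                        torque_interp=self.torque_interp,
                    )
                )
        return out

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML config file; any violation raises
    InvalidParameterError with the offending field."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # pydantic ValidationError carries field paths
        raise InvalidParameterError(f"invalid config {path}: {exc}") from exc
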