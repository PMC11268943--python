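"""PID pressure controller commanding normalized blower speed.

Parallel form with derivative on measurement (no setpoint kick), output
clamped to the normalized speed range and the integrator clamped to the
anti-windup bounds.  The published device gives no gains, loop rate or
anti-windup scheme; the defaults here were tuned once against the default
plant (see tests for the disturbance-rejection and settling checks that
froze them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class PIDConfig:
    kp: float = 0.05  # speed fraction per cmH2O
    ki: float = 0.4  # per s
    kd: float = 0.0  # s
    output_limits: tuple[float, float] = (0.0, 1.0)
    anti_windup: tuple[float, float] = (0.0, 1.0)  # integrator clamp
    sample_rate: float = 100.0  # Hz

    def __post_init__(self) -> None:
        if min(self.kp, self.ki, self.kd) < 0:
            raise ValueError("gains must be >= 0")
        if self.output_limits[0] >= self.output_limits[1]:
            raise ValueError("output_limits: must be ordered")
        if self.anti_windup[0] >= self.anti_windup[1]:
            raise ValueError("anti_windup: must be ordered")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate: must be > 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclass
class PIDState:
    integrator: float = 0.0
    last_measurement: float = float("nan")
    last_output: float = 0.0


def pid_step(
    setpoint: float, measured_p_awo: float, state: PIDState, cfg: PIDConfig
) -> tuple[float, PIDState]:
    """One controller update; returns (speed command, new state)."""
    if not (math.isfinite(setpoint) and math.isfinite(measured_p_awo)):
        raise ValueError("setpoint and measurement must be finite")
    dt = cfg.dt
    error = setpoint - measured_p_awo

    integrator = state.integrator + cfg.ki * error * dt
    integrator = min(max(integrator, cfg.anti_windup[0]), cfg.anti_windup[1])

    if math.isnan(state.last_measurement):
        derivative = 0.0
    else:
        derivative = -cfg.kd * (measured_p_awo - state.last_measurement) / dt

    raw = cfg.kp * error + integrator + derivative
    out = min(max(raw, cfg.output_limits[0]), cfg.output_limits[1])
    if raw != out:
        # conditional anti-windup: do not keep integrating into saturation
        if (raw > out and error > 0) or (raw < out and error < 0):
            integrator = state.integrator

    return out, PIDState(integrator=integrator, last_measurement=measured_p_awo, last_output=out)
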