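"""Controller-side estimation of airway-opening pressure and flow.

Only blower-side sensors exist: the airway pressure is the blower pressure
minus the (constant-resistance) tube drop, and the airway flow is the
blower flow minus the modelled intentional-leak flow evaluated at the
blower pressure.  The estimate deliberately excludes the concentrator
inflow, which is injected downstream of the leak.  A windowed mean of the
positive (inspiratory) part of the estimated flow provides the single
ventilator-flow figure the FiO2 allocator consumes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .plant import LeakModel, leak_flow


@dataclass(frozen=True)
class SensorReadings:
    """Blower-outlet pressure (cmH2O) and pneumotachograph flow (L/min)."""

    p_blower: float
    flow_blower: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.p_blower) and np.isfinite(self.flow_blower)):
            raise ValueError("sensor readings must be finite")


@dataclass(frozen=True)
class EstimatorConfig:
    r_tube: float = 1.0  # cmH2O*s/L, treated as constant
    leak: LeakModel = field(default_factory=LeakModel)
    averaging_window: float = 10.0  # s

    def __post_init__(self) -> None:
        if self.r_tube <= 0:
            raise ValueError("r_tube: must be > 0")
        if self.averaging_window <= 0:
            raise ValueError("averaging_window: must be > 0")


@dataclass(frozen=True)
class AirwayEstimate:
    p_awo: float  # cmH2O
    flow_awo: float  # L/min, instantaneous
    mean_insp_flow_awo: float = 0.0  # L/min, windowed mean of positive part


def estimate_airway(readings: SensorReadings, cfg: EstimatorConfig) -> AirwayEstimate:
    """Airway pressure/flow from blower-side readings.

    p_awo = p_blower - r_tube * flow (flow in L/s for the product);
    flow_awo = flow_blower - leak(p_blower).  The leak is evaluated at the
    blower pressure, as the controller has no downstream sensor; the small
    tube-drop mismatch is an inherent error of the method.
    """
    p_awo = readings.p_blower - cfg.r_tube * readings.flow_blower / 60.0
    leak = leak_flow(max(readings.p_blower, 0.0), cfg.leak)
    return AirwayEstimate(p_awo=p_awo, flow_awo=readings.flow_blower - leak)


def update_mean_insp_flow(history, dt: float, cfg: EstimatorConfig) -> float:
    """Mean of the positive part of ``history`` over the averaging window.

    ``history`` is a flow series sampled at ``dt``; the last
    ``averaging_window / dt`` samples are used and must span the window.
    """
    flows = np.asarray(history, dtype=float)
    if flows.size == 0:
        raise ValueError("history: empty")
    n = int(round(cfg.averaging_window / dt))
    if flows.size < n:
        raise ValueError("history: spans less than the averaging window")
    window = flows[-n:]
    return float(np.mean(np.clip(window, 0.0, None)))


class InspiratoryFlowAverager:
    """Streaming counterpart of :func:`update_mean_insp_flow` (O(1)/step).

    Before the buffer fills, the mean is taken over the samples seen so far
    (the loop starts the allocator only once this is marked ``ready``).
    """

    def __init__(self, window: float, dt: float):
        if window <= 0 or dt <= 0:
            raise ValueError("window and dt must be > 0")
        self._n = max(int(round(window / dt)), 1)
        self._buf: deque[float] = deque()
        self._sum = 0.0

    @property
    def ready(self) -> bool:
        return len(self._buf) >= self._n

    def update(self, flow_awo: float) -> float:
        pos = max(flow_awo, 0.0)
        self._buf.append(pos)
        self._sum += pos
        if len(self._buf) > self._n:
            self._sum -= self._buf.popleft()
        return self._sum / len(self._buf)
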