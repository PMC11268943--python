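"""Closed-loop system: pressure control plus FiO2 control allocation.

Wires the plant simulator to the airway estimator, the PID blower
controller (100 Hz), and the concentrator allocator (1 Hz, via the
precompiled lookup table).  The concentrator's commanded output passes
through the reservoir low-pass before entering the circuit, and its
injection acts as a pressure disturbance the PID must reject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import allocation as alloc
from .concentrator import AMBIENT_O2, ReservoirFilter, TruthSurfaces
from .control import PIDConfig, PIDState, pid_step
from .estimator import EstimatorConfig, InspiratoryFlowAverager, SensorReadings, estimate_airway
from .plant import BreathPattern, CircuitSimulator, PlantConfig


@dataclass
class LoopConfig:
    """Controller-side configuration of the closed loop."""

    pid: PIDConfig = field(default_factory=PIDConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    allocation: alloc.AllocationConfig = field(default_factory=alloc.AllocationConfig)
    allocator_period: float = 1.0  # s between allocation updates
    reservoir_tau: float = 3.4  # s (170 ml reservoir at ~3 L/min)
    averager_min_fill: float = 2.0  # s of data before the allocator starts


@dataclass
class RunLog:
    """Uniformly sampled telemetry of one closed-loop run."""

    time_s: np.ndarray
    p_blower_cmH2O: np.ndarray
    flow_blower_Lmin: np.ndarray
    p_awo_true_cmH2O: np.ndarray
    patient_flow_Lmin: np.ndarray
    leak_flow_Lmin: np.ndarray
    delivered_fio2: np.ndarray
    sensor_fio2: np.ndarray
    mix_fio2: np.ndarray
    p_awo_est_cmH2O: np.ndarray
    flow_awo_est_Lmin: np.ndarray
    mean_insp_flow_Lmin: np.ndarray
    cs_pct: np.ndarray
    sv_pct: np.ndarray
    conc_flow_Lmin: np.ndarray
    compressor_power_W: np.ndarray
    total_power_W: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({k: getattr(self, k) for k in self.__dataclass_fields__})


class ClosedLoopSystem:
    """One CPAP + concentrator system under closed-loop control."""

    def __init__(
        self,
        cpap_setpoint: float,
        fio2_target: float = AMBIENT_O2,
        pattern: BreathPattern | None = None,
        plant_config: PlantConfig | None = None,
        loop_config: LoopConfig | None = None,
        surfaces: TruthSurfaces | None = None,
        lookup: alloc.LookupTable | None = None,
        coeffs: tuple | None = None,
        seed: int | None = None,
        conc_override: Callable[[float], tuple[float, float]] | None = None,
    ):
        self.cpap_setpoint = float(cpap_setpoint)
        self.fio2_target = float(fio2_target)
        self.pattern = pattern
        self.plant_config = plant_config or PlantConfig()
        self.loop_config = loop_config or LoopConfig()
        self.surfaces = surfaces or TruthSurfaces()
        self.lookup = lookup
        self.coeffs = coeffs  # (coeffs_cs, coeffs_sv) for direct allocation
        self.conc_override = conc_override

        self.sim = CircuitSimulator(self.plant_config, seed=seed)
        self.pid_state = PIDState()
        dt = self.plant_config.dt
        self._averager = InspiratoryFlowAverager(self.loop_config.estimator.averaging_window, dt)
        self._min_fill_steps = max(int(round(self.loop_config.averager_min_fill / dt)), 1)
        self._steps_seen = 0
        self._flow_filter = ReservoirFilter(self.loop_config.reservoir_tau, dt)
        self._o2_filter = ReservoirFilter(self.loop_config.reservoir_tau, dt, initial=AMBIENT_O2)
        self._control_every = max(int(round(1.0 / self.loop_config.pid.sample_rate / dt)), 1)
        self._alloc_every = max(int(round(self.loop_config.allocator_period / dt)), 1)
        self._speed_cmd = 0.0
        self._cmd = alloc.OFF_COMMAND
        self._out_c = self.surfaces.output(self._cmd)
        self._mean_insp = 0.0
        self._k = 0

    # -- effort waveform (analytic, matches generate_breath_tracing) -------

    def _effort(self, t: float) -> float:
        pat = self.pattern
        if pat is None or pat.tidal_volume == 0.0:
            return 0.0
        period = 60.0 / pat.respiratory_rate
        ti = pat.inspiratory_fraction * period
        te = period - ti
        phase = math.fmod(t, period)
        if phase < ti:
            return 60.0 * math.pi * pat.tidal_volume / (2.0 * ti) * math.sin(math.pi * phase / ti)
        tau_e = te / 5.0
        b = pat.tidal_volume / (tau_e * (1.0 - math.exp(-te / tau_e)))
        return -60.0 * b * math.exp(-(phase - ti) / tau_e)

    # -- allocation --------------------------------------------------------

    def _allocate(self, v_awo: float) -> alloc.AllocationResult:
        if self.fio2_target <= AMBIENT_O2 + 1e-9:
            return alloc.AllocationResult(alloc.OFF_COMMAND, 0.0, True, AMBIENT_O2, 0.0)
        if self.lookup is not None:
            res = alloc.query_lookup(self.lookup, self.fio2_target, v_awo)
            if not res.feasible and self.coeffs is not None:
                # at the table's feasibility boundary (mixed cell) or beyond
                # it: fall back to the direct, saturating allocation
                res = alloc.allocate(
                    self.fio2_target, v_awo, *self.coeffs, self.loop_config.allocation
                )
            return res
        if self.coeffs is not None:
            return alloc.allocate(self.fio2_target, v_awo, *self.coeffs, self.loop_config.allocation)
        return alloc.AllocationResult(alloc.OFF_COMMAND, 0.0, True, AMBIENT_O2, 0.0)

    # -- main loop ---------------------------------------------------------

    def run(self, duration: float, record: bool = True, log_decimation: int = 1) -> RunLog | None:
        cfg = self.plant_config
        dt = cfg.dt
        n = int(round(duration / dt))
        est_cfg = self.loop_config.estimator
        out = {k: [] for k in RunLog.__dataclass_fields__} if record else None

        comp_power = 0.0
        total_power = 0.0
        for i in range(n):
            t = self._k * dt
            effort = self._effort(t)

            # concentrator output (smoothed by the reservoir)
            if self.conc_override is not None:
                raw_flow, raw_o2 = self.conc_override(t)
                comp_power = 0.0
                total_power = 0.0
            else:
                if (
                    self._k % self._alloc_every == 0
                    and self._steps_seen >= self._min_fill_steps
                ):
                    res = self._allocate(self._mean_insp)
                    if res.command != self._cmd:
                        self._cmd = res.command
                        self._out_c = self.surfaces.output(self._cmd)
                out_c = self._out_c
                raw_flow, raw_o2 = out_c.flow, out_c.o2
                comp_power = out_c.compressor_power
                total_power = out_c.total_power
            conc_flow = self._flow_filter.update(raw_flow)
            conc_o2 = self._o2_filter.update(raw_o2) if raw_flow > 0 else raw_o2

            st = self.sim.step(self._speed_cmd, conc_flow, conc_o2, effort)

            est = estimate_airway(SensorReadings(st.p_blower, st.flow_blower), est_cfg)
            self._mean_insp = self._averager.update(est.flow_awo)
            self._steps_seen += 1

            if self._k % self._control_every == 0:
                self._speed_cmd, self.pid_state = pid_step(
                    self.cpap_setpoint, est.p_awo, self.pid_state, self.loop_config.pid
                )
            self._k += 1

            if record and i % log_decimation == 0:
                out["time_s"].append(t)
                out["p_blower_cmH2O"].append(st.p_blower)
                out["flow_blower_Lmin"].append(st.flow_blower)
                out["p_awo_true_cmH2O"].append(st.p_awo_true)
                out["patient_flow_Lmin"].append(st.patient_flow)
                out["leak_flow_Lmin"].append(st.leak_flow)
                out["delivered_fio2"].append(st.delivered_fio2)
                out["sensor_fio2"].append(st.o2_sensor_reading)
                out["mix_fio2"].append(st.mix_fio2)
                out["p_awo_est_cmH2O"].append(est.p_awo)
                out["flow_awo_est_Lmin"].append(est.flow_awo)
                out["mean_insp_flow_Lmin"].append(self._mean_insp)
                out["cs_pct"].append(self._cmd.cs)
                out["sv_pct"].append(self._cmd.sv)
                out["conc_flow_Lmin"].append(conc_flow)
                out["compressor_power_W"].append(comp_power)
                out["total_power_W"].append(total_power)

        if record:
            return RunLog(**{k: np.asarray(v) for k, v in out.items()})
        return None


def closed_loop_settle(
    setpoint: float,
    plant_config: PlantConfig | None = None,
    loop_config: LoopConfig | None = None,
    duration: float = 30.0,
    pattern: BreathPattern | None = None,
    conc_override: Callable[[float], tuple[float, float]] | None = None,
) -> dict:
    """Run the pressure loop to steady state and report regulation quality.

    Reports mean and peak-to-peak true airway pressure over the last 10 s
    and the mean blower (bias) flow; a ripple above 2 cmH2O flags
    non-convergence rather than raising.
    """
    if duration < 30.0:
        raise ValueError("duration: must be >= 30 s simulated")
    sys_ = ClosedLoopSystem(
        setpoint,
        pattern=pattern,
        plant_config=plant_config,
        loop_config=loop_config,
        conc_override=conc_override,
    )
    log = sys_.run(duration)
    tail = log.time_s >= duration - 10.0
    p = log.p_awo_true_cmH2O[tail]
    ripple = float(p.max() - p.min())
    return {
        "setpoint_cmH2O": setpoint,
        "mean_p_awo_cmH2O": float(p.mean()),
        "ripple_p_awo_cmH2O": ripple,
        "mean_blower_flow_Lmin": float(log.flow_blower_Lmin[tail].mean()),
        "converged": ripple <= 2.0,
    }
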