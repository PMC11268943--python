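"""Physical simulation of the blower CPAP circuit and an active test lung.

Topology: radial blower -> single-limb tube (constant resistance) ->
connector carrying the intentional leak and the oxygen-injection inlet ->
patient interface -> single-compartment test lung driven in parallel by a
breath-simulator flow source.

Units: pressure cmH2O, flow L/min (converted to L/s only inside products
with resistances), volume L, time s, oxygen as fraction.

The oxygen path models a small well-mixed volume between the injection
point and the mouth (connector + interface dead space): concentrator gas
enters continuously, inspiration draws the mixture, expiration returns test
lung gas (which, in vitro, has the composition it inhaled -- there is no
gas exchange).  Enriched gas pushed back past the connector during
expiration is lost through the leak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

AMBIENT_O2 = 0.21

#: Mass-balance closure required of the circuit solver, L/min.
NODE_BALANCE_TOL = 1e-6


class InvalidCircuitState(ValueError):
    """Raised for physically invalid circuit inputs (e.g. negative leak
    pressure) or solver divergence."""


@dataclass
class LungModel:
    """Single-compartment test lung (resistance-compliance analogue)."""

    resistance: float = 60.0  # cmH2O*s/L
    compliance: float = 0.0015  # L/cmH2O
    volume: float = 0.0  # L above relaxation volume

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise ValueError("resistance: must be > 0")
        if self.compliance <= 0:
            raise ValueError("compliance: must be > 0")
        if self.volume < 0:
            raise ValueError("volume: must be >= 0")


@dataclass(frozen=True)
class BreathPattern:
    """Spontaneous breathing pattern of the simulated infant."""

    respiratory_rate: float = 50.0  # breaths/min
    tidal_volume: float = 0.02  # L
    inspiratory_fraction: float = 0.4  # fraction of the cycle

    def __post_init__(self) -> None:
        if self.respiratory_rate <= 0:
            raise ValueError("respiratory_rate: must be > 0")
        if self.tidal_volume < 0:
            raise ValueError("tidal_volume: must be >= 0")
        if not 0.0 < self.inspiratory_fraction < 1.0:
            raise ValueError("inspiratory_fraction: must be in (0, 1)")

    @property
    def minute_ventilation(self) -> float:
        """ml/min (= RR * Vt * 1000)."""
        return self.respiratory_rate * self.tidal_volume * 1000.0

    @classmethod
    def from_minute_ventilation(
        cls, mv_ml_min: float, respiratory_rate: float = 50.0, inspiratory_fraction: float = 0.4
    ) -> "BreathPattern":
        return cls(respiratory_rate, mv_ml_min / 1000.0 / respiratory_rate, inspiratory_fraction)


@dataclass(frozen=True)
class LeakModel:
    """Power-law characteristic of the intentional leak.

    The default coefficient is calibrated so a 5 cmH2O circuit pressure
    vents 3 L/min (the published operating point); the raw printed
    coefficient is available via :meth:`printed`, but does not reproduce
    that anchor in these units.
    """

    coefficient: float = 3.0 / 5.0**0.704  # L/min per cmH2O^exponent
    exponent: float = 0.704

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient: must be > 0")
        if not 0.0 < self.exponent < 1.0:
            raise ValueError("exponent: must be in (0, 1)")

    @classmethod
    def printed(cls) -> "LeakModel":
        """The coefficient/exponent pair exactly as printed (0.013, 0.704)."""
        return cls(coefficient=0.013, exponent=0.704)


@dataclass(frozen=True)
class BlowerModel:
    """Radial blower fan curve p = Pmax*w^2 - droop*w*flow, with a
    first-order servo lag on the normalized speed w in [0, 1]."""

    max_static_pressure: float = 40.0  # cmH2O at w=1, zero flow
    flow_droop: float = 0.5  # cmH2O per L/min at w=1
    servo_time_constant: float = 0.05  # s

    def __post_init__(self) -> None:
        if self.max_static_pressure < 15.0:
            raise ValueError("max_static_pressure: must be >= 15 cmH2O to reach protocol CPAP")
        if self.flow_droop < 0 or self.servo_time_constant <= 0:
            raise ValueError("flow_droop must be >= 0 and servo_time_constant > 0")

    def pressure(self, speed: float, flow: float) -> float:
        return self.max_static_pressure * speed * speed - self.flow_droop * speed * flow


def leak_flow(p: float, model: LeakModel) -> float:
    """Leak flow (L/min) through the intentional leak at pressure ``p``."""
    if p < 0:
        raise InvalidCircuitState(f"leak pressure must be >= 0, got {p}")
    return model.coefficient * p**model.exponent


def generate_breath_tracing(pattern: BreathPattern, duration: float, dt: float) -> np.ndarray:
    """Synthetic infant flow-demand tracing (L/min, positive = inspiration).

    Half-sine inspiration over the inspiratory fraction of the cycle,
    passive exponential expiration returning exactly the tidal volume.
    """
    if dt <= 0:
        raise ValueError("dt: must be > 0")
    period = 60.0 / pattern.respiratory_rate
    if duration < period:
        raise ValueError("duration: must cover at least one breath period")
    t = np.arange(0.0, duration, dt)
    if pattern.tidal_volume == 0.0:
        return np.zeros_like(t)
    ti = pattern.inspiratory_fraction * period
    te = period - ti
    if te <= 0:
        raise ValueError("inspiratory_fraction leaves no expiration time")
    phase = np.mod(t, period)
    amp_ls = math.pi * pattern.tidal_volume / (2.0 * ti)  # L/s
    tau_e = te / 5.0
    b_ls = pattern.tidal_volume / (tau_e * (1.0 - math.exp(-te / tau_e)))
    insp = amp_ls * np.sin(math.pi * phase / ti)
    exp_ = -b_ls * np.exp(-(phase - ti) / tau_e)
    return 60.0 * np.where(phase < ti, insp, exp_)


def lung_step(
    lung: LungModel, p_awo: float, effort_flow: float, dt: float
) -> tuple[LungModel, float]:
    """Advance the test lung one step; returns (new lung, patient flow L/min).

    The RC test lung and the breath simulator are parallel branches at the
    airway opening: the lung volume integrates only the passive RC flow,
    while the simulator's effort flow (a forced volume source) superposes
    onto the patient flow.  Explicit update, stable for dt well below R*C.
    """
    if dt > 0.01:
        raise ValueError("dt: must be <= 0.01 s for a stable explicit lung update")
    passive_ls = (p_awo - lung.volume / lung.compliance) / lung.resistance
    new_volume = max(lung.volume + passive_ls * dt, 0.0)
    return replace(lung, volume=new_volume), 60.0 * passive_ls + effort_flow


def mix_at_injection_node(
    circuit_flow_to_patient: float,
    conc_flow: float,
    conc_o2: float,
    patient_flow: float,
    previous: float = AMBIENT_O2,
) -> float:
    """Instantaneous inspired O2 fraction at the injection node (the
    zero-dead-space limit of the mixing model).

    During inspiration the patient receives the concentrator stream topped
    up with circuit air; excess concentrator flow is vented.  During
    expiration (or zero flow) the previous value holds.
    """
    if conc_flow < 0 or circuit_flow_to_patient < 0:
        raise ValueError("flows must be >= 0")
    if patient_flow <= 0:
        return previous
    if conc_flow >= patient_flow:
        return conc_o2
    enriched = conc_o2 * conc_flow
    ambient = AMBIENT_O2 * (patient_flow - conc_flow)
    return (enriched + ambient) / patient_flow


@dataclass
class CircuitState:
    """Snapshot of the simulated circuit."""

    p_blower: float = 0.0  # cmH2O
    flow_blower: float = 0.0  # L/min
    p_awo_true: float = 0.0  # cmH2O
    patient_flow: float = 0.0  # L/min, positive = inspiration
    leak_flow: float = 0.0  # L/min
    delivered_fio2: float = AMBIENT_O2  # volume-weighted inspired fraction, last breath
    o2_sensor_reading: float = AMBIENT_O2  # lagged (optionally noisy) fraction
    blower_speed: float = 0.0  # normalized
    mix_fio2: float = AMBIENT_O2  # proximal-compartment fraction
    lung_fio2: float = AMBIENT_O2


@dataclass
class PlantConfig:
    """All physical parameters of the simulated plant."""

    blower: BlowerModel = field(default_factory=BlowerModel)
    leak: LeakModel = field(default_factory=LeakModel)
    lung: LungModel = field(default_factory=LungModel)
    r_tube: float = 1.0  # cmH2O*s/L, blower-to-connector tube
    mixing_volume: float = 0.05  # L, connector + interface dead space
    lung_rest_volume: float = 0.05  # L, gas volume at relaxation
    o2_sensor_tau: float = 2.0  # s, paramagnetic sensor lag
    o2_sensor_noise_sd: float = 0.005  # O2 fraction; 0 disables
    dt: float = 0.002  # s

    def __post_init__(self) -> None:
        if self.r_tube <= 0:
            raise ValueError("r_tube: must be > 0")
        if self.dt <= 0 or self.dt > 0.01:
            raise ValueError("dt: must be in (0, 0.01] s")
        if self.mixing_volume < 0 or self.lung_rest_volume <= 0:
            raise ValueError("mixing_volume >= 0 and lung_rest_volume > 0 required")


class CircuitSimulator:
    """Fixed-step simulator of the full pneumatic circuit.

    Each step solves the (static) node pressure balance -- the pneumatic
    time constants are far below the integration step -- then integrates
    the slow states: blower servo speed, lung volume and the gas fractions.
    """

    def __init__(self, config: PlantConfig | None = None, seed: int | None = None):
        self.config = config or PlantConfig()
        self.state = CircuitState()
        self.lung = replace(self.config.lung)
        self._rng = np.random.default_rng(seed)
        self._p_node = 0.0
        self._sensor_lagged = AMBIENT_O2  # noise-free filter state
        self._lung_fio2 = AMBIENT_O2
        # per-breath delivered-FiO2 accumulators
        self._insp_o2_vol = 0.0
        self._insp_vol = 0.0
        self._was_inspiring = False

    # -- node solver -------------------------------------------------------

    def _signed_leak(self, p: float) -> float:
        k, e = self.config.leak.coefficient, self.config.leak.exponent
        return math.copysign(k * abs(p) ** e, p)

    def _solve_node(self, speed: float, conc_flow: float, effort_flow: float) -> float:
        """Node (airway-opening) pressure closing the mass balance.

        blower inflow + concentrator inflow = leak outflow + patient flow.
        The balance residual is strictly decreasing in pressure, so a
        safeguarded Newton iteration with a widening bracket is used.
        """
        cfg = self.config
        blower = cfg.blower
        g_b = 1.0 / (blower.flow_droop * speed + cfg.r_tube / 60.0)  # blower-branch conductance
        p_static = blower.max_static_pressure * speed * speed
        lung = self.lung
        k, e = cfg.leak.coefficient, cfg.leak.exponent

        def residual(p: float) -> float:
            q_b = (p_static - p) * g_b
            q_p = 60.0 * (p - lung.volume / lung.compliance) / lung.resistance + effort_flow
            return q_b + conc_flow - self._signed_leak(p) - q_p

        # bracket the root
        lo, hi = -5.0, max(blower.max_static_pressure, 10.0) + 5.0
        p = min(max(self._p_node, lo + 1e-9), hi - 1e-9)
        for _ in range(80):
            r = residual(p)
            if abs(r) < NODE_BALANCE_TOL:
                break
            if r > 0:
                lo = p
            else:
                hi = p
            dq = -g_b - 60.0 / lung.resistance - (k * e * abs(p) ** (e - 1.0) if p != 0.0 else 1e6)
            step = -r / dq
            p_new = p + step
            if not lo < p_new < hi:
                p_new = 0.5 * (lo + hi)
            p = p_new
        else:
            raise InvalidCircuitState("node pressure solver did not converge")
        if not math.isfinite(p):
            raise InvalidCircuitState("node pressure diverged (non-finite)")
        return p

    # -- stepping ----------------------------------------------------------

    def step(
        self,
        blower_speed_cmd: float,
        conc_flow: float = 0.0,
        conc_o2: float = AMBIENT_O2,
        effort_flow: float = 0.0,
    ) -> CircuitState:
        cfg = self.config
        dt = cfg.dt
        st = self.state

        # blower servo lag
        w = st.blower_speed + dt / cfg.blower.servo_time_constant * (
            min(max(blower_speed_cmd, 0.0), 1.0) - st.blower_speed
        )
        w = min(max(w, 0.0), 1.0)

        # static pneumatic balance at the connector node
        p = self._solve_node(w, conc_flow, effort_flow)
        self._p_node = p
        g_b = 1.0 / (cfg.blower.flow_droop * w + cfg.r_tube / 60.0)
        q_b = (cfg.blower.max_static_pressure * w * w - p) * g_b
        p_blower = p + cfg.r_tube * q_b / 60.0
        q_leak = self._signed_leak(p)

        # lung volume and patient flow
        self.lung, q_p = lung_step(self.lung, p, effort_flow, dt)

        # gas fractions
        mix = self._advance_gas(q_p, conc_flow, conc_o2, dt)

        # paramagnetic O2 sensor: first-order lag plus optional noise
        y = self._sensor_lagged + dt / cfg.o2_sensor_tau * (mix - self._sensor_lagged)
        self._sensor_lagged = y
        if cfg.o2_sensor_noise_sd > 0.0:
            y_read = y + self._rng.normal(0.0, cfg.o2_sensor_noise_sd)
        else:
            y_read = y

        delivered = self._update_breath_average(mix, q_p, dt)

        self.state = CircuitState(
            p_blower=p_blower,
            flow_blower=q_b,
            p_awo_true=p,
            patient_flow=q_p,
            leak_flow=max(q_leak, 0.0),
            delivered_fio2=delivered,
            o2_sensor_reading=y_read,
            blower_speed=w,
            mix_fio2=mix,
            lung_fio2=self._lung_fio2,
        )
        return self.state

    def _advance_gas(self, q_p: float, conc_flow: float, conc_o2: float, dt: float) -> float:
        """Advance the proximal mixing compartment and lung O2 fractions."""
        cfg = self.config
        st = self.state
        f_mix = st.mix_fio2
        f_lung = st.lung_fio2
        vm = cfg.mixing_volume
        q_p_ls = q_p / 60.0
        qc_ls = conc_flow / 60.0

        if vm > 0.0:
            dfdt = qc_ls * (conc_o2 - f_mix)
            junction_ls = q_p_ls - qc_ls  # circuit air makeup (signed)
            if junction_ls > 0.0:
                dfdt += junction_ls * (AMBIENT_O2 - f_mix)
            if q_p_ls < 0.0:  # exhaled test-lung gas re-enters the compartment
                dfdt += -q_p_ls * (f_lung - f_mix)
            f_mix = f_mix + dt * dfdt / vm
            f_mix = min(max(f_mix, AMBIENT_O2), 0.95)
        else:
            f_mix = mix_at_injection_node(
                max(q_p - conc_flow, 0.0), conc_flow, conc_o2, q_p, previous=f_mix
            )

        if q_p_ls > 0.0:
            v_lung = cfg.lung_rest_volume + self.lung.volume
            f_lung = f_lung + dt * q_p_ls * (f_mix - f_lung) / v_lung
        self._lung_fio2 = min(max(f_lung, AMBIENT_O2), 0.95)
        return f_mix

    def _update_breath_average(self, f_insp: float, q_p: float, dt: float) -> float:
        """Volume-weighted inspired fraction, finalized at each breath end."""
        delivered = self.state.delivered_fio2
        if q_p > 0.0:
            self._insp_o2_vol += f_insp * q_p * dt
            self._insp_vol += q_p * dt
            self._was_inspiring = True
        elif self._was_inspiring:
            if self._insp_vol > 1e-9:
                delivered = self._insp_o2_vol / self._insp_vol
            self._insp_o2_vol = 0.0
            self._insp_vol = 0.0
            self._was_inspiring = False
        return delivered


def step_circuit(
    sim: CircuitSimulator,
    blower_speed_cmd: float,
    conc_flow: float = 0.0,
    conc_o2: float = AMBIENT_O2,
    effort_flow: float = 0.0,
) -> CircuitState:
    """Functional wrapper advancing a simulator one step."""
    return sim.step(blower_speed_cmd, conc_flow, conc_o2, effort_flow)
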