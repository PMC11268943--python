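"""Static model of the PSA oxygen concentrator and its data-driven inverse models.

The concentrator is abstracted to static mean surfaces flow(cs, sv),
o2(cs, sv) and power(cs, sv) over its two control inputs: compressor speed
``cs`` and solenoid-valve duty ``sv`` (both in percent).  A characterization
experiment samples those surfaces on a fixed grid and two bivariate
quadratics are fitted to the *inverted* characteristics:

* ``cs = poly(flow, o2)``
* ``sv = poly(cs, flow)``

which are what the power-minimizing allocator consumes.  PSA cycling is not
modelled; a first-order reservoir low-pass stands in for the 170 ml buffer
that smooths the bed-switching ripple.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

AMBIENT_O2 = 0.21

#: Compressor electrical power at minimum / maximum speed (W).
COMPRESSOR_POWER_MIN_W = 65.0
COMPRESSOR_POWER_MAX_W = 146.0

#: Compressor power in "standard mode" (maximum achievable purity at the
#: required output flow), the baseline for power-saving figures.
STANDARD_MODE_COMPRESSOR_W = 130.0

CS_MIN, CS_MAX = 20.0, 100.0
SV_MIN, SV_MAX = 10.0, 100.0

#: Characterization grid (percent).
CS_GRID = tuple(range(20, 101, 10))
SV_GRID = tuple(range(10, 101, 10))


class ConcentratorError(ValueError):
    """Invalid concentrator command or degenerate characterization data."""


@dataclass(frozen=True)
class ConcentratorCommand:
    """Compressor speed and solenoid-valve duty pair, both in percent.

    ``cs = sv = 0`` is the off state; otherwise both must lie inside the
    actuation limits and an open valve requires a running compressor.
    """

    cs: float
    sv: float

    def __post_init__(self) -> None:
        if not (self.cs == 0.0 or CS_MIN <= self.cs <= CS_MAX):
            raise ConcentratorError(f"cs: must be 0 or in [{CS_MIN}, {CS_MAX}], got {self.cs}")
        if not (self.sv == 0.0 or SV_MIN <= self.sv <= SV_MAX):
            raise ConcentratorError(f"sv: must be 0 or in [{SV_MIN}, {SV_MAX}], got {self.sv}")
        if self.sv > 0.0 and self.cs == 0.0:
            raise ConcentratorError("sv: open valve requires cs > 0")

    @property
    def is_off(self) -> bool:
        return self.cs == 0.0 and self.sv == 0.0


OFF_COMMAND = ConcentratorCommand(0.0, 0.0)


@dataclass(frozen=True)
class ConcentratorOutput:
    """Steady-state output of the concentrator for one command."""

    flow: float  # L/min of oxygen-enriched gas
    o2: float  # O2 fraction of the output gas
    compressor_power: float  # W
    total_power: float  # W (compressor + valves + sensors)


@dataclass(frozen=True)
class TruthSurfaces:
    """Synthetic ground-truth characteristics of the concentrator.

    The functional forms are calibrated to the published anchors: a 65-146 W
    compressor power range affine in speed, a purity ceiling of ~93%, and
    the four monotone characterization trends (flow increases with sv and
    cs; purity decreases with sv and increases with cs).

    In a pressure-swing cycle the valve duty sets the product draw while
    the compressor speed sets the feed-air supply, so speed buys *purity*
    far more than flow.  The surfaces encode that:

    ``flow = fmax * (sv - sv_offset)/(100 - sv_offset) / (speed_gain - speed_droop * cs/100)``

    (a weakly speed-dependent flow, linear in valve duty above the opening
    threshold, whose inverted valve characteristic is an exact polynomial),
    and the speed demanded by a (flow, o2) operating point is
    quadratic-in-flow / linear-in-purity:

    ``cs = purity_cost * (o2 - base) + flow_cost1 * flow + flow_cost2 * flow**2``

    solved here for ``o2``.  Small smooth perturbations (``ripple_*``) keep
    the characteristics from being *exactly* polynomial so the inverse-model
    fits retain a realistic residual.
    """

    fmax: float = 5.0  # L/min, output flow at cs=100, sv=100
    sv_offset: float = 9.0  # percent duty below which the valves stay shut
    speed_gain: float = 1.15  # hyperbolic speed-curve parameters
    speed_droop: float = 0.15
    purity_cost: float = 400.0  # cs percent per unit purity demand
    purity_base: float = 0.65  # o2 fraction delivered at cs -> 0, low draw
    flow_cost1: float = 4.0  # cs percent per L/min
    flow_cost2: float = 2.8  # cs percent per (L/min)^2
    ripple_o2: float = 0.003  # smooth non-polynomial residual, o2 fraction
    ripple_flow: float = 0.01  # relative flow residual
    sensor_power: float = 10.0  # W
    solenoid_power_range: tuple[float, float] = (1.9, 5.0)  # W at sv=10..100
    switching_valve_power: float = 4 * 0.8  # W, supply/exhaust valves

    def _speed_curve(self, cs):
        return 1.0 / (self.speed_gain - self.speed_droop * np.asarray(cs, float) / 100.0)

    def flow(self, cs, sv):
        """Output flow in L/min; accepts scalars or arrays."""
        cs = np.asarray(cs, float)
        sv = np.asarray(sv, float)
        opening = np.clip((sv - self.sv_offset) / (100.0 - self.sv_offset), 0.0, None)
        base = self.fmax * opening * self._speed_curve(cs)
        ripple = 1.0 + self.ripple_flow * np.sin(4.3 * cs / 100.0 - 2.7 * sv / 100.0 + 0.5)
        out = np.where((cs == 0.0) | (sv == 0.0), 0.0, base * ripple)
        return float(out) if out.ndim == 0 else out

    def o2(self, cs, sv):
        """Output O2 fraction; accepts scalars or arrays."""
        cs = np.asarray(cs, float)
        sv = np.asarray(sv, float)
        f = self.flow(cs, sv)
        base = self.purity_base + (cs - self.flow_cost1 * f - self.flow_cost2 * f * f) / self.purity_cost
        ripple = self.ripple_o2 * np.sin(5.0 * cs / 100.0 + 3.0 * sv / 100.0 - 0.7)
        out = np.clip(base + ripple, AMBIENT_O2, 0.93)
        out = np.where((cs == 0.0) | (sv == 0.0), AMBIENT_O2, out)
        return float(out) if out.ndim == 0 else out

    def o2_capacity(self, cs: float) -> float:
        """Maximum O2 production rate flow*(o2 - 0.21) over sv, L/min.

        Used by the oxygen mass-conservation invariant; evaluated on a fine
        valve-duty sweep since the rippled surfaces have no closed form.
        """
        if cs == 0.0:
            return 0.0
        best = 0.0
        for sv in np.linspace(SV_MIN, SV_MAX, 181):
            rate = self.flow(cs, sv) * (self.o2(cs, sv) - AMBIENT_O2)
            best = max(best, rate)
        return best

    def compressor_power(self, cs: float) -> float:
        if cs == 0.0:
            return 0.0
        span = COMPRESSOR_POWER_MAX_W - COMPRESSOR_POWER_MIN_W
        return COMPRESSOR_POWER_MIN_W + span * (cs - CS_MIN) / (CS_MAX - CS_MIN)

    def solenoid_power(self, sv: float) -> float:
        if sv == 0.0:
            return 0.0
        lo, hi = self.solenoid_power_range
        return lo + (hi - lo) * (sv - SV_MIN) / (SV_MAX - SV_MIN)

    def __call__(self, cmd: ConcentratorCommand) -> ConcentratorOutput:
        return self.output(cmd)

    def output(self, cmd: ConcentratorCommand) -> ConcentratorOutput:
        if not isinstance(cmd, ConcentratorCommand):
            cmd = ConcentratorCommand(*cmd)
        if cmd.is_off:
            return ConcentratorOutput(0.0, AMBIENT_O2, 0.0, 0.0)
        comp = self.compressor_power(cmd.cs)
        total = (
            comp
            + self.sensor_power
            + self.solenoid_power(cmd.sv)
            + self.switching_valve_power
        )
        return ConcentratorOutput(self.flow(cmd.cs, cmd.sv), self.o2(cmd.cs, cmd.sv), comp, total)


def truth_surfaces(cmd: ConcentratorCommand, surfaces: TruthSurfaces | None = None) -> ConcentratorOutput:
    """Evaluate the synthetic ground-truth characteristics for one command."""
    return (surfaces or TruthSurfaces()).output(cmd)


def standard_mode_cs() -> float:
    """Compressor speed of standard mode under the affine power map."""
    span = COMPRESSOR_POWER_MAX_W - COMPRESSOR_POWER_MIN_W
    return CS_MIN + (STANDARD_MODE_COMPRESSOR_W - COMPRESSOR_POWER_MIN_W) / span * (CS_MAX - CS_MIN)


def run_characterization(
    surfaces: TruthSurfaces | None = None,
    noise_seed: int | None = None,
    noise_sd: tuple[float, float, float] = (0.05, 0.005, 0.5),
) -> pd.DataFrame:
    """Sample the truth surfaces on the characterization grid.

    Returns a 90-row table with columns ``cs_pct, sv_pct, flow_Lmin,
    o2_frac, compressor_W``.  Measurement noise (sd for flow, o2 fraction
    and power respectively) is only added when ``noise_seed`` is given.
    """
    surfaces = surfaces or TruthSurfaces()
    rows = []
    for cs in CS_GRID:
        for sv in SV_GRID:
            out = surfaces.output(ConcentratorCommand(float(cs), float(sv)))
            rows.append((float(cs), float(sv), out.flow, out.o2, out.compressor_power))
    table = pd.DataFrame(rows, columns=["cs_pct", "sv_pct", "flow_Lmin", "o2_frac", "compressor_W"])
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        n = len(table)
        table["flow_Lmin"] = np.clip(table["flow_Lmin"] + rng.normal(0, noise_sd[0], n), 0, None)
        table["o2_frac"] = np.clip(table["o2_frac"] + rng.normal(0, noise_sd[1], n), AMBIENT_O2, 0.93)
        table["compressor_W"] = np.clip(table["compressor_W"] + rng.normal(0, noise_sd[2], n), 0, None)
    return table


@dataclass(frozen=True)
class PolySurfaceCoeffs:
    """Coefficients of one bivariate quadratic ``z = p00 + p10 x + p01 y +
    p20 x^2 + p11 x y + p02 y^2`` plus the fit residual RMSE."""

    p00: float
    p10: float
    p01: float
    p20: float
    p11: float
    p02: float
    rmse: float = 0.0

    def evaluate(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = (
            self.p00
            + self.p10 * x
            + self.p01 * y
            + self.p20 * x * x
            + self.p11 * x * y
            + self.p02 * y * y
        )
        return float(out) if out.ndim == 0 else out

    __call__ = evaluate

    def to_dict(self) -> dict:
        return {
            "p00": self.p00, "p10": self.p10, "p01": self.p01,
            "p20": self.p20, "p11": self.p11, "p02": self.p02,
            "rmse": self.rmse,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PolySurfaceCoeffs":
        return cls(**{k: float(d[k]) for k in ("p00", "p10", "p01", "p20", "p11", "p02")},
                   rmse=float(d.get("rmse", 0.0)))

    @classmethod
    def from_json(cls, path) -> "PolySurfaceCoeffs":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fit_quadratic(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> PolySurfaceCoeffs:
    design = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    # Column scaling keeps the normal equations well conditioned across the
    # very different magnitudes of flow (L/min) and O2 fraction.
    scale = np.abs(design).max(axis=0)
    scale[scale == 0.0] = 1.0
    coef, _, rank, _ = np.linalg.lstsq(design / scale, z, rcond=None)
    if rank < design.shape[1]:
        raise ConcentratorError("characterization table is degenerate (rank-deficient design)")
    coef = coef / scale
    rmse = float(np.sqrt(np.mean((design @ coef - z) ** 2)))
    return PolySurfaceCoeffs(*map(float, coef), rmse=rmse)


def fit_inverse_cs(table: pd.DataFrame) -> PolySurfaceCoeffs:
    """Fit ``cs = poly(flow, o2)`` by ordinary least squares."""
    return _fit_quadratic(
        table["flow_Lmin"].to_numpy(float),
        table["o2_frac"].to_numpy(float),
        table["cs_pct"].to_numpy(float),
    )


def fit_inverse_sv(table: pd.DataFrame) -> PolySurfaceCoeffs:
    """Fit ``sv = poly(cs, flow)`` by ordinary least squares."""
    return _fit_quadratic(
        table["cs_pct"].to_numpy(float),
        table["flow_Lmin"].to_numpy(float),
        table["sv_pct"].to_numpy(float),
    )


def reservoir_filter(series: Sequence[float], tau: float, dt: float) -> np.ndarray:
    """First-order low-pass with unit steady-state gain.

    Models the output reservoir that buffers the PSA bed-switching ripple.
    The filter is initialized at the first sample so a constant input passes
    unchanged.
    """
    if tau <= 0:
        raise ValueError("tau: must be > 0")
    if dt <= 0:
        raise ValueError("dt: must be > 0")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x.copy()
    a = math.exp(-dt / tau)
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, x.size):
        y[i] = a * y[i - 1] + (1.0 - a) * x[i]
    return y


class ReservoirFilter:
    """Streaming counterpart of :func:`reservoir_filter`."""

    def __init__(self, tau: float, dt: float, initial: float = 0.0):
        if tau <= 0 or dt <= 0:
            raise ValueError("tau and dt must be > 0")
        self._a = math.exp(-dt / tau)
        self.value = float(initial)

    def update(self, x: float) -> float:
        self.value = self._a * self.value + (1.0 - self._a) * x
        return self.value
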