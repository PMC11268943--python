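"""In-vitro validation protocol run against the simulated plant.

Sweeps the full CPAP x FiO2 x minute-ventilation grid, records the
steady-state delivered FiO2 and power at each point, and computes the
agreement (Bland-Altman) and power-saving statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import allocation as alloc
from . import concentrator as conc
from .loop import ClosedLoopSystem, LoopConfig
from .plant import BreathPattern, PlantConfig


@dataclass(frozen=True)
class ProtocolGrid:
    """The printed validation grid; every protocol constant lives here."""

    cpap_levels: tuple[float, ...] = (3.0, 5.0, 8.0, 10.0)  # cmH2O
    fio2_levels: tuple[float, ...] = tuple(np.round(np.arange(0.25, 0.7001, 0.05), 4))
    minute_ventilations: tuple[float, ...] = (800.0, 1000.0, 1500.0)  # ml/min
    settle_time: float = 30.0  # s
    measure_window: float = 20.0  # s
    seed: int = 42

    def __post_init__(self) -> None:
        if self.settle_time <= 0 or self.measure_window <= 0:
            raise ValueError("settle_time and measure_window must be > 0")

    @property
    def n_combinations(self) -> int:
        return len(self.cpap_levels) * len(self.fio2_levels) * len(self.minute_ventilations)

    def fast(self) -> "ProtocolGrid":
        """CI profile: shorter settle/measure windows (pair with dt=5 ms)."""
        return replace(self, settle_time=28.0, measure_window=10.0)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between set and delivered FiO2, in percentage points."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean_diff_pct": self.mean_diff,
            "sd_diff_pct": self.sd_diff,
            "loa_lower_pct": self.loa_lower,
            "loa_upper_pct": self.loa_upper,
            "n": self.n,
        }


RECORD_COLUMNS = [
    "set_cpap_cmH2O",
    "set_fio2",
    "mv_ml_min",
    "delivered_fio2",
    "mean_p_awo_cmH2O",
    "compressor_power_W",
    "total_power_W",
    "standard_mode_power_W",
    "converged",
]


def _measure_point(
    cpap: float,
    fio2: float,
    mv: float,
    grid: ProtocolGrid,
    plant_config: PlantConfig,
    loop_config: LoopConfig,
    surfaces: conc.TruthSurfaces,
    lookup: alloc.LookupTable,
    coeffs: tuple,
    seed: int,
) -> dict:
    pattern = BreathPattern.from_minute_ventilation(mv)
    system = ClosedLoopSystem(
        cpap,
        fio2_target=fio2,
        pattern=pattern,
        plant_config=plant_config,
        loop_config=loop_config,
        surfaces=surfaces,
        lookup=lookup,
        coeffs=coeffs,
        seed=seed,
    )
    log = system.run(grid.settle_time + grid.measure_window, log_decimation=2)
    w = log.time_s >= grid.settle_time
    qp_pos = np.clip(log.patient_flow_Lmin[w], 0.0, None)
    if qp_pos.sum() > 0:
        delivered = float((log.sensor_fio2[w] * qp_pos).sum() / qp_pos.sum())
    else:  # no breathing: plain time average of the sensor
        delivered = float(log.sensor_fio2[w].mean())
    mean_p = float(log.p_awo_true_cmH2O[w].mean())
    converged = abs(mean_p - cpap) <= 0.3 and np.isfinite(delivered)
    return {
        "set_cpap_cmH2O": cpap,
        "set_fio2": fio2,
        "mv_ml_min": mv,
        "delivered_fio2": delivered,
        "mean_p_awo_cmH2O": mean_p,
        "compressor_power_W": float(log.compressor_power_W[w].mean()),
        "total_power_W": float(log.total_power_W[w].mean()),
        "standard_mode_power_W": conc.STANDARD_MODE_COMPRESSOR_W,
        "converged": bool(converged),
    }


def run_validation_grid(
    grid: ProtocolGrid | None = None,
    plant_config: PlantConfig | None = None,
    loop_config: LoopConfig | None = None,
    surfaces: conc.TruthSurfaces | None = None,
    characterization_noise_seed: int | None = None,
) -> pd.DataFrame:
    """Run the whole protocol grid; one row per combination.

    Deterministic for a fixed grid seed: each point draws its sensor-noise
    stream from a seed derived from the grid seed and the point index.
    Non-converged points are flagged, never dropped.
    """
    grid = grid or ProtocolGrid()
    plant_config = plant_config or PlantConfig()
    loop_config = loop_config or LoopConfig()
    surfaces = surfaces or conc.TruthSurfaces()

    table = conc.run_characterization(surfaces, noise_seed=characterization_noise_seed)
    coeffs = (conc.fit_inverse_cs(table), conc.fit_inverse_sv(table))
    lookup = alloc.build_lookup_table(*coeffs, loop_config.allocation)

    rows = []
    index = 0
    for cpap in grid.cpap_levels:
        for fio2 in grid.fio2_levels:
            for mv in grid.minute_ventilations:
                rows.append(
                    _measure_point(
                        cpap, fio2, mv, grid, plant_config, loop_config,
                        surfaces, lookup, coeffs, seed=grid.seed * 100003 + index,
                    )
                )
                index += 1
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def bland_altman(pairs) -> BlandAltmanResult:
    """Agreement statistics for (set, delivered) FiO2 fraction pairs.

    Differences are delivered - set, expressed in percentage points; the
    limits of agreement are mean +/- 1.96 sample standard deviations.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("pairs: need an (n >= 2, 2) array of (set, delivered)")
    diffs = (arr[:, 1] - arr[:, 0]) * 100.0
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd, arr.shape[0])


def bland_altman_from_records(records: pd.DataFrame, unflagged_only: bool = False) -> BlandAltmanResult:
    df = records
    if unflagged_only:
        df = df[df["converged"]]
    return bland_altman(np.column_stack([df["set_fio2"], df["delivered_fio2"]]))


def power_report(records: pd.DataFrame) -> pd.DataFrame:
    """Per-FiO2-level power summary versus standard mode.

    Saving is computed on compressor power (as the published figure does);
    the total-power saving, including valve and sensor overhead, is also
    reported.
    """
    if len(records) == 0:
        raise ValueError("records: empty")
    df = records.copy()
    df["compressor_saving"] = 1.0 - df["compressor_power_W"] / df["standard_mode_power_W"]
    standard_total = (
        conc.STANDARD_MODE_COMPRESSOR_W
        + df["total_power_W"]
        - df["compressor_power_W"]
    )
    df["total_saving"] = 1.0 - df["total_power_W"] / standard_total
    out = (
        df.groupby("set_fio2")
        .agg(
            mean_compressor_W=("compressor_power_W", "mean"),
            mean_total_W=("total_power_W", "mean"),
            compressor_saving=("compressor_saving", "mean"),
            total_saving=("total_saving", "mean"),
            n=("set_fio2", "size"),
        )
        .reset_index()
        .sort_values("set_fio2", ignore_index=True)
    )
    return out
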