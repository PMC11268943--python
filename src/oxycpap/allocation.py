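"""Power-minimizing FiO2 control allocation.

The gas-blending mass balance admits many (purity, flow) pairs for one FiO2
target; the allocator resolves the redundancy by sampling candidate
purities, computing the flow each needs, mapping both through the fitted
inverse models to a (compressor speed, valve duty) command, discarding
commands outside the actuation limits, and keeping the feasible command
with the lowest compressor speed -- the dominant power driver under the
affine speed-to-power map.  The solution is precompiled into a lookup table
over (FiO2 target, mean inspiratory flow) for cheap in-loop queries, and an
exhaustive grid-search oracle over the ground-truth surfaces is provided
for verification.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .concentrator import (
    AMBIENT_O2,
    CS_MAX,
    CS_MIN,
    OFF_COMMAND,
    SV_MAX,
    SV_MIN,
    ConcentratorCommand,
    PolySurfaceCoeffs,
    TruthSurfaces,
)

logger = logging.getLogger(__name__)


def required_conc_flow(fio2_target: float, o2_conc: float, v_awo: float) -> float | None:
    """Concentrator flow needed to hit ``fio2_target`` given purity and
    ventilator flow (the mass balance solved for the concentrator flow).

    Returns ``None`` when the candidate purity cannot reach the target
    (infeasible candidate), which is not an error.
    """
    if v_awo < 0:
        raise ValueError("v_awo: must be >= 0")
    if fio2_target < AMBIENT_O2:
        raise ValueError(f"fio2_target: must be >= {AMBIENT_O2}")
    if fio2_target == AMBIENT_O2:
        return 0.0
    if o2_conc <= fio2_target:
        return None
    return v_awo * (fio2_target - AMBIENT_O2) / (o2_conc - fio2_target)


def blend_fio2(conc_flow: float, conc_o2: float, v_awo: float) -> float:
    """Forward gas-blending mass balance: FiO2 of the mixture of the
    concentrator stream with ambient-air ventilator flow ``v_awo``."""
    total = conc_flow + v_awo
    if total <= 0:
        return AMBIENT_O2
    return (conc_o2 * conc_flow + AMBIENT_O2 * v_awo) / total


def blend_fio2_arr(conc_flow, conc_o2, v_awo):
    """Vectorized forward mass balance."""
    conc_flow = np.asarray(conc_flow, float)
    total = conc_flow + v_awo
    out = np.where(
        total > 0, (conc_o2 * conc_flow + AMBIENT_O2 * v_awo) / np.where(total > 0, total, 1.0),
        AMBIENT_O2,
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AllocationConfig:
    """Sampling density, candidate purity range and lookup-table axes."""

    n_candidates: int = 69
    o2_range: tuple[float, float] = (0.25, 0.93)
    tolerance: float = 0.005  # |FiO2 achieved - target| bound for the oracle
    fio2_axis: tuple[float, float, float] = (0.22, 0.70, 0.01)  # lo, hi, step
    v_awo_axis: tuple[float, float, float] = (0.0, 10.0, 0.25)
    # Fit-noise margin on the actuation-limit feasibility check: commands
    # within this distance outside a limit are clamped onto it rather than
    # discarded, so boundary optima survive polynomial-fit error.
    limit_slack: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.o2_range
        if not (AMBIENT_O2 < lo < hi <= 0.93):
            raise ValueError(f"o2_range: must be within ({AMBIENT_O2}, 0.93], got {self.o2_range}")
        if self.tolerance <= 0:
            raise ValueError("tolerance: must be > 0")
        if self.n_candidates < 2:
            raise ValueError("n_candidates: must be >= 2")

    def candidate_purities(self) -> np.ndarray:
        return np.linspace(self.o2_range[0], self.o2_range[1], self.n_candidates)

    def fio2_grid(self) -> np.ndarray:
        lo, hi, step = self.fio2_axis
        return np.round(np.arange(lo, hi + step / 2, step), 10)

    def v_awo_grid(self) -> np.ndarray:
        lo, hi, step = self.v_awo_axis
        return np.round(np.arange(lo, hi + step / 2, step), 10)

    def to_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "o2_range": list(self.o2_range),
            "tolerance": self.tolerance,
            "fio2_axis": list(self.fio2_axis),
            "v_awo_axis": list(self.v_awo_axis),
            "limit_slack": self.limit_slack,
        }


@dataclass(frozen=True)
class AllocationResult:
    """Outcome of one allocation query.

    ``feasible`` is False when no candidate maps inside the actuation
    limits; the returned command is then the nearest-achievable one and
    ``nearest_achievable_fio2`` reports the best target the allocator can
    reach at this ventilator flow (a saturating device, not a failure).
    """

    command: ConcentratorCommand
    compressor_power: float
    feasible: bool
    candidate_o2: float = AMBIENT_O2
    candidate_flow: float = 0.0
    nearest_achievable_fio2: float | None = None


def _compressor_power_from_cs(cs):
    from .concentrator import COMPRESSOR_POWER_MAX_W, COMPRESSOR_POWER_MIN_W

    span = COMPRESSOR_POWER_MAX_W - COMPRESSOR_POWER_MIN_W
    power = COMPRESSOR_POWER_MIN_W + span * (np.asarray(cs, float) - CS_MIN) / (CS_MAX - CS_MIN)
    power = np.where(np.asarray(cs, float) == 0.0, 0.0, power)
    return float(power) if power.ndim == 0 else power


def allocate(
    fio2_target: float,
    v_awo: float,
    coeffs_cs: PolySurfaceCoeffs,
    coeffs_sv: PolySurfaceCoeffs,
    cfg: AllocationConfig | None = None,
    _search_nearest: bool = True,
) -> AllocationResult:
    """Solve the power-minimizing allocation through the fitted inverses.

    Implements the four-step procedure: candidate purities are sampled, the
    mass balance gives each candidate's flow, the two fitted polynomials
    map (flow, purity) to a command, commands outside the actuation limits
    are discarded, and the lowest-compressor-speed feasible command wins
    (ties broken by lower valve duty).
    """
    cfg = cfg or AllocationConfig()
    if not np.isfinite(fio2_target) or not np.isfinite(v_awo):
        raise ValueError("fio2_target and v_awo must be finite")
    if fio2_target <= AMBIENT_O2 + 1e-9:
        return AllocationResult(OFF_COMMAND, 0.0, True, AMBIENT_O2, 0.0)

    o2c = cfg.candidate_purities()
    mask = o2c > fio2_target
    o2c = o2c[mask]
    if o2c.size == 0:
        return _nearest_achievable(fio2_target, v_awo, coeffs_cs, coeffs_sv, cfg)
    flow = v_awo * (fio2_target - AMBIENT_O2) / (o2c - fio2_target)

    cs = coeffs_cs.evaluate(flow, o2c)
    slack = cfg.limit_slack
    cs_ok = (cs >= CS_MIN - slack) & (cs <= CS_MAX + slack)
    cs_cmd = np.clip(cs, CS_MIN, CS_MAX)
    # valve duty is computed at the *commanded* (clamped) speed so the
    # inverse valve model still reproduces the candidate flow
    sv = coeffs_sv.evaluate(cs_cmd, flow)
    ok = cs_ok & (sv >= SV_MIN - slack) & (sv <= SV_MAX + slack)
    if not ok.any():
        if not _search_nearest:
            return AllocationResult(OFF_COMMAND, 0.0, False, nearest_achievable_fio2=None)
        return _nearest_achievable(fio2_target, v_awo, coeffs_cs, coeffs_sv, cfg)

    cs_f = cs_cmd[ok]
    sv_f = np.clip(sv[ok], SV_MIN, SV_MAX)
    order = np.lexsort((sv_f, cs_f))
    best = order[0]
    cmd = ConcentratorCommand(float(cs_f[best]), float(sv_f[best]))
    return AllocationResult(
        cmd,
        _compressor_power_from_cs(cmd.cs),
        True,
        float(o2c[ok][best]),
        float(flow[ok][best]),
    )


def _nearest_achievable(fio2_target, v_awo, coeffs_cs, coeffs_sv, cfg) -> AllocationResult:
    """Bisect the largest feasible target below ``fio2_target`` and return
    its command flagged infeasible."""
    lo, hi = AMBIENT_O2 + 1e-6, fio2_target
    best = None
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        res = allocate(mid, v_awo, coeffs_cs, coeffs_sv, cfg, _search_nearest=False)
        if res.feasible:
            best, lo = (mid, res), mid
        else:
            hi = mid
    if best is None:
        return AllocationResult(OFF_COMMAND, 0.0, False, nearest_achievable_fio2=AMBIENT_O2)
    mid, res = best
    return AllocationResult(
        res.command, res.compressor_power, False,
        res.candidate_o2, res.candidate_flow, nearest_achievable_fio2=mid,
    )


def brute_force_allocate(
    fio2_target: float,
    v_awo: float,
    surfaces: TruthSurfaces | None = None,
    cfg: AllocationConfig | None = None,
) -> AllocationResult:
    """Exhaustive search over the ground-truth surfaces.

    Verification oracle, independent of the fitted inverse models: the
    compressor speed is scanned in 1%-steps and, for each speed, the valve
    duty that delivers the target through the true surfaces and the forward
    mass balance is solved by bisection (achieved FiO2 is monotone in the
    duty).  The lowest feasible speed -- the minimum of the affine power
    map -- wins.  A 1%-step duty grid would quantize the achieved FiO2 more
    coarsely than the feasibility tolerance near the minimum dose, so the
    duty is treated as continuous, like the PWM that drives it.
    """
    surfaces = surfaces or TruthSurfaces()
    cfg = cfg or AllocationConfig()
    if fio2_target <= AMBIENT_O2 + 1e-9:
        return AllocationResult(OFF_COMMAND, 0.0, True, AMBIENT_O2, 0.0)

    sv_scan = np.linspace(SV_MIN, SV_MAX, 1801)  # 0.05%-duty sweep

    def achieved(cs, sv):
        return blend_fio2_arr(surfaces.flow(cs, sv), surfaces.o2(cs, sv), v_awo)

    best_gap, best = np.inf, None
    for cs in np.arange(CS_MIN, CS_MAX + 0.5, 1.0):
        cs = float(cs)
        f_scan = achieved(cs, sv_scan)  # not monotone: flow rises, purity falls
        k = int(np.argmin(np.abs(f_scan - fio2_target)))
        lo, hi = max(k - 1, 0), min(k + 1, sv_scan.size - 1)
        # golden-section-free refinement: ternary sample on the bracketing span
        span = np.linspace(sv_scan[lo], sv_scan[hi], 41)
        f_span = achieved(cs, span)
        j = int(np.argmin(np.abs(f_span - fio2_target)))
        sv_star, f_star = float(span[j]), float(f_span[j])
        gap = abs(f_star - fio2_target)
        if gap <= cfg.tolerance:
            cmd = ConcentratorCommand(cs, sv_star)
            return AllocationResult(
                cmd, _compressor_power_from_cs(cs), True,
                surfaces.o2(cs, sv_star), surfaces.flow(cs, sv_star),
            )
        if gap < best_gap:
            best_gap, best = gap, (cs, sv_star, f_star)
    cs, sv_star, f_star = best
    cmd = ConcentratorCommand(cs, sv_star)
    return AllocationResult(
        cmd, _compressor_power_from_cs(cs), False,
        surfaces.o2(cs, sv_star), surfaces.flow(cs, sv_star),
        nearest_achievable_fio2=f_star,
    )


@dataclass
class LookupTable:
    """Precompiled allocation over a (FiO2 target, v_awo) grid.

    ``cs`` and ``sv`` hold NaN where the grid node is infeasible; queries
    interpolate bilinearly between feasible nodes and clamp out-of-axis
    queries (with a logged warning).
    """

    fio2_axis: np.ndarray
    v_awo_axis: np.ndarray
    cs: np.ndarray  # shape (len(fio2_axis), len(v_awo_axis))
    sv: np.ndarray
    config_hash: str
    coeffs_hash: str

    def to_json(self, path) -> None:
        def _encode(a: np.ndarray) -> list:
            return [[None if not np.isfinite(v) else float(v) for v in row] for row in a]

        payload = {
            "fio2_axis": self.fio2_axis.tolist(),
            "v_awo_axis": self.v_awo_axis.tolist(),
            "cs": _encode(self.cs),
            "sv": _encode(self.sv),
            "metadata": {"config_hash": self.config_hash, "coeffs_hash": self.coeffs_hash},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "LookupTable":
        with open(path) as fh:
            d = json.load(fh)

        def _decode(rows: list) -> np.ndarray:
            return np.array([[np.nan if v is None else v for v in row] for row in rows], float)

        return cls(
            np.asarray(d["fio2_axis"], float),
            np.asarray(d["v_awo_axis"], float),
            _decode(d["cs"]),
            _decode(d["sv"]),
            d["metadata"]["config_hash"],
            d["metadata"]["coeffs_hash"],
        )


def _hash_dict(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def build_lookup_table(
    coeffs_cs: PolySurfaceCoeffs,
    coeffs_sv: PolySurfaceCoeffs,
    cfg: AllocationConfig | None = None,
) -> LookupTable:
    """Tabulate :func:`allocate` on the configured axes (deterministic)."""
    cfg = cfg or AllocationConfig()
    fio2 = cfg.fio2_grid()
    v_awo = cfg.v_awo_grid()
    cs = np.full((fio2.size, v_awo.size), np.nan)
    sv = np.full_like(cs, np.nan)
    for i, f in enumerate(fio2):
        for j, v in enumerate(v_awo):
            res = allocate(float(f), float(v), coeffs_cs, coeffs_sv, cfg, _search_nearest=False)
            if res.feasible:
                cs[i, j] = res.command.cs
                sv[i, j] = res.command.sv
    return LookupTable(
        fio2, v_awo, cs, sv,
        _hash_dict(cfg.to_dict()),
        _hash_dict({"cs": coeffs_cs.to_dict(), "sv": coeffs_sv.to_dict()}),
    )


def query_lookup(table: LookupTable, fio2_target: float, v_awo: float) -> AllocationResult:
    """Bilinear interpolation query with clamping at the axes."""
    if fio2_target <= AMBIENT_O2 + 1e-9:
        return AllocationResult(OFF_COMMAND, 0.0, True, AMBIENT_O2, 0.0)
    fa, va = table.fio2_axis, table.v_awo_axis
    f, v = fio2_target, v_awo
    if not (fa[0] <= f <= fa[-1]) or not (va[0] <= v <= va[-1]):
        logger.warning("lookup query (%.3f, %.3f) outside table axes; clamping", f, v)
        f = min(max(f, fa[0]), fa[-1])
        v = min(max(v, va[0]), va[-1])
    i = min(int(np.searchsorted(fa, f, side="right")) - 1, fa.size - 2)
    j = min(int(np.searchsorted(va, v, side="right")) - 1, va.size - 2)
    i = max(i, 0)
    j = max(j, 0)
    tx = 0.0 if fa[i + 1] == fa[i] else (f - fa[i]) / (fa[i + 1] - fa[i])
    ty = 0.0 if va[j + 1] == va[j] else (v - va[j]) / (va[j + 1] - va[j])

    corners_cs = table.cs[i : i + 2, j : j + 2]
    corners_sv = table.sv[i : i + 2, j : j + 2]
    finite = np.isfinite(corners_cs)
    if not finite.any():
        return AllocationResult(OFF_COMMAND, 0.0, False)
    if finite.all():
        w = np.array([[(1 - tx) * (1 - ty), (1 - tx) * ty], [tx * (1 - ty), tx * ty]])
        cs = float((w * corners_cs).sum())
        sv = float((w * corners_sv).sum())
    else:
        # mixed feasibility at the cell corners: fall back to the nearest
        # feasible corner rather than interpolating across the boundary
        dist = np.array([[tx**2 + ty**2, tx**2 + (1 - ty) ** 2],
                         [(1 - tx) ** 2 + ty**2, (1 - tx) ** 2 + (1 - ty) ** 2]])
        dist[~finite] = np.inf
        k = np.unravel_index(np.argmin(dist), dist.shape)
        cs = float(corners_cs[k])
        sv = float(corners_sv[k])
    cs = min(max(cs, CS_MIN), CS_MAX)
    sv = min(max(sv, SV_MIN), SV_MAX)
    cmd = ConcentratorCommand(cs, sv)
    return AllocationResult(cmd, _compressor_power_from_cs(cs), bool(finite.all()))
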