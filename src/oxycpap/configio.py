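"""JSON configuration loading with field-level validation.

One JSON file configures the whole system; every section is optional and
falls back to the documented defaults.  Errors name the offending field
path (e.g. ``plant.leak.exponent``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import allocation as alloc
from .concentrator import TruthSurfaces
from .control import PIDConfig
from .estimator import EstimatorConfig
from .loop import LoopConfig
from .plant import BlowerModel, LeakModel, LungModel, PlantConfig
from .protocol import ProtocolGrid


class ConfigError(ValueError):
    """Malformed configuration; the message names the field."""


@dataclass
class SystemConfig:
    """Everything needed to build and run the simulated system."""

    plant: PlantConfig = field(default_factory=PlantConfig)
    loop: LoopConfig = field(default_factory=LoopConfig)
    surfaces: TruthSurfaces = field(default_factory=TruthSurfaces)
    protocol: ProtocolGrid = field(default_factory=ProtocolGrid)


def _build(cls, data: dict, path: str):
    """Instantiate a (possibly nested) dataclass from a plain dict."""
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected an object, got {type(data).__name__}")
    known = {f.name: f for f in dataclasses.fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"{path}.{key}: unknown field")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        sub = path + "." + name
        ftype = f.type if isinstance(f.type, type) else None
        nested = _NESTED.get((cls, name))
        try:
            if nested is not None:
                kwargs[name] = _build(nested, value, sub)
            elif isinstance(value, list):
                kwargs[name] = tuple(value)
            else:
                kwargs[name] = value
        except ConfigError:
            raise
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


# nested-dataclass field registry (field annotations are strings under
# `from __future__ import annotations`, so resolve the types explicitly)
_NESTED = {
    (PlantConfig, "blower"): BlowerModel,
    (PlantConfig, "leak"): LeakModel,
    (PlantConfig, "lung"): LungModel,
    (LoopConfig, "pid"): PIDConfig,
    (LoopConfig, "estimator"): EstimatorConfig,
    (LoopConfig, "allocation"): alloc.AllocationConfig,
    (EstimatorConfig, "leak"): LeakModel,
    (SystemConfig, "plant"): PlantConfig,
    (SystemConfig, "loop"): LoopConfig,
    (SystemConfig, "surfaces"): TruthSurfaces,
    (SystemConfig, "protocol"): ProtocolGrid,
}


def load_config(path: str | Path | None = None) -> SystemConfig:
    """Load a system configuration from JSON (or return all defaults)."""
    if path is None:
        return SystemConfig()
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
    return _build(SystemConfig, data, "config")


def dump_default_config(path: str | Path) -> None:
    """Write the full default configuration as a commented-free JSON file."""
    cfg = SystemConfig()

    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    with open(path, "w") as fh:
        json.dump(encode(cfg), fh, indent=2)
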