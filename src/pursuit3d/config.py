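"""Run configuration: every tunable constant, serialisable as YAML.

The config nests one section per module; unknown keys are rejected so a
typo in an override never silently falls back to a default.  Provenance
(file vs default) is recorded per key, and a stable hash of the fully
resolved config goes into every results summary so runs are
reproducible from their outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .controllers import RegressionCoeffs
from .recursion import RecursionParams
from .simulator import EnergyParams, StrikeZone
from .synthetic import BoutScheduleParams, EncounterParams, PreyMotionParams

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

_SECTIONS = {
    "prey": PreyMotionParams,
    "encounter": EncounterParams,
    "schedule": BoutScheduleParams,
    "coeffs": RegressionCoeffs,
    "zone": StrikeZone,
    "energy": EnergyParams,
    "recursion": RecursionParams,
}


@dataclass(frozen=True)
class RunConfig:
    """All defaults of the pipeline, keyed by module section."""

    prey: PreyMotionParams = field(default_factory=PreyMotionParams)
    encounter: EncounterParams = field(default_factory=EncounterParams)
    schedule: BoutScheduleParams = field(default_factory=BoutScheduleParams)
    coeffs: RegressionCoeffs = field(default_factory=RegressionCoeffs)
    zone: StrikeZone = field(default_factory=StrikeZone)
    energy: EnergyParams = field(default_factory=EnergyParams)
    recursion: RecursionParams = field(default_factory=RecursionParams)
    pool_size: int = 1782
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _coerce(value, typ):
    # YAML yields ints where floats are declared; lists where tuples are
    if typ is float and isinstance(value, (int, float)):
        return float(value)
    if typ is tuple and isinstance(value, (list, tuple)):
        return tuple(value)
    return value


def _build_section(cls, data: dict, section: str, provenance: dict):
    valid = {f.name: f.type for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown key '{section}.{key}'")
        ftype = {f.name: f for f in fields(cls)}[key].type
        typ = float if "float" in str(ftype) else (
            tuple if "tuple" in str(ftype) else None)
        kwargs[key] = _coerce(value, typ) if typ else value
        provenance[f"{section}.{key}"] = "file"
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ValueError(f"bad value in section '{section}': {exc}") from exc


def load_config(path=None):
    """Load a YAML config; missing keys fall back to defaults.

    Returns (RunConfig, provenance) where provenance maps dotted keys
    to "file" or "default".  An empty / absent file yields defaults.
    Unknown keys raise ValueError naming the key.
    """
    provenance = {}
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config root must be a mapping")
    top_valid = {f.name for f in fields(RunConfig)}
    kwargs = {}
    for key, value in data.items():
        if key not in top_valid:
            raise ValueError(f"unknown key '{key}'")
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key, provenance)
        else:
            if key == "pool_size" and (not isinstance(value, int) or value < 1):
                raise ValueError("pool_size must be a positive integer")
            kwargs[key] = value
            provenance[key] = "file"
    cfg = RunConfig(**kwargs)
    for f in fields(RunConfig):
        if f.name in _SECTIONS:
            for sub in fields(_SECTIONS[f.name]):
                provenance.setdefault(f"{f.name}.{sub.name}", "default")
        else:
            provenance.setdefault(f.name, "default")
    return cfg, provenance


def save_config(cfg: RunConfig, path):
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 of the fully resolved configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()
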