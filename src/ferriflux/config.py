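"""Run configuration: schema-validated YAML with unknown keys rejected."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "ConfigError", "load_conditions"]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


@dataclass(frozen=True)
class RunConfig:
    """Pipeline switches shared across subcommands."""

    seed: int = 0
    n_last: int = 5
    pressure_atm: float = 1.0
    temperature_k: float = 298.0
    initial_headspace_ml: float = 300.0
    include_current_removal: bool = True
    include_same_day_liquid: bool = False
    nominal_gas_ml: float | None = None
    fe_tol_fraction: float = 0.02

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        return cls.from_mapping(data)


def load_conditions(path: str | Path) -> list[dict[str, Any]]:
    """Thermodynamic condition sets: a YAML list of mappings with keys
    ``label``, ``pH`` and ``activities`` (species -> activity)."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, list):
        raise ConfigError("conditions file must be a YAML list")
    out = []
    for i, entry in enumerate(data):
        if not isinstance(entry, dict):
            raise ConfigError(f"condition {i} must be a mapping")
        unknown = set(entry) - {"label", "pH", "activities", "temperature_K"}
        if unknown:
            raise ConfigError(f"condition {i}: unknown keys {sorted(unknown)}")
        if "pH" not in entry or "activities" not in entry:
            raise ConfigError(f"condition {i}: requires 'pH' and 'activities'")
        out.append(entry)
    return out
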