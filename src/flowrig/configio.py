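"""Configuration and tabular I/O.

Scenario configs are plain YAML mappings mirroring the fields of the
scenario dataclasses; fault schedules load from CSV with columns
``time_s, device, fault_type, duration_s`` (duration blank for faults that
persist until re-primed, and ``fault_type`` ``re_prime`` for the operator
action).
"""

from __future__ import annotations

import csv
from dataclasses import fields as dc_fields
from typing import Any

import yaml

from .orchestrate import DoeConfig, HydrationConfig, TwoStepConfig
from .simplant import HydrogenationUnit


def load_yaml(path: str) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return data


def load_fault_schedule_csv(path: str) -> list[dict[str, Any]]:
    """Fault schedule rows: time_s, device, fault_type, duration_s."""
    out: list[dict[str, Any]] = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                {
                    "time_s": float(row["time_s"]),
                    "device": row.get("device", ""),
                    "fault_type": row["fault_type"],
                    "duration_s": float(row["duration_s"]) if row.get("duration_s") else None,
                }
            )
    return out


def _build(cls: type, data: dict[str, Any]) -> Any:
    """Instantiate a config dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in dc_fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "unit" in kwargs and isinstance(kwargs["unit"], dict):
        unit_kwargs = dict(kwargs["unit"])
        for key in ("temp_grid", "temp_levels", "flow_levels"):
            if key in unit_kwargs:
                unit_kwargs[key] = tuple(unit_kwargs[key])
        kwargs["unit"] = HydrogenationUnit(**unit_kwargs)
    return cls(**kwargs)


def hydration_config(data: dict[str, Any] | None = None) -> HydrationConfig:
    return _build(HydrationConfig, data or {})


def doe_config(data: dict[str, Any] | None = None) -> DoeConfig:
    return _build(DoeConfig, data or {})


def twostep_config(data: dict[str, Any] | None = None) -> TwoStepConfig:
    return _build(TwoStepConfig, data or {})
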