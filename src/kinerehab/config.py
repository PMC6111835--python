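"""Detector configuration from YAML files.

A single config file can override any detector default; every key below is
optional and absent keys keep their documented defaults. The effective
(fully resolved) configuration is echoed into each session report for
provenance.

Example::

    flexion:
      elbow: {flexion_threshold_deg: 50, extension_threshold_deg: 100, convention: interior}
      knee:  {flexion_threshold_deg: 70, extension_threshold_deg: 30, convention: deviation}
    step:
      hip_rise_threshold_m: 0.09
      step_height_m: 0.15
      baseline_window_s: 2.0
    balance:
      level: 1
      excursions_m: [0.04, 0.06, 0.08]
      target_radius_m: 0.015
      time_per_target_s: 10.0
      idle_radius_m: 0.015
      calibration_window_s: 2.0
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .detectors import BalanceConfig, FlexionConfig, StepConfig

__all__ = ["load_config", "flexion_config", "step_config", "balance_config", "config_snapshot"]


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a YAML config file; ``None`` yields an empty override set."""
    if path is None:
        return {}
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    return doc


def _build(cls, defaults, overrides: dict[str, Any]):
    known = {f.name for f in dataclasses.fields(cls)}
    bad = set(overrides) - known
    if bad:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    merged = {**dataclasses.asdict(defaults), **overrides}
    if "excursions_m" in merged and isinstance(merged["excursions_m"], list):
        merged["excursions_m"] = tuple(merged["excursions_m"])
    return cls(**merged)


def flexion_config(cfg: dict[str, Any], joint: str, side: str) -> FlexionConfig:
    base = FlexionConfig.elbow(side) if joint == "elbow" else FlexionConfig.knee(side)
    overrides = dict((cfg.get("flexion") or {}).get(joint) or {})
    overrides.setdefault("joint", joint)
    overrides.setdefault("side", side)
    return _build(FlexionConfig, base, overrides)


def step_config(cfg: dict[str, Any]) -> StepConfig:
    return _build(StepConfig, StepConfig(), dict(cfg.get("step") or {}))


def balance_config(cfg: dict[str, Any]) -> BalanceConfig:
    return _build(BalanceConfig, BalanceConfig(), dict(cfg.get("balance") or {}))


def config_snapshot(obj) -> dict[str, Any]:
    """Flatten a detector config dataclass into plain JSON-safe keys."""
    out = {}
    for k, v in dataclasses.asdict(obj).items():
        out[k] = list(v) if isinstance(v, tuple) else v
    return out
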