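"""YAML/JSON run configuration: a `cohort` and a `training` section."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .cohort import CohortConfig, NoiseConfig, ScheduleConfig, VariabilityConfig
from .loso import TrainingConfig


def _build(cls, d: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    for k in d:
        if k not in names:
            raise KeyError(f"unknown config key '{path}.{k}'")
    return d


def load_config(path) -> dict:
    """Read a config file and return {'cohort': ..., 'training': ...}."""
    path = Path(path)
    text = path.read_text()
    raw = (json.loads(text) if path.suffix == ".json"
           else yaml.safe_load(text)) or {}
    for section in raw:
        if section not in ("cohort", "training"):
            raise KeyError(f"unknown config section '{section}'")
    return {
        "cohort": cohort_config_from_dict(raw.get("cohort", {})),
        "training": training_config_from_dict(raw.get("training", {})),
    }


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    sub = {"schedule": ScheduleConfig, "noise": NoiseConfig,
           "variability": VariabilityConfig}
    kwargs = {}
    for key, cls in sub.items():
        if key in d:
            kwargs[key] = cls(**_build(cls, d.pop(key), f"cohort.{key}"))
    _build(CohortConfig, d, "cohort")
    return CohortConfig(**d, **kwargs)


def training_config_from_dict(d: dict) -> TrainingConfig:
    _build(TrainingConfig, dict(d), "training")
    return TrainingConfig(**d)
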