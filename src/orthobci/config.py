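"""One-document run configuration for the command-line workflows.

All tunable defaults of the pipeline live in a single YAML-serializable
structure; unknown keys are rejected so a typo cannot silently fall back to a
default.  Every output bundle echoes the effective configuration and its hash
for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .calibration import ScheduleConfig, TrainingConfig
from .classification import StepwiseConfig
from .controller import ControllerConfig
from .preprocessing import ArtifactThresholds
from .simulate import SimulationParams

__all__ = ["RunConfig", "load_config", "config_hash"]

CONFIG_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Versioned bundle of all module defaults."""

    version: int = CONFIG_VERSION
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    thresholds: ArtifactThresholds = field(default_factory=ArtifactThresholds)
    stepwise: StepwiseConfig = field(default_factory=StepwiseConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    n_w: int = 4
    filter_order: int = 256
    cv_folds: int = 5
    permutations: int = 10000

    def training_config(self, compute_cv: bool = True,
                        cv_seed: int = 0) -> TrainingConfig:
        return TrainingConfig(n_w=self.n_w, filter_order=self.filter_order,
                              thresholds=self.thresholds,
                              stepwise=self.stepwise, compute_cv=compute_cv,
                              cv_seed=cv_seed)

    def to_dict(self) -> dict[str, Any]:
        def unpack(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj):
                return {f.name: unpack(getattr(obj, f.name))
                        for f in fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return unpack(self)


def _build(cls, doc: dict[str, Any], context: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(doc) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys under {context}: "
                         f"{sorted(unknown)}")
    kwargs = {}
    for key, value in doc.items():
        f = known[key]
        if dataclasses.is_dataclass(f.type) or key in (
                "schedule", "thresholds", "stepwise", "controller",
                "simulation"):
            sub_cls = {
                "schedule": ScheduleConfig, "thresholds": ArtifactThresholds,
                "stepwise": StepwiseConfig, "controller": ControllerConfig,
                "simulation": SimulationParams,
            }[key]
            kwargs[key] = _build(sub_cls, value or {}, f"{context}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    version = doc.get("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ValueError(f"{path}: unsupported config version {version}")
    return _build(RunConfig, doc, "config")


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the effective configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
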