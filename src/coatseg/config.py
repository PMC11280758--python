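"""Experiment configuration: one YAML file describing data, model, loss,
optimizer, augmentation and cross-validation settings.

The optimizer defaults encode the training protocol the package targets:
Adam, learning rate 0.01, first-moment coefficient 0.9, weight decay 1e-4,
batch size 6, 224 x 224 inputs, five-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .backbone import BackboneConfig
from .losses import LossConfig
from .model import ModelConfig
from .train import AugmentConfig, OptimConfig


class ConfigSchemaError(ValueError):
    """An unknown or ill-typed key in an experiment configuration."""


@dataclass
class CrossValConfig:
    k: int = 5
    seed: int = 0


@dataclass
class TrainScheduleConfig:
    steps: int = 200
    eval_every: int = 50


@dataclass
class ExperimentConfig:
    manifest: Optional[str] = None          # path to a dataset manifest CSV
    synthetic: Optional[Dict[str, Any]] = None  # or a SyntheticSpec mapping
    n_samples: int = 16                     # for synthetic data
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    optim: OptimConfig = field(default_factory=OptimConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    schedule: TrainScheduleConfig = field(default_factory=TrainScheduleConfig)
    cv: CrossValConfig = field(default_factory=CrossValConfig)
    out_dir: str = "runs/default"
    seed: int = 0


def _build(cls, mapping: Dict[str, Any], path: str = ""):
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in mapping.items():
        if key not in known:
            raise ConfigSchemaError(f"unknown config key {path}{key!r}")
        sub = _NESTED.get((cls, key))
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build(sub, value, path=f"{path}{key}.")
        elif isinstance(value, list) and key in _TUPLE_KEYS:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


_NESTED = {
    (ExperimentConfig, "model"): ModelConfig,
    (ExperimentConfig, "loss"): LossConfig,
    (ExperimentConfig, "optim"): OptimConfig,
    (ExperimentConfig, "augment"): AugmentConfig,
    (ExperimentConfig, "schedule"): TrainScheduleConfig,
    (ExperimentConfig, "cv"): CrossValConfig,
    (ModelConfig, "backbone"): BackboneConfig,
}

_TUPLE_KEYS = {"stage_widths", "blocks_per_stage", "decoder_channels"}


def load_experiment(path: Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigSchemaError("experiment config must be a mapping")
    cfg = _build(ExperimentConfig, raw)
    cfg.model.validate()
    cfg.loss.validate()
    cfg.optim.validate()
    return cfg


def save_experiment(cfg: ExperimentConfig, path: Path) -> None:
    def _plain(obj):
        if is_dataclass(obj):
            return {k: _plain(v) for k, v in asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_plain(cfg), fh, sort_keys=False)
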