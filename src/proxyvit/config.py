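"""Training configuration and flat YAML/JSON config-file handling.

A config file is a flat mapping whose keys belong to either TrainConfig
or ModelConfig; unknown keys are rejected rather than ignored, so typos
fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .model import ModelConfig

__all__ = ["TrainConfig", "load_config", "save_config"]


@dataclass
class TrainConfig:
    """Optimization and augmentation settings.

    Defaults follow the reference recipe: batch 8, Adam, learning rate
    1e-5, 500 epochs, 10-fold cross-validation. Desk-scale runs override
    epochs (5 is the CLI default) and the model size.
    """

    batch_size: int = 8
    optimizer: str = "adam"
    lr: float = 1e-5
    epochs: int = 500
    folds: int = 10
    seed: int = 0
    rotate: bool = True
    flip: bool = True
    zoom: bool = True
    rotate_deg: float = 20.0
    zoom_range: tuple = (0.9, 1.1)
    minority_boost: float = 1.0
    val_fraction: float = 0.2
    adam_betas: tuple = (0.9, 0.999)
    weight_decay: float = 0.0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.minority_boost < 1.0:
            raise ValueError("minority_boost must be >= 1")


def _field_names(cls) -> set[str]:
    return {f.name for f in fields(cls)}


def load_config(path: str) -> tuple[ModelConfig, TrainConfig]:
    """Parse a flat YAML or JSON config into (ModelConfig, TrainConfig)."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key/value mapping")
    m_names, t_names = _field_names(ModelConfig), _field_names(TrainConfig)
    unknown = set(raw) - m_names - t_names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    m_kwargs = {k: v for k, v in raw.items() if k in m_names}
    t_kwargs = {k: v for k, v in raw.items() if k in t_names}
    for kw in (m_kwargs, t_kwargs):
        for k, v in kw.items():
            if isinstance(v, list):
                kw[k] = tuple(v)
    return ModelConfig(**m_kwargs), TrainConfig(**t_kwargs)


def save_config(model_cfg: ModelConfig, train_cfg: TrainConfig,
                path: str) -> None:
    merged = {**dataclasses.asdict(model_cfg), **dataclasses.asdict(train_cfg)}
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(merged, fh, indent=2)
        else:
            yaml.safe_dump(merged, fh, sort_keys=True)
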