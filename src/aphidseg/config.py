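"""YAML round-tripping for model and training configuration."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .backbone import ModelConfig
from .train import TrainConfig

__all__ = ["load_config", "save_config"]


def save_config(path, model_cfg: ModelConfig, train_cfg: TrainConfig | None = None):
    doc = {"model": asdict(model_cfg)}
    if train_cfg is not None:
        doc["train"] = asdict(train_cfg)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> tuple[ModelConfig, TrainConfig]:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    model_cfg = ModelConfig.from_dict(doc.get("model", {}))
    train_cfg = TrainConfig(**doc.get("train", {}))
    return model_cfg, train_cfg
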