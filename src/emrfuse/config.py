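"""Structured configuration: model/training hyperparameters and YAML loading."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .synthetic import CohortConfig

__all__ = ["ModelConfig", "TrainConfig", "ExperimentConfig", "load_config"]


class ModelConfig(BaseModel):
    dim: int = 64
    n_blocks: int = 2
    n_heads: int = 4
    ffn_mult: int = 4
    d_text: int = 32
    backbone: str = "tiny-test"  # selector; only the tiny seeded backbone ships
    backbone_layers: int = 1
    backbone_heads: int = 4
    backbone_trainable: bool = False
    vocab_size: int = 512
    max_len: int = 256
    d_z: int = 32
    tau_init: float = 0.07
    lambda_init: float = 1.0
    bidirectional: bool = True


class TrainConfig(BaseModel):
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    grad_accum: int = 1
    alpha: float = 1.0
    beta: float = 0.5
    gamma: float = 1e-5
    threshold: float = Field(default=0.5, gt=0.0, lt=1.0)
    n_folds: int = 5
    seed: int = 0


class ExperimentConfig(BaseModel):
    cohort: CohortConfig = CohortConfig()
    model: ModelConfig = ModelConfig()
    train: TrainConfig = TrainConfig()


def load_config(path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return ExperimentConfig.model_validate(raw)
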