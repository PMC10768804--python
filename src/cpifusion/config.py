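"""Run configuration: a validated schema for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "validate_config", "load_config_file", "config_hash"]


class PathsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    data: str
    cache: str | None = None
    output: str = "output"


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", protected_namespaces=())
    hidden_dim: int = Field(16, ge=1)
    n_pna_layers: int = Field(2, ge=1)
    fp_bits: int = Field(512, ge=64)
    fp_radius: int = Field(2, ge=0)
    attn_dim: int = Field(16, ge=1)
    n_heads: int = Field(2, ge=1)
    conv1d_channels: int = Field(8, ge=1)
    conv2d_channels: int = Field(4, ge=1)
    head_hidden: int = Field(16, ge=1)
    fourier_F: int = Field(2, ge=1)
    max_residues: int = Field(48, ge=4)
    max_atoms: int = Field(192, ge=8)
    freeze_fraction: float = Field(0.0, ge=0.0, le=0.95)


class TrainingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pretrain_epochs: int = Field(10, ge=0)
    epochs: int = Field(20, ge=1)
    batch_size: int = Field(32, ge=1)
    lr: float = Field(1e-3, gt=0)
    pretrain_lr: float = Field(1e-3, gt=0)
    tau: float = Field(0.1, gt=0)
    patience: int = Field(5, ge=1)


class SplitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    setting: str = "novel_pair"
    n_folds: int = Field(3, ge=1)
    sim_threshold: float = Field(0.3, gt=0.0, le=1.0)
    butina_cutoff: float = Field(0.6, gt=0.0, le=1.0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    paths: PathsConfig
    model: ModelConfig = ModelConfig()
    training: TrainingConfig = TrainingConfig()
    split: SplitConfig = SplitConfig()
    task: str = "regression"
    seed: int = Field(0, ge=0)

    def model_post_init(self, _ctx) -> None:
        from .split import SETTINGS
        if self.split.setting not in SETTINGS:
            raise ValueError(
                f"unknown split setting {self.split.setting!r}; "
                f"expected one of {SETTINGS}")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw mapping against the schema; unknown keys are rejected."""
    return RunConfig.model_validate(raw)


def load_config_file(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return validate_config(raw)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
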