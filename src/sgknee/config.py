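"""Structured run configuration with schema validation.

A YAML file with sections data / augment / model / sg / optim / eval /
fusion plus a global seed; unknown keys are rejected with the offending
key path.  Every tunable documented in the library has its default here,
so a config file only needs to state deviations.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from sgknee.dda import AugmentConfig
from sgknee.network import BackboneConfig
from sgknee.phantom import PhantomParams
from sgknee.training import TrainConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataSection(_Section):
    n_exams: int = 400
    out_dir: str = "runs/data"
    spatial_size: int = 64
    layer_min: int = 16
    layer_max: int = 24
    band_width: float = 5.0
    gap_length: float = 10.0
    noise_sd: float = 0.05
    pos_fraction: float = 0.3


class AugmentSection(_Section):
    crop_size: int = 56
    erase_ratio: float = 0.5
    mixup_ratio: float = 0.25
    layer_ratio: float = 0.25
    beta_alpha: float = 0.4
    p_erase: float = 0.5
    p_mixup: float = 0.5
    block_mode: str = "side"
    style: str = "dda"


class ModelSection(_Section):
    arch: str = "small_cnn"
    out_channels: int = 32


class SgSection(_Section):
    enabled: bool = True
    group_sizes: list[int] = Field(default_factory=lambda: [1, 2, 4])
    reduction: int = 4


class OptimSection(_Section):
    epochs: int = 15
    batch_size: int = 16
    lr: float = 1e-3
    weight_decay: float = 0.01
    plateau_factor: float = 0.8
    plateau_patience: int = 5
    alpha: float | None = None
    gamma: float = 2.0
    use_dda: bool = True


class EvalSection(_Section):
    k_folds: int = 5
    tune_frac: float = 0.2
    valid_frac: float = 0.25


class FusionSection(_Section):
    enabled: bool = True


class RunConfig(_Section):
    seed: int = 0
    views: list[str] = Field(default_factory=lambda: ["axial", "coronal", "sagittal"])
    data: DataSection = Field(default_factory=DataSection)
    augment: AugmentSection = Field(default_factory=AugmentSection)
    model: ModelSection = Field(default_factory=ModelSection)
    sg: SgSection = Field(default_factory=SgSection)
    optim: OptimSection = Field(default_factory=OptimSection)
    eval: EvalSection = Field(default_factory=EvalSection)
    fusion: FusionSection = Field(default_factory=FusionSection)

    def phantom_params(self) -> PhantomParams:
        d = self.data
        return PhantomParams(
            spatial_size=d.spatial_size,
            layer_range=(d.layer_min, d.layer_max),
            band_width=d.band_width,
            gap_length=d.gap_length,
            noise_sd=d.noise_sd,
            pos_fraction=d.pos_fraction,
            seed=self.seed,
        )

    def augment_config(self) -> AugmentConfig:
        a = self.augment
        return AugmentConfig(
            crop_size=a.crop_size,
            erase_ratio=a.erase_ratio,
            mixup_ratio=a.mixup_ratio,
            layer_ratio=a.layer_ratio,
            beta_alpha=a.beta_alpha,
            mode_probabilities={"erase": a.p_erase, "mixup": a.p_mixup},
            block_mode=a.block_mode,
            seed=self.seed,
        )

    def train_config(self) -> TrainConfig:
        o = self.optim
        return TrainConfig(
            epochs=o.epochs,
            batch_size=o.batch_size,
            lr=o.lr,
            weight_decay=o.weight_decay,
            plateau_factor=o.plateau_factor,
            plateau_patience=o.plateau_patience,
            backbone=BackboneConfig(arch=self.model.arch, out_channels=self.model.out_channels),
            use_dda=o.use_dda,
            use_sg=self.sg.enabled,
            augment=self.augment_config(),
            augment_style=self.augment.style,
            group_sizes=tuple(self.sg.group_sizes),
            reduction=self.sg.reduction,
            alpha=o.alpha,
            gamma=o.gamma,
            views=tuple(self.views),
            seed=self.seed,
        )


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; `overrides` are applied on top."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for key, val in overrides.items():
            parts = key.split(".")
            node = raw
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = val
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in exc.errors())
        raise ValueError(f"invalid config: {paths}") from exc


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
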