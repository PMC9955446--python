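"""Run configuration: validated, serializable, echoed into every output.

YAML with JSON fallback; unknown keys are rejected so typos fail loudly;
CLI flags override file values. The section objects convert to the
dataclasses the library modules consume.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict

from .masking import DropWeakSpec, WeakRule
from .model import ArchitectureConfig, TrainConfig
from .phantom import OODShift, SyntheticSpec

__all__ = ["RunConfig", "load_config", "echo_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WeakRuleConfig(_Section):
    type: Literal["quantile", "absolute"] = "quantile"
    value: float = 0.10


class DropWeakConfig(_Section):
    node_drop_prob: float = 0.1
    weight_drop_prob: float = 0.1
    weak_rule: Optional[WeakRuleConfig] = WeakRuleConfig()
    scale_mode: Literal["inverted", "none"] = "inverted"

    def to_spec(self) -> DropWeakSpec:
        rule = None if self.weak_rule is None else WeakRule(self.weak_rule.type, self.weak_rule.value)
        return DropWeakSpec(self.node_drop_prob, self.weight_drop_prob, rule, self.scale_mode)


class ModelConfig(_Section):
    input_size: int = 64
    channels: tuple[int, int] = (8, 16)
    n_res_blocks: int = 1
    n_classes: int = 2
    dropout_prob: float = 0.2
    optional_nb_head: bool = False

    def to_architecture(self, dropweak: DropWeakSpec) -> ArchitectureConfig:
        return ArchitectureConfig(
            input_size=(self.input_size, self.input_size),
            channels=tuple(self.channels),
            n_res_blocks=self.n_res_blocks,
            n_classes=self.n_classes,
            dropweak_spec=dropweak,
            dropout_prob=self.dropout_prob,
            optional_nb_head=self.optional_nb_head,
        )


class TrainSection(_Section):
    optimizer: str = "adam"
    learning_rate: float = 1e-3  # full-scale reference: 1e-5
    lr_factor: float = 0.2
    lr_patience: int = 10
    batch_size: int = 16
    epochs: int = 20  # full-scale reference: 750
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    augmentation: bool = False

    def to_train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            lr_factor=self.lr_factor,
            lr_patience=self.lr_patience,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=seed,
            split=tuple(self.split),
            augmentation=self.augmentation,
        )


class OODConfig(_Section):
    texture_sd_factor: float = 2.0
    invert_vignette: bool = False
    intensity_offset: float = 0.0

    def to_shift(self) -> OODShift:
        return OODShift(self.texture_sd_factor, self.invert_vignette, self.intensity_offset)


class SyntheticConfig(_Section):
    n_images: int = 2000
    image_size: int = 64
    benign_diameter_range: tuple[float, float] = (3.0, 9.0)
    malignant_diameter_range: tuple[float, float] = (12.0, 30.0)
    benign_irregularity: float = 0.03
    malignant_irregularity: float = 0.25
    nodule_contrast: float = 0.35
    texture_sd: float = 0.08
    texture_scale: float = 3.0
    vignette_strength: float = 0.25
    pixel_noise_sd: float = 0.04
    label_noise_rate: float = 0.05
    class_balance: float = 0.5
    ood_shift: Optional[OODConfig] = None

    def to_spec(self, seed: int) -> SyntheticSpec:
        return SyntheticSpec(
            n_images=self.n_images,
            image_size=self.image_size,
            benign_diameter_range=tuple(self.benign_diameter_range),
            malignant_diameter_range=tuple(self.malignant_diameter_range),
            benign_irregularity=self.benign_irregularity,
            malignant_irregularity=self.malignant_irregularity,
            nodule_contrast=self.nodule_contrast,
            texture_sd=self.texture_sd,
            texture_scale=self.texture_scale,
            vignette_strength=self.vignette_strength,
            pixel_noise_sd=self.pixel_noise_sd,
            label_noise_rate=self.label_noise_rate,
            class_balance=self.class_balance,
            seed=seed,
            ood_shift=None if self.ood_shift is None else self.ood_shift.to_shift(),
        )


class DataConfig(_Section):
    synthetic: Optional[SyntheticConfig] = SyntheticConfig()
    manifest: Optional[str] = None


class UQConfig(_Section):
    mc_samples: int = 25  # reference sample counts: 10, 25, 50


class EvalConfig(_Section):
    k: int = 9
    thresholds: tuple[float, ...] = (0.3, 0.5)
    mode: Literal["entropy", "ph"] = "entropy"


class RunConfig(_Section):
    seed: int = 0
    data: DataConfig = DataConfig()
    model: ModelConfig = ModelConfig()
    train: TrainSection = TrainSection()
    dropweak: DropWeakConfig = DropWeakConfig()
    uq: UQConfig = UQConfig()
    eval: EvalConfig = EvalConfig()


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load YAML (JSON fallback) and apply flat key overrides."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError:
            raw = json.loads(text)
    cfg = RunConfig.model_validate(raw)
    if overrides:
        data = cfg.model_dump()
        for key, value in overrides.items():
            if value is None:
                continue
            node = data
            *parents, leaf = key.split(".")
            for p in parents:
                node = node[p]
            node[leaf] = value
        cfg = RunConfig.model_validate(data)
    return cfg


def echo_config(cfg: RunConfig, out_dir: str | Path) -> Path:
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"dropweak_version": __version__, **cfg.model_dump()}
    path = out / "config_echo.yaml"
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
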