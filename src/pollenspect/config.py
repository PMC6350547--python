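"""YAML run configuration: schema, validation and resolution.

The schema is strict — any unknown key raises a validation error rather than
being silently ignored — and a fully resolved copy (all defaults expanded) is
written into every run directory for provenance.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .augmentation import MixupConfig
from .fpa import FPAConfig
from .network import NetworkConfig
from .synthetic import DEFAULT_CLASS_COUNTS
from .training import TrainConfig

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DatasetSection(_Strict):
    counts: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    image_size: int = 32
    seed: int = 0


class AugmentationSection(_Strict):
    alpha_low: float = 0.5
    alpha_high: float = 1.0
    target_per_class: int = 2000
    train_per_class: int = 1400
    test_per_class: int = 600
    split_first: bool = False
    seed: int = 0

    def to_mixup_config(self) -> MixupConfig:
        return MixupConfig(self.alpha_low, self.alpha_high, self.target_per_class,
                           self.train_per_class, self.test_per_class, self.split_first)

    @model_validator(mode="after")
    def _check(self):
        self.to_mixup_config()  # reuse dataclass validation
        return self


class NetworkSection(_Strict):
    preset: str | None = "small"
    input_size: int | None = None
    stem_channels: int | None = None
    block_layers: list[int] | None = None
    growth_rate: int | None = None
    downsample: str = "dilated_conv"
    dropout_rate: float = 0.2
    use_batch_norm: bool = True
    seed: int = 0

    def to_network_config(self) -> NetworkConfig:
        overrides = {k: v for k, v in dict(
            input_size=self.input_size, stem_channels=self.stem_channels,
            block_layers=tuple(self.block_layers) if self.block_layers else None,
            growth_rate=self.growth_rate).items() if v is not None}
        overrides.update(downsample=self.downsample, dropout_rate=self.dropout_rate,
                         use_batch_norm=self.use_batch_norm)
        if self.preset:
            return NetworkConfig.preset(self.preset, **overrides)
        return NetworkConfig(**overrides)

    @model_validator(mode="after")
    def _check(self):
        self.to_network_config()
        return self


class FPASection(_Strict):
    n_iterations: int = 10
    n_pollen: int = 10
    switch_prob: float = 0.8
    gamma: float = 0.1
    levy_exponent: float = 1.5
    lr_min: float = 1e-4
    lr_max: float = 0.5
    every_k_steps: int = 1

    def to_fpa_config(self) -> FPAConfig:
        return FPAConfig(**self.model_dump())


class TrainingSection(_Strict):
    batch_size: int = 5
    max_epochs: int = 30
    lr_init: float = 0.05
    fpa: FPASection = Field(default_factory=FPASection)
    fpa_enabled: bool = True
    early_stop_patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0

    def to_train_config(self) -> TrainConfig:
        fpa = self.fpa.to_fpa_config()
        return TrainConfig(
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            lr_init=self.lr_init, fpa=fpa,
            fpa_every_k_steps=self.fpa.every_k_steps if self.fpa_enabled else None,
            early_stop_patience=self.early_stop_patience,
            validation_fraction=self.validation_fraction, seed=self.seed)

    @model_validator(mode="after")
    def _check(self):
        self.to_train_config()
        return self


class EvaluationSection(_Strict):
    checkpoint_every: int = 1  # epochs between precision-curve checkpoints
    batch_size: int = 64


class RunConfig(_Strict):
    dataset: DatasetSection = Field(default_factory=DatasetSection)
    augmentation: AugmentationSection = Field(default_factory=AugmentationSection)
    network: NetworkSection = Field(default_factory=NetworkSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)

    def write_resolved(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "config.resolved.yaml"
        path.write_text(self.resolved_yaml())
        return path


def load_config(path: str | Path | None = None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
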