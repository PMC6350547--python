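"""High-level model/results facade.

``SpectClassifier`` bundles the network, augmentation and training
configuration around a training set; ``fit()`` runs the optimizer and returns
a :class:`FitResults` carrying the trained network, the step/epoch history
and evaluation helpers with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .augmentation import SoftSample
from .evaluation import CLASSES, EvaluationResult, evaluate
from .network import DenseSpectNet, NetworkConfig, build_network, forward
from .synthetic import read_dataset
from .training import TrainConfig, TrainHistory, train

__all__ = ["SpectClassifier", "FitResults"]


@dataclass
class SpectClassifier:
    """A weighted-DenseNet thyroid-SPECT classifier bound to a training set."""

    train_samples: Sequence[SoftSample]
    network_config: NetworkConfig = field(default_factory=NetworkConfig)
    train_config: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, *,
                      network_config: NetworkConfig | None = None,
                      train_config: TrainConfig | None = None,
                      mixup_config=None, seed: int = 0) -> "SpectClassifier":
        """Build from a written dataset manifest, applying mixup balancing."""
        from .augmentation import MixupConfig, augment_and_split
        images = read_dataset(manifest_path)
        cfg = mixup_config or MixupConfig()
        train_set, _ = augment_and_split(images, cfg, seed)
        return cls(train_set,
                   network_config or NetworkConfig(),
                   train_config or TrainConfig(seed=seed))

    def fit(self, seed: int | None = None) -> "FitResults":
        s = self.train_config.seed if seed is None else seed
        net = build_network(self.network_config, seed=s)
        net, history = train(net, list(self.train_samples), self.train_config)
        return FitResults(net, history, self)


@dataclass
class FitResults:
    network: DenseSpectNet
    history: TrainHistory
    model: SpectClassifier

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        self.network.eval()
        return forward(self.network, images)

    def predict(self, images: np.ndarray) -> list[str]:
        return [CLASSES[i] for i in np.argmax(self.predict_proba(images), axis=1)]

    def evaluate(self, test_samples: Sequence[SoftSample]) -> EvaluationResult:
        return evaluate(self.network, list(test_samples))

    def summary(self, test_samples: Sequence[SoftSample] | None = None) -> str:
        """Plain-text fit summary; includes the per-class metric table when a
        test set is supplied."""
        lines = ["Weighted-DenseNet thyroid SPECT classifier", "=" * 44]
        cfg = self.model.network_config
        lines.append(f"blocks: {cfg.block_layers}, growth rate {cfg.growth_rate}, "
                     f"input {cfg.input_size}x{cfg.input_size}, "
                     f"downsample {cfg.downsample}")
        n_params = sum(p.data.size for p in self.network.parameters())
        n_skip = self.network.skip_weight_values().size
        lines.append(f"trainable parameters: {n_params} "
                     f"(of which {n_skip} skip-connection weights)")
        if self.history.epochs:
            last = self.history.epochs[-1]
            best = min(r["val_loss"] for r in self.history.epochs)
            lines.append(f"epochs run: {len(self.history.epochs)}; "
                         f"best validation loss {best:.4f}; "
                         f"final validation macro precision "
                         f"{last['val_macro_precision']:.4f}")
        if self.history.steps:
            lrs = [r["lr"] for r in self.history.steps]
            lines.append(f"committed learning rates: median {np.median(lrs):.4g}, "
                         f"range [{min(lrs):.4g}, {max(lrs):.4g}]")
        kw = self.network.skip_weight_values()
        lines.append(f"skip weights: mean {kw.mean():.4f}, "
                     f"min {kw.min():.4f}, max {kw.max():.4f}")
        if test_samples is not None:
            result = self.evaluate(test_samples)
            lines.append("")
            lines.append("test metrics (percent):")
            for row in result.metric_table():
                lines.append("  " + "  ".join(f"{cell:>12}" for cell in row))
            lines.append(f"  micro accuracy: {100 * result.cm.micro_accuracy():.2f}")
        return "\n".join(lines)
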