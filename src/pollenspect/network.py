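"""Weighted DenseNet classifier.

A dense block concatenates all earlier feature maps as input to each layer.
Here every incoming map additionally carries a trainable scalar weight
k_{l,i}, so layer l computes

    y_l = F_l(k_{l,0}·x_0, k_{l,1}·x_1, ..., k_{l,l-1}·x_{l-1}; W_l)

where F_l is 3x3 convolution → batch norm → ReLU and x_0 is the block input.
The convolution must come first: batch norm normalizes each channel, so
BN(k·x) = BN(x) for any k > 0 and a norm-first composite would cancel the
skip weights exactly, leaving them untrainable.  All k are initialized to 1,
so a freshly built network is numerically the standard (unweighted) dense
block; training then reweights connections by the usefulness of each feature
map.  Between blocks, downsampling uses a dilated
3x3 convolution (dilation 2, stride 2) in place of average pooling, keeping
the 2x spatial reduction while enlarging the receptive field; an average-pool
variant is retained for reference comparisons.

Within a block of ``n_layers`` features, the block input is feature 0 and
features 1..n_layers-1 are produced by transform layers; layer l therefore
carries exactly l skip weights and a block holds n_layers·(n_layers-1)/2
trainable scalars in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import _autodiff as F
from ._nn import BatchNorm2d, Conv2d, Dropout, Linear, Module, SkipWeight
from .synthetic import CLASSES

__all__ = [
    "NetworkConfig",
    "WeightedDenseLayer",
    "WeightedDenseBlock",
    "Transition",
    "DenseSpectNet",
    "weighted_dense_layer",
    "build_network",
    "load_pretrained",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
    "LoadReport",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``block_layers[i]`` is the number of features (block input included) in
    block i; ``growth_rate`` is the channel count each transform layer adds.
    """

    input_size: int = 32
    n_classes: int = 4
    stem_channels: int = 16
    block_layers: tuple[int, ...] = (4, 4, 4)
    growth_rate: int = 12
    downsample: str = "dilated_conv"
    dropout_rate: float = 0.2
    use_batch_norm: bool = True
    compression: float = 0.5

    def __post_init__(self):
        if self.n_classes != 4:
            raise ValueError("this classifier is fixed at 4 thyroid classes")
        if self.downsample not in ("dilated_conv", "pool"):
            raise ValueError(f"unknown downsample mode {self.downsample!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if any(n < 2 for n in self.block_layers):
            raise ValueError("each block needs at least 2 features (input + one layer)")
        n_transitions = len(self.block_layers) - 1
        size = self.input_size
        for _ in range(n_transitions):
            if size < 8:
                raise ValueError(
                    f"input_size {self.input_size} too small for "
                    f"{n_transitions} downsampling stages")
            if self.downsample == "pool":
                if size % 2:
                    raise ValueError(
                        f"input_size {self.input_size} not divisible by 2 at every "
                        f"of the {n_transitions} pooling stages")
                size //= 2
            else:
                size = (size - 1) // 2 + 1  # stride-2 dilated conv floors odd sizes

    @classmethod
    def preset(cls, name: str, **overrides) -> "NetworkConfig":
        if name == "tiny":
            base = dict(input_size=32, stem_channels=8, block_layers=(3, 3), growth_rate=8)
        elif name == "small":
            base = dict(input_size=32, stem_channels=16, block_layers=(4, 4, 4), growth_rate=12)
        elif name == "full":
            # mirrors DenseNet121's 6/12/24/16 transform layers per block
            base = dict(input_size=255, stem_channels=64,
                        block_layers=(7, 13, 25, 17), growth_rate=32)
        else:
            raise ValueError(f"unknown preset {name!r}")
        base.update(overrides)
        return cls(**base)


def weighted_dense_layer(features: Sequence[F.Tensor], weights: Sequence[F.Tensor],
                         transform) -> F.Tensor:
    """Scale each incoming feature map by its skip weight, concatenate along
    the channel axis, and apply the transform F_l."""
    if len(weights) != len(features):
        raise ValueError(
            f"expected {len(features)} skip weights, got {len(weights)}")
    scaled = [F.scale(x, k) for x, k in zip(features, weights)]
    return transform(F.concat(scaled, axis=1))


class WeightedDenseLayer(Module):
    """F_l = 3x3 conv → BN → ReLU, preceded by weighted concatenation.

    The convolution sees the scaled maps directly; normalizing first would
    make the output invariant to the skip weights (BN(k·x) = BN(x), k > 0).
    """

    def __init__(self, in_channels: int, growth_rate: int, n_inputs: int,
                 rng: np.random.Generator, use_batch_norm: bool = True):
        super().__init__()
        self.use_batch_norm = use_batch_norm
        self.conv = Conv2d(in_channels, growth_rate, 3, rng, padding=1)
        if use_batch_norm:
            self.norm = BatchNorm2d(growth_rate)
        for i in range(n_inputs):
            setattr(self, f"k{i}", SkipWeight())
        self.n_inputs = n_inputs

    def skip_weights(self) -> list[SkipWeight]:
        return [getattr(self, f"k{i}") for i in range(self.n_inputs)]

    def _transform(self, x: F.Tensor) -> F.Tensor:
        x = self.conv(x)
        if self.use_batch_norm:
            x = self.norm(x)
        return F.relu(x)

    def __call__(self, features: Sequence[F.Tensor]) -> F.Tensor:
        return weighted_dense_layer(features, [k.weight for k in self.skip_weights()],
                                    self._transform)


class WeightedDenseBlock(Module):
    def __init__(self, in_channels: int, n_layers: int, growth_rate: int,
                 rng: np.random.Generator, use_batch_norm: bool = True):
        super().__init__()
        self.n_layers = n_layers
        channels = in_channels
        for l in range(1, n_layers):
            setattr(self, f"layer{l}",
                    WeightedDenseLayer(channels, growth_rate, l, rng, use_batch_norm))
            channels += growth_rate
        self.out_channels = channels

    def layers(self) -> list[WeightedDenseLayer]:
        return [getattr(self, f"layer{l}") for l in range(1, self.n_layers)]

    def __call__(self, x: F.Tensor) -> F.Tensor:
        features = [x]
        for layer in self.layers():
            features.append(layer(features))
        return F.concat(features, axis=1)

    def skip_weight_values(self) -> np.ndarray:
        return np.array([k.value for layer in self.layers() for k in layer.skip_weights()])


class Transition(Module):
    """1x1 compression conv → BN → ReLU → 2x downsampling."""

    def __init__(self, in_channels: int, out_channels: int, mode: str,
                 rng: np.random.Generator, use_batch_norm: bool = True):
        super().__init__()
        self.mode = mode
        self.use_batch_norm = use_batch_norm
        self.conv = Conv2d(in_channels, out_channels, 1, rng)
        if use_batch_norm:
            self.norm = BatchNorm2d(out_channels)
        if mode == "dilated_conv":
            # 3x3, dilation 2, stride 2, padding 2: halves even spatial dims
            self.down = Conv2d(out_channels, out_channels, 3, rng,
                               stride=2, padding=2, dilation=2)
        self.out_channels = out_channels

    def __call__(self, x: F.Tensor) -> F.Tensor:
        x = self.conv(x)
        if self.use_batch_norm:
            x = self.norm(x)
        x = F.relu(x)
        if self.mode == "dilated_conv":
            return self.down(x)
        return F.avg_pool2d(x, 2)


class DenseSpectNet(Module):
    """Stem conv → weighted dense blocks with transitions → GAP → 4-way head."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2 ** 31))
        self.stem = Conv2d(1, config.stem_channels, 3, rng, padding=1)
        if config.use_batch_norm:
            self.stem_norm = BatchNorm2d(config.stem_channels)
        channels = config.stem_channels
        n_blocks = len(config.block_layers)
        for b, n_layers in enumerate(config.block_layers):
            block = WeightedDenseBlock(channels, n_layers, config.growth_rate,
                                       rng, config.use_batch_norm)
            setattr(self, f"block{b}", block)
            channels = block.out_channels
            if b < n_blocks - 1:
                out_ch = max(int(channels * config.compression), 1)
                trans = Transition(channels, out_ch, config.downsample, rng,
                                   config.use_batch_norm)
                setattr(self, f"transition{b}", trans)
                channels = out_ch
        self.head_dropout = Dropout(config.dropout_rate, self._dropout_rng)
        self.classifier = Linear(channels, config.n_classes, rng)
        self.n_blocks = n_blocks

    def blocks(self) -> list[WeightedDenseBlock]:
        return [getattr(self, f"block{b}") for b in range(self.n_blocks)]

    def forward_logits(self, x) -> F.Tensor:
        t = x if isinstance(x, F.Tensor) else F.Tensor(x)
        if t.ndim != 4 or t.shape[1] != 1 or t.shape[2] != self.config.input_size \
                or t.shape[3] != self.config.input_size:
            raise ValueError(
                f"expected input of shape (N, 1, {self.config.input_size}, "
                f"{self.config.input_size}), got {t.shape}")
        h = self.stem(t)
        if self.config.use_batch_norm:
            h = self.stem_norm(h)
        h = F.relu(h)
        for b in range(self.n_blocks):
            h = getattr(self, f"block{b}")(h)
            if b < self.n_blocks - 1:
                h = getattr(self, f"transition{b}")(h)
        h = F.global_avg_pool(h)
        h = self.head_dropout(h)
        return self.classifier(h)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return F.softmax(self.forward_logits(x).data)

    def skip_weight_values(self) -> np.ndarray:
        return np.concatenate([b.skip_weight_values() for b in self.blocks()])


def build_network(config: NetworkConfig, seed: int = 0) -> DenseSpectNet:
    """Construct a seeded weighted-DenseNet; skip weights start at exactly 1."""
    return DenseSpectNet(config, seed)


def forward(model: DenseSpectNet, batch: np.ndarray) -> np.ndarray:
    """Class-probability rows for a batch of images (N, 1, H, W) or (N, H, W)."""
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim == 3:
        batch = batch[:, None, :, :]
    return model.predict_proba(batch)


@dataclass
class LoadReport:
    loaded: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def load_pretrained(model: DenseSpectNet,
                    weight_source: Mapping[str, np.ndarray] | str | Path) -> LoadReport:
    """Copy parameters whose name and shape match; leave the rest (including
    all skip weights, absent from standard checkpoints) at initialization."""
    if isinstance(weight_source, (str, Path)):
        path = Path(weight_source)
        if not path.exists():
            raise FileNotFoundError(f"weight source not found: {path}")
        with np.load(path) as npz:
            weight_source = {k: npz[k] for k in npz.files}
    report = LoadReport()
    params = dict(model.named_parameters())
    owners = model._buffer_owners()
    for name, value in weight_source.items():
        value = np.asarray(value, dtype=np.float64)
        if name in params and params[name].data.shape == value.shape:
            params[name].data = value.copy()
            report.loaded.append(name)
        elif name in owners and owners[name][0]._buffers[owners[name][1]].shape == value.shape:
            mod, attr = owners[name]
            mod._set_buffer(attr, value.copy())
            report.loaded.append(name)
        else:
            report.skipped.append(name)
    if weight_source and not report.loaded:
        warnings.warn("no parameters matched the pretrained weight source",
                      stacklevel=2)
    return report


def save_checkpoint(model: DenseSpectNet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = model.config
    meta = dict(
        input_size=cfg.input_size, stem_channels=cfg.stem_channels,
        block_layers=np.array(cfg.block_layers), growth_rate=cfg.growth_rate,
        dropout_rate=cfg.dropout_rate, compression=cfg.compression,
        downsample=cfg.downsample, use_batch_norm=cfg.use_batch_norm,
    )
    np.savez(path, **model.state_dict(),
             **{f"__config__{k}": v for k, v in meta.items()})


def load_checkpoint(path: str | Path) -> DenseSpectNet:
    path = Path(path)
    with np.load(path, allow_pickle=False) as npz:
        cfg_keys = [k for k in npz.files if k.startswith("__config__")]
        cfg = {k[len("__config__"):]: npz[k] for k in cfg_keys}
        state = {k: npz[k] for k in npz.files if not k.startswith("__config__")}
    config = NetworkConfig(
        input_size=int(cfg["input_size"]), stem_channels=int(cfg["stem_channels"]),
        block_layers=tuple(int(n) for n in cfg["block_layers"]),
        growth_rate=int(cfg["growth_rate"]), downsample=str(cfg["downsample"]),
        dropout_rate=float(cfg["dropout_rate"]), compression=float(cfg["compression"]),
        use_batch_norm=bool(cfg["use_batch_norm"]),
    )
    model = DenseSpectNet(config)
    model.load_state_dict(state)
    return model


def class_names() -> tuple[str, ...]:
    return CLASSES
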