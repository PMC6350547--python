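"""Independent plain-numpy forward pass of the *standard* (unweighted)
DenseNet used as a verification oracle.

This module deliberately shares no code with the autodiff engine: convolution
goes through ``scipy.signal.correlate2d``, normalization and pooling are
written directly from their formulas.  With every skip weight at 1 and
pool-mode downsampling, the weighted network must reproduce this reference to
high precision; the comparison guards both the engine and the block wiring.
Inference-mode semantics (running batch-norm statistics, no dropout) are used
on both sides.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import correlate2d

from .network import DenseSpectNet

__all__ = ["reference_forward"]


def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, stride: int,
          padding: int) -> np.ndarray:
    n, c, _, _ = x.shape
    f = w.shape[0]
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    outs = []
    for img in x:
        maps = []
        for o in range(f):
            acc = sum(correlate2d(img[i], w[o, i], mode="valid") for i in range(c))
            maps.append(acc)
        outs.append(np.stack(maps))
    out = np.stack(outs)
    if stride > 1:
        out = out[:, :, ::stride, ::stride]
    if b is not None:
        out = out + b.reshape(1, -1, 1, 1)
    return out


def _bn_eval(x: np.ndarray, gamma, beta, mean, var, eps=1e-5) -> np.ndarray:
    return gamma.reshape(1, -1, 1, 1) * (x - mean.reshape(1, -1, 1, 1)) \
        / np.sqrt(var.reshape(1, -1, 1, 1) + eps) + beta.reshape(1, -1, 1, 1)


def _avg_pool(x: np.ndarray, s: int = 2) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // s, s, w // s, s).mean(axis=(3, 5))


def reference_forward(model: DenseSpectNet, x: np.ndarray) -> np.ndarray:
    """Class probabilities of the standard dense network carrying the model's
    parameters; requires ``downsample='pool'`` (skip weights are ignored,
    i.e. treated as the standard value 1)."""
    if model.config.downsample != "pool":
        raise ValueError("reference covers the standard pool-downsampling network")
    sd = model.state_dict()
    cfg = model.config
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, None]

    def conv_of(prefix: str, xx: np.ndarray, stride: int = 1, padding: int = 0):
        bias = sd.get(prefix + ".bias")
        return _conv(xx, sd[prefix + ".weight"], bias, stride, padding)

    def bn_of(prefix: str, xx: np.ndarray):
        return _bn_eval(xx, sd[prefix + ".weight"], sd[prefix + ".bias"],
                        sd[prefix + ".running_mean"], sd[prefix + ".running_var"])

    h = conv_of("stem", x, padding=1)
    if cfg.use_batch_norm:
        h = bn_of("stem_norm", h)
    h = np.maximum(h, 0.0)

    for b, n_layers in enumerate(cfg.block_layers):
        features = [h]
        for l in range(1, n_layers):
            concat = np.concatenate(features, axis=1)  # all skip weights = 1
            y = conv_of(f"block{b}.layer{l}.conv", concat, padding=1)
            if cfg.use_batch_norm:
                y = bn_of(f"block{b}.layer{l}.norm", y)
            features.append(np.maximum(y, 0.0))
        h = np.concatenate(features, axis=1)
        if b < len(cfg.block_layers) - 1:
            h = conv_of(f"transition{b}.conv", h)
            if cfg.use_batch_norm:
                h = bn_of(f"transition{b}.norm", h)
            h = _avg_pool(np.maximum(h, 0.0))

    pooled = h.mean(axis=(2, 3))
    logits = pooled @ sd["classifier.weight"].T + sd["classifier.bias"]
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
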