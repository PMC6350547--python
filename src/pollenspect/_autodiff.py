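"""Compact reverse-mode automatic differentiation over numpy arrays.

This engine provides exactly the operations the weighted-DenseNet classifier
needs: 2-D convolution (with stride, padding and dilation), batch
normalization, ReLU, inverted dropout, channel concatenation, multiplication
by a trainable scalar (the skip-connection weights), average / global-average
pooling, affine layers and a soft-target cross-entropy head.

Gradients flow through a dynamically built DAG; ``Tensor.backward`` runs a
topological sweep and accumulates into ``Tensor.grad``.  All floating point
work is float64 so that analytic identities (e.g. reduction of the weighted
dense block to the unweighted one at k=1) hold to tight tolerances.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "relu",
    "concat",
    "scale",
    "conv2d",
    "batch_norm2d",
    "avg_pool2d",
    "global_avg_pool",
    "linear",
    "dropout",
    "softmax",
    "log_softmax",
    "soft_cross_entropy",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs are deep for large nets
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g: np.ndarray) -> None:
        x._accumulate(g * mask)

    return Tensor(x.data * mask, (x,), bwd)


def concat(xs: Sequence[Tensor], axis: int = 1) -> Tensor:
    xs = [_as_tensor(x) for x in xs]
    sizes = [x.data.shape[axis] for x in xs]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for x, lo, hi in zip(xs, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            x._accumulate(g[tuple(idx)])

    return Tensor(np.concatenate([x.data for x in xs], axis=axis), tuple(xs), bwd)


def scale(x: Tensor, k: Tensor) -> Tensor:
    """Multiply a feature map by a scalar (the skip-connection weight)."""
    if k.data.size != 1:
        raise ValueError("scale expects a scalar weight")

    def bwd(g: np.ndarray) -> None:
        x._accumulate(g * k.data)
        k._accumulate(np.sum(g * x.data).reshape(k.data.shape))

    return Tensor(x.data * k.data, (x, k), bwd)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _conv_geometry(h: int, w: int, kh: int, kw: int, stride: int, padding: int,
                   dilation: int) -> tuple[int, int]:
    eh = dilation * (kh - 1) + 1
    ew = dilation * (kw - 1) + 1
    oh = (h + 2 * padding - eh) // stride + 1
    ow = (w + 2 * padding - ew) // stride + 1
    if oh < 1 or ow < 1:
        raise ValueError(
            f"convolution output would be empty for input {h}x{w}, "
            f"kernel {kh}x{kw}, stride {stride}, dilation {dilation}"
        )
    return oh, ow


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
            oh: int, ow: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            cols[:, :, i, j] = xp[:, :, hi:hi + oh * stride:stride,
                                  wj:wj + ow * stride:stride]
    return cols.reshape(n, c * kh * kw, oh * ow)


def _col2im(gcols: np.ndarray, shape: tuple, kh: int, kw: int, stride: int,
            dilation: int, oh: int, ow: int) -> np.ndarray:
    n, c, hp, wp = shape
    g = np.zeros((n, c, hp, wp), dtype=gcols.dtype)
    gc = gcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            g[:, :, hi:hi + oh * stride:stride, wj:wj + ow * stride:stride] += gc[:, :, i, j]
    return g


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation; ``w`` has shape (out, in, kh, kw)."""
    n, c, h, wd = x.data.shape
    f, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    oh, ow = _conv_geometry(h, wd, kh, kw, stride, padding, dilation)
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    cols = _im2col(xp, kh, kw, stride, dilation, oh, ow)       # (N, C*kh*kw, L)
    w2 = w.data.reshape(f, -1)
    out = np.matmul(w2, cols)                                  # (N, F, L)
    if b is not None:
        out += b.data[:, None]
    out = out.reshape(n, f, oh, ow)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g: np.ndarray) -> None:
        g2 = g.reshape(n, f, oh * ow)
        w._accumulate(np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.data.shape))
        if b is not None:
            b._accumulate(g2.sum(axis=(0, 2)))
        gcols = np.matmul(w2.T, g2)                            # (N, C*kh*kw, L)
        gxp = _col2im(gcols, xp.shape, kh, kw, stride, dilation, oh, ow)
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp)

    return Tensor(out, parents, bwd)


# ---------------------------------------------------------------------------
# normalization / pooling / affine
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
                 var: np.ndarray, eps: float = 1e-5) -> Tensor:
    """Normalize NCHW activations with the given per-channel statistics.

    The caller decides whether ``mean``/``var`` are batch statistics
    (training) or running statistics (inference); the backward pass treats
    them as the batch moments when they depend on ``x`` — pass
    ``stats_from_batch=False`` semantics by using :func:`batch_norm2d_frozen`
    for running statistics.
    """
    m = mean.reshape(1, -1, 1, 1)
    v = var.reshape(1, -1, 1, 1)
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m) * inv
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
    nhw = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bwd(g: np.ndarray) -> None:
        gamma._accumulate(np.sum(g * xhat, axis=(0, 2, 3)))
        beta._accumulate(np.sum(g, axis=(0, 2, 3)))
        gxhat = g * gamma.data.reshape(1, -1, 1, 1)
        # batch moments depend on x: full batch-norm backward
        gx = (gxhat - gxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / nhw) * inv
        x._accumulate(gx)

    return Tensor(out, (x, gamma, beta), bwd)


def batch_norm2d_frozen(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
                        var: np.ndarray, eps: float = 1e-5) -> Tensor:
    """Batch norm with statistics treated as constants (inference mode)."""
    inv = 1.0 / np.sqrt(var.reshape(1, -1, 1, 1) + eps)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def bwd(g: np.ndarray) -> None:
        gamma._accumulate(np.sum(g * xhat, axis=(0, 2, 3)))
        beta._accumulate(np.sum(g, axis=(0, 2, 3)))
        x._accumulate(g * gamma.data.reshape(1, -1, 1, 1) * inv)

    return Tensor(out, (x, gamma, beta), bwd)


def avg_pool2d(x: Tensor, size: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if h % size or w % size:
        raise ValueError(f"avg_pool2d: spatial dims {h}x{w} not divisible by {size}")
    oh, ow = h // size, w // size
    out = x.data.reshape(n, c, oh, size, ow, size).mean(axis=(3, 5))

    def bwd(g: np.ndarray) -> None:
        gx = np.repeat(np.repeat(g, size, axis=2), size, axis=3) / (size * size)
        x._accumulate(gx)

    return Tensor(out, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def bwd(g: np.ndarray) -> None:
        x._accumulate(np.broadcast_to(g[:, :, None, None], x.data.shape) / (h * w))

    return Tensor(out, (x,), bwd)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    out = x.data @ w.data.T + b.data

    def bwd(g: np.ndarray) -> None:
        w._accumulate(g.T @ x.data)
        b._accumulate(g.sum(axis=0))
        x._accumulate(g @ w.data)

    return Tensor(out, (x, w, b), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {p}")
    if p == 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)

    def bwd(g: np.ndarray) -> None:
        x._accumulate(g * mask)

    return Tensor(x.data * mask, (x,), bwd)


# ---------------------------------------------------------------------------
# classification head
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def soft_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross entropy between soft target rows and softmax(logits)."""
    t = np.asarray(targets, dtype=np.float64)
    if t.shape != logits.data.shape:
        raise ValueError(f"target shape {t.shape} != logits shape {logits.data.shape}")
    n = logits.data.shape[0]
    ls = log_softmax(logits.data)
    loss = -np.sum(t * ls) / n

    def bwd(g: np.ndarray) -> None:
        logits._accumulate(g * (softmax(logits.data) - t) / n)

    return Tensor(loss, (logits,), bwd)
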