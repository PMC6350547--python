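"""Layer abstractions over the autodiff engine: modules, parameters, buffers.

Modules own named :class:`Parameter` leaves and non-trainable buffers (batch
norm running statistics) and compose hierarchically; ``state_dict`` /
``load_state_dict`` use fully qualified names so checkpoints survive
re-instantiation from the same config.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._autodiff import (
    Parameter,
    Tensor,
    avg_pool2d,
    batch_norm2d,
    batch_norm2d_frozen,
    conv2d,
    dropout,
    linear,
    relu,
)

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "Dropout", "SkipWeight"]


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # -- mode / grads ------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        sd = {name: p.data.copy() for name, p in self.named_parameters()}
        sd.update({name: b.copy() for name, b in self.named_buffers()})
        return sd

    def load_state_dict(self, sd: dict[str, np.ndarray], strict: bool = True) -> None:
        own_params = dict(self.named_parameters())
        own_buffers = self._buffer_owners()
        missing = []
        for name, p in own_params.items():
            if name in sd:
                p.data = np.array(sd[name], dtype=np.float64).reshape(p.data.shape)
            else:
                missing.append(name)
        for name, (mod, attr) in own_buffers.items():
            if name in sd:
                mod._set_buffer(attr, np.array(sd[name], dtype=np.float64))
            else:
                missing.append(name)
        unexpected = [k for k in sd if k not in own_params and k not in own_buffers]
        if strict and (missing or unexpected):
            raise KeyError(f"state dict mismatch: missing={missing}, unexpected={unexpected}")

    def _buffer_owners(self, prefix: str = "") -> dict[str, tuple["Module", str]]:
        owners = {prefix + name: (self, name) for name in self._buffers}
        for name, m in self._modules.items():
            owners.update(m._buffer_owners(prefix + name + "."))
        return owners


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, *, stride: int = 1, padding: int = 0,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.weight = Parameter(rng.normal(0.0, std,
                                (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))
        # toggled off while the optimizer probes trial updates
        object.__setattr__(self, "update_running", True)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            if self.update_running:
                m = self.momentum
                self._set_buffer("running_mean", (1 - m) * self.running_mean + m * mean)
                self._set_buffer("running_var", (1 - m) * self.running_var + m * var)
            return batch_norm2d(x, self.weight, self.bias, mean, var, self.eps)
        return batch_norm2d_frozen(x, self.weight, self.bias,
                                   self.running_mean, self.running_var, self.eps)


class Identity(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        return dropout(x, self.p, self.rng)


class SkipWeight(Module):
    """One trainable scalar per skip connection, initialized to 1 so that the
    freshly built network coincides with the unweighted dense block."""

    def __init__(self):
        super().__init__()
        self.weight = Parameter(np.array(1.0))

    @property
    def value(self) -> float:
        return float(self.weight.data)


def relu_(x: Tensor) -> Tensor:
    return relu(x)
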