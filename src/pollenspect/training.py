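"""SGD training loop with per-minibatch learning-rate search.

Each step computes the minibatch soft-target cross entropy C and its gradient
∇w once.  The update w ← w − l·∇w is then committed at the learning rate the
flower pollination search selects, where a candidate rate's fitness is the
loss of the *same* minibatch at the trial parameters w − l·∇w (one extra
forward pass per candidate, no extra backward).  Seeding the search with the
incumbent rate — the rate committed at the previous step — guarantees the
committed loss never exceeds what the incumbent would have achieved on that
minibatch.

Trial losses are evaluated under a deterministic map: dropout disabled and
batch-norm batch statistics frozen (no running-average updates), so the
fitness is a pure function of the learning rate during one search.
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._autodiff import soft_cross_entropy
from ._nn import BatchNorm2d, Dropout
from .augmentation import SoftSample, samples_to_arrays
from .evaluation import evaluate
from .fpa import FPAConfig, optimize_learning_rate
from .network import DenseSpectNet
from .synthetic import CLASSES

__all__ = ["TrainConfig", "TrainHistory", "compute_loss", "trial_update_loss", "train"]


@dataclass
class TrainConfig:
    batch_size: int = 5
    max_epochs: int = 30
    lr_init: float = 0.05
    loss: str = "cross_entropy_soft"
    fpa: FPAConfig = field(default_factory=FPAConfig)
    fpa_every_k_steps: int | float | None = 1
    early_stop_patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.loss != "cross_entropy_soft":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if not 0.0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must lie in (0, 0.5)")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")

    @property
    def fpa_enabled(self) -> bool:
        k = self.fpa_every_k_steps
        return k is not None and k != 0 and not (isinstance(k, float) and math.isinf(k))


@dataclass
class TrainHistory:
    steps: list[dict] = field(default_factory=list)
    epochs: list[dict] = field(default_factory=list)

    def steps_frame(self):
        import pandas as pd
        return pd.DataFrame(self.steps)

    def epochs_frame(self):
        import pandas as pd
        return pd.DataFrame(self.epochs)

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.steps_frame().to_csv(out / "steps.csv", index=False)
        self.epochs_frame().to_csv(out / "epochs.csv", index=False)


@contextmanager
def _deterministic_loss_mode(model: DenseSpectNet):
    """Disable dropout and freeze batch-norm running-average updates while the
    model stays in batch-statistics (training) mode."""
    saved: list[tuple[object, str, object]] = []
    for m in model.modules():
        if isinstance(m, Dropout):
            saved.append((m, "training", m.training))
            object.__setattr__(m, "training", False)
        elif isinstance(m, BatchNorm2d):
            saved.append((m, "update_running", m.update_running))
            object.__setattr__(m, "update_running", False)
    try:
        yield
    finally:
        for obj, attr, val in saved:
            object.__setattr__(obj, attr, val)


def compute_loss(model: DenseSpectNet, x: np.ndarray, y: np.ndarray,
                 step: int | None = None) -> tuple[float, list[np.ndarray]]:
    """Minibatch soft cross entropy and its gradient w.r.t. every trainable
    parameter (skip weights included)."""
    model.zero_grad()
    loss = soft_cross_entropy(model.forward_logits(x), y)
    value = loss.item()
    if not math.isfinite(value):
        where = f" at step {step}" if step is not None else ""
        raise FloatingPointError(f"non-finite training loss{where}")
    loss.backward()
    grads = [np.zeros_like(p.data) if p.grad is None else p.grad.copy()
             for p in model.parameters()]
    return value, grads


def _deterministic_loss(model: DenseSpectNet, x: np.ndarray, y: np.ndarray) -> float:
    with _deterministic_loss_mode(model):
        return soft_cross_entropy(model.forward_logits(x), y).item()


def trial_update_loss(model, x: np.ndarray, y: np.ndarray,
                      grads: Sequence[np.ndarray], lr: float,
                      loss_fn=None) -> float:
    """Loss of the minibatch at parameters w − lr·∇w; the model's parameters
    are restored (bit-identically) before returning.

    ``loss_fn(model, x, y) -> float`` defaults to the deterministic soft
    cross entropy; ``model`` needs only ``parameters()`` and whatever the
    loss function evaluates.
    """
    if loss_fn is None:
        loss_fn = _deterministic_loss
    params = model.parameters()
    originals = [p.data for p in params]
    try:
        for p, orig, g in zip(params, originals, grads):
            p.data = orig - lr * g
        return float(loss_fn(model, x, y))
    finally:
        for p, orig in zip(params, originals):
            p.data = orig


def _apply_update(model: DenseSpectNet, grads: Sequence[np.ndarray], lr: float) -> None:
    for p, g in zip(model.parameters(), grads):
        p.data = p.data - lr * g


def _stratified_val_split(samples: Sequence[SoftSample], fraction: float,
                          rng: np.random.Generator) -> tuple[list[SoftSample], list[SoftSample]]:
    train: list[SoftSample] = []
    val: list[SoftSample] = []
    for ci in range(len(CLASSES)):
        grp = [s for s in samples if s.class_index == ci]
        if not grp:
            raise ValueError(f"training set has no samples of class {CLASSES[ci]!r}")
        n_val = max(1, int(round(fraction * len(grp))))
        if n_val >= len(grp):
            raise ValueError(f"class {CLASSES[ci]!r} too small for a validation split")
        perm = rng.permutation(len(grp))
        val.extend(grp[j] for j in perm[:n_val])
        train.extend(grp[j] for j in perm[n_val:])
    return train, val


def _validation_metrics(model: DenseSpectNet, val: Sequence[SoftSample]) -> dict:
    x, y = samples_to_arrays(val)
    was_training = model.training
    model.eval()
    loss = soft_cross_entropy(model.forward_logits(x), y).item()
    result = evaluate(model, list(val))
    if was_training:
        model.train()
    out = {"val_loss": loss,
           "val_macro_precision": result.macro["Precision"]}
    for c in CLASSES:
        p = result.reports[c].precision
        out[f"val_precision_{c}"] = float("nan") if p is None else p
    return out


def train(model: DenseSpectNet, train_samples: Sequence[SoftSample],
          config: TrainConfig) -> tuple[DenseSpectNet, TrainHistory]:
    """Train with per-minibatch FPA learning-rate search and early stopping.

    Returns the model restored to its best-validation-loss state along with
    the per-step / per-epoch history.
    """
    if len(train_samples) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    fit_samples, val_samples = _stratified_val_split(
        train_samples, config.validation_fraction, rng)
    x_all, y_all = samples_to_arrays(fit_samples)
    n = len(fit_samples)

    history = TrainHistory()
    incumbent = float(config.lr_init)
    best_val = math.inf
    best_state: dict | None = None
    epochs_since_best = 0
    step = 0
    k = config.fpa_every_k_steps

    model.train()
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            loss_before, grads = compute_loss(model, xb, yb, step)

            fpa_used = config.fpa_enabled and step % int(k) == 0
            f_incumbent = None
            if fpa_used:
                result = optimize_learning_rate(
                    lambda lr: trial_update_loss(model, xb, yb, grads, lr),
                    config.fpa, rng, incumbent_lr=incumbent)
                lr = result.l_best
                f_incumbent = result.f_incumbent
                loss_after = result.f_best
                _apply_update(model, grads, lr)
            else:
                lr = incumbent
                _apply_update(model, grads, lr)
                loss_after = _deterministic_loss(model, xb, yb)

            history.steps.append({
                "step": step, "epoch": epoch, "lr": lr,
                "loss_before": loss_before, "loss_after": loss_after,
                "loss_at_incumbent": f_incumbent, "fpa_used": fpa_used,
            })
            incumbent = lr
            step += 1

        rec = {"epoch": epoch, **_validation_metrics(model, val_samples)}
        history.epochs.append(rec)
        if rec["val_loss"] < best_val - 1e-12:
            best_val = rec["val_loss"]
            best_state = model.state_dict()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.early_stop_patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history
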