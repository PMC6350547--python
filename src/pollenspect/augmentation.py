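"""Mixup augmentation to a fixed per-class size, and the train/test split.

A virtual sample is the convex combination of two images and of their one-hot
labels,

    X' = a·X_i + (1 - a)·X_j,    Y' = a·Y_i + (1 - a)·Y_j,

with the mixing factor ``a`` drawn uniformly from [0.5, 1].  Because a >= 0.5,
X_i dominates and the mixed sample is counted toward X_i's class.  Each class
is topped up with mixed samples until it reaches ``target_per_class`` (default
2000), after which every class group is randomly partitioned into
``train_per_class`` / ``test_per_class`` (default 1400 / 600).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .synthetic import CLASS_INDEX, CLASSES, LabeledImage

N_CLASSES = len(CLASSES)


@dataclass
class SoftSample:
    """An image with a probability vector over the four classes."""

    pixels: np.ndarray
    label_vec: np.ndarray
    origin: Literal["real", "mixed"]
    class_index: int  # class of X_i for mixed samples; the hard label for real ones
    id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.label_vec = np.asarray(self.label_vec, dtype=np.float64)
        if self.label_vec.shape != (N_CLASSES,):
            raise ValueError(f"label_vec must have length {N_CLASSES}")
        if np.any(self.label_vec < 0) or abs(self.label_vec.sum() - 1.0) > 1e-9:
            raise ValueError("label_vec must be a probability vector (sum 1, entries >= 0)")
        if self.origin == "real" and not np.isclose(self.label_vec.max(), 1.0):
            raise ValueError("real samples must carry a one-hot label")
        if self.origin == "mixed" and self.label_vec.max() < 0.5 - 1e-12:
            raise ValueError("mixed samples must have a dominant component (alpha >= 0.5)")

    @property
    def hard_class(self) -> str:
        return CLASSES[self.class_index]


@dataclass
class MixupConfig:
    alpha_low: float = 0.5
    alpha_high: float = 1.0
    target_per_class: int = 2000
    train_per_class: int = 1400
    test_per_class: int = 600
    split_first: bool = False

    def __post_init__(self):
        if not 0.5 <= self.alpha_low <= self.alpha_high <= 1.0:
            raise ValueError("require 0.5 <= alpha_low <= alpha_high <= 1")
        if self.train_per_class + self.test_per_class != self.target_per_class:
            raise ValueError("train_per_class + test_per_class must equal target_per_class")
        if min(self.target_per_class, self.train_per_class, self.test_per_class) <= 0:
            raise ValueError("per-class sizes must be positive")


def one_hot(label: str, n_classes: int = N_CLASSES) -> np.ndarray:
    """One-hot vector in the fixed class order (graves, hashimoto, subacute, normal)."""
    if label not in CLASS_INDEX:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASSES}")
    vec = np.zeros(n_classes)
    vec[CLASS_INDEX[label]] = 1.0
    return vec


def mixup_pair(x_i: np.ndarray, y_i: np.ndarray, x_j: np.ndarray, y_j: np.ndarray,
               alpha: float, *, class_index: int | None = None,
               sample_id: str = "") -> SoftSample:
    """Linearly interpolate two images and their label vectors."""
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    if x_i.shape != x_j.shape:
        raise ValueError(f"image shape mismatch: {x_i.shape} vs {x_j.shape}")
    if not 0.5 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0.5, 1], got {alpha}")
    pixels = alpha * x_i + (1.0 - alpha) * x_j
    label_vec = alpha * np.asarray(y_i, dtype=np.float64) + \
        (1.0 - alpha) * np.asarray(y_j, dtype=np.float64)
    if class_index is None:
        class_index = int(np.argmax(y_i))  # X_i dominates for alpha >= 0.5
    return SoftSample(pixels, label_vec, "mixed", class_index, sample_id)


def _as_soft(img: LabeledImage) -> SoftSample:
    return SoftSample(img.pixels, one_hot(img.label), "real",
                      CLASS_INDEX[img.label], img.id)


def augment_to_target(dataset: Sequence[LabeledImage], config: MixupConfig,
                      seed: int = 0) -> list[SoftSample]:
    """Top every class up to ``target_per_class`` samples with mixup.

    All originals are retained as one-hot samples.  For each missing slot of
    class c, X_i is drawn uniformly from the class-c originals and X_j
    uniformly from all originals with X_j != X_i.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[LabeledImage]] = {c: [] for c in CLASSES}
    for img in dataset:
        by_class[img.label].append(img)
    for c in CLASSES:
        n = len(by_class[c])
        if n == 0:
            raise ValueError(f"cannot augment: class {c!r} has no original samples")
        if n > config.target_per_class:
            raise ValueError(
                f"class {c!r} has {n} originals, above the target {config.target_per_class}")

    out: list[SoftSample] = [_as_soft(img) for img in dataset]
    all_imgs = list(dataset)
    one_hots = {c: one_hot(c) for c in CLASSES}
    for c in CLASSES:
        pool = by_class[c]
        need = config.target_per_class - len(pool)
        for k in range(need):
            xi = pool[rng.integers(len(pool))]
            while True:
                xj = all_imgs[rng.integers(len(all_imgs))]
                if xj.id != xi.id:
                    break
            alpha = rng.uniform(config.alpha_low, config.alpha_high)
            out.append(mixup_pair(
                xi.pixels, one_hots[xi.label], xj.pixels, one_hots[xj.label], alpha,
                class_index=CLASS_INDEX[c], sample_id=f"mix_{c}_{k:05d}"))
    return out


def split_dataset(samples: Sequence[SoftSample], config: MixupConfig,
                  seed: int = 0) -> tuple[list[SoftSample], list[SoftSample]]:
    """Seeded per-class partition into train and test sets."""
    rng = np.random.default_rng(seed)
    groups: dict[int, list[SoftSample]] = {i: [] for i in range(N_CLASSES)}
    for s in samples:
        groups[s.class_index].append(s)
    for i, grp in groups.items():
        if len(grp) != config.target_per_class:
            raise ValueError(
                f"class {CLASSES[i]!r} group has {len(grp)} samples, "
                f"expected target_per_class={config.target_per_class}")
    train: list[SoftSample] = []
    test: list[SoftSample] = []
    for i in range(N_CLASSES):
        grp = groups[i]
        perm = rng.permutation(len(grp))
        train.extend(grp[j] for j in perm[:config.train_per_class])
        test.extend(grp[j] for j in perm[config.train_per_class:])
    return train, test


def augment_and_split(dataset: Sequence[LabeledImage], config: MixupConfig,
                      seed: int = 0) -> tuple[list[SoftSample], list[SoftSample]]:
    """Augment to target then split (default), or split originals first and
    augment each side separately (``split_first=True``, leakage-free)."""
    if not config.split_first:
        samples = augment_to_target(dataset, config, seed)
        return split_dataset(samples, config, seed + 1)

    rng = np.random.default_rng(seed)
    train_frac = config.train_per_class / config.target_per_class
    train_orig: list[LabeledImage] = []
    test_orig: list[LabeledImage] = []
    for c in CLASSES:
        grp = [img for img in dataset if img.label == c]
        if not grp:
            raise ValueError(f"cannot augment: class {c!r} has no original samples")
        perm = rng.permutation(len(grp))
        n_train = int(round(train_frac * len(grp)))
        n_train = min(max(n_train, 1), len(grp) - 1) if len(grp) > 1 else len(grp)
        train_orig.extend(grp[j] for j in perm[:n_train])
        test_orig.extend(grp[j] for j in perm[n_train:])
    tr_cfg = MixupConfig(config.alpha_low, config.alpha_high,
                         config.train_per_class, config.train_per_class - 1, 1)
    te_cfg = MixupConfig(config.alpha_low, config.alpha_high,
                         config.test_per_class, config.test_per_class - 1, 1)
    train = augment_to_target(train_orig, tr_cfg, seed + 1)
    test = augment_to_target(test_orig, te_cfg, seed + 2)
    return train, test


def samples_to_arrays(samples: Sequence[SoftSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (N, 1, H, W) images and (N, 4) soft labels."""
    x = np.stack([s.pixels for s in samples])[:, None, :, :]
    y = np.stack([s.label_vec for s in samples])
    return x, y
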