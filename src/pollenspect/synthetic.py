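"""Synthetic thyroid-SPECT-style image generation.

Planar thyroid scintigraphy shows two lobes either side of the trachea — a
"butterfly" of tracer uptake.  The four diagnostic categories modelled here
differ in uptake pattern in a way that mirrors their clinical appearance:

* ``normal``     — two mirrored lobes of moderate, fairly uniform uptake;
* ``graves``     — a diffusely enlarged gland with uniformly elevated uptake
                   (diffuse toxic goitre);
* ``hashimoto``  — normal-sized gland with patchy, heterogeneous uptake
                   (lymphocytic infiltration);
* ``subacute``   — strongly suppressed uptake across the gland (the
                   radioiodine-quiet phase of subacute thyroiditis).

Every image is drawn from a parametric family (ellipse geometry, intensity
levels, patch masks) whose parameters come from one seeded generator, so a
dataset is a pure function of ``(class_counts, image_size, seed)``.  Images
are stored as 8-bit grayscale PNG with a CSV manifest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

CLASSES: tuple[str, ...] = ("graves", "hashimoto", "subacute", "normal")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

#: class sizes of the hospital cohort the generator emulates
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "graves": 780,
    "hashimoto": 438,
    "subacute": 810,
    "normal": 860,
}

MANIFEST_NAME = "manifest.csv"
MANIFEST_HEADER = ("filename", "label", "split")


@dataclass
class LabeledImage:
    """A grayscale intensity grid in [0, 1] with a hard class label."""

    pixels: np.ndarray
    label: str
    id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"image {self.id!r}: pixels must be a square 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError(f"image {self.id!r}: non-finite pixel values")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError(f"image {self.id!r}: pixel values outside [0, 1]")
        if self.label not in CLASS_INDEX:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CLASSES}")


@dataclass
class DatasetManifest:
    """File-level view of a written dataset: (path, label, split) records."""

    records: list[tuple[str, str, str]]
    root: Path
    class_counts: dict[str, int] = field(init=False)

    def __post_init__(self):
        paths = [r[0] for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest contains duplicate file paths")
        counts: dict[str, int] = {}
        for _, label, _ in self.records:
            counts[label] = counts.get(label, 0) + 1
        self.class_counts = counts

    @property
    def path(self) -> Path:
        return self.root / MANIFEST_NAME


# ---------------------------------------------------------------------------
# pattern families
# ---------------------------------------------------------------------------

def _ellipse_mask(size: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _lobes(size: int, rng: np.random.Generator, scale: float) -> np.ndarray:
    """Two mirrored elliptical lobes; ``scale`` multiplies the gland size."""
    s = size
    cy = s * (0.50 + rng.uniform(-0.03, 0.03))
    sep = s * (0.17 + rng.uniform(-0.02, 0.02))          # half-distance between lobes
    ax = s * (0.105 + rng.uniform(-0.012, 0.012)) * scale
    ay = s * (0.28 + rng.uniform(-0.03, 0.03)) * scale
    left = _ellipse_mask(s, s / 2 - sep, cy, ax, ay)
    right = _ellipse_mask(s, s / 2 + sep, cy, ax, ay)
    # thin isthmus bridging the lobes
    isthmus = _ellipse_mask(s, s / 2, cy + 0.12 * s, 0.10 * s * scale, 0.05 * s * scale)
    return (left | right | isthmus).astype(np.float64)


def _patchy_field(size: int, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Smooth zero-mean heterogeneity used for the Hashimoto pattern."""
    noise = rng.normal(0.0, 1.0, (size, size))
    smooth = gaussian_filter(noise, sigma=size / 12.0)
    smooth /= max(np.abs(smooth).max(), 1e-12)
    return amplitude * smooth


def _render_class(label: str, size: int, rng: np.random.Generator) -> np.ndarray:
    background = 0.05
    noise_sigma = 0.03
    if label == "normal":
        mask = _lobes(size, rng, scale=1.0)
        level = rng.uniform(0.50, 0.60)
        img = background + mask * (level - background)
        img += mask * _patchy_field(size, rng, amplitude=0.04)
    elif label == "graves":
        mask = _lobes(size, rng, scale=rng.uniform(1.30, 1.50))
        level = rng.uniform(0.82, 0.92)
        img = background + mask * (level - background)
    elif label == "hashimoto":
        mask = _lobes(size, rng, scale=1.0)
        level = rng.uniform(0.45, 0.55)
        img = background + mask * (level - background)
        img += mask * _patchy_field(size, rng, amplitude=rng.uniform(0.20, 0.30))
    elif label == "subacute":
        mask = _lobes(size, rng, scale=rng.uniform(0.85, 1.0))
        level = rng.uniform(0.12, 0.20)
        img = background + mask * (level - background)
    else:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown label {label!r}")
    img = img + rng.normal(0.0, noise_sigma, (size, size))
    return np.clip(img, 0.0, 1.0)


def generate_dataset(class_counts: dict[str, int] | None = None,
                     image_size: int = 255, seed: int = 0) -> list[LabeledImage]:
    """Generate a labeled synthetic dataset with the requested per-class sizes.

    Deterministic in ``(class_counts, image_size, seed)``; classes are always
    rendered in the canonical order regardless of dict ordering.
    """
    if class_counts is None:
        class_counts = DEFAULT_CLASS_COUNTS
    for label, n in class_counts.items():
        if label not in CLASS_INDEX:
            raise ValueError(f"unknown label {label!r}; expected one of {CLASSES}")
        if not isinstance(n, (int, np.integer)) or n < 0:
            raise ValueError(f"count for {label!r} must be a nonnegative integer, got {n!r}")
    if image_size < 16:
        raise ValueError(f"image_size must be >= 16, got {image_size}")
    rng = np.random.default_rng(seed)
    images: list[LabeledImage] = []
    for label in CLASSES:
        n = int(class_counts.get(label, 0))
        for k in range(n):
            pixels = _render_class(label, image_size, rng)
            images.append(LabeledImage(pixels, label, f"{label}_{k:05d}"))
    return images


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(pixels * 255.0), 0, 255).astype(np.uint8)


def write_dataset(images: list[LabeledImage], out_dir: str | Path,
                  splits: dict[str, str] | None = None) -> DatasetManifest:
    """Write images as 8-bit PNGs plus a (filename,label,split) manifest."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    records: list[tuple[str, str, str]] = []
    for img in images:
        fname = f"{img.id}.png"
        Image.fromarray(_to_uint8(img.pixels), mode="L").save(root / fname)
        split = (splits or {}).get(img.id, "")
        records.append((fname, img.label, split))
    manifest = DatasetManifest(records, root)
    with open(manifest.path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_HEADER)
        writer.writerows(records)
    return manifest


def read_manifest(manifest_path: str | Path) -> DatasetManifest:
    path = Path(manifest_path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = tuple(next(reader))
        if header != MANIFEST_HEADER:
            raise ValueError(f"unexpected manifest header {header!r} in {path}")
        records = [(row[0], row[1], row[2]) for row in reader]
    return DatasetManifest(records, path.parent)


def read_dataset(manifest_path: str | Path) -> list[LabeledImage]:
    """Load a written dataset; pixel values are the 8-bit levels / 255."""
    manifest = read_manifest(manifest_path)
    images: list[LabeledImage] = []
    for fname, label, _split in manifest.records:
        fpath = manifest.root / fname
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing image file: {fpath}")
        with Image.open(fpath) as im:
            pixels = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
        images.append(LabeledImage(pixels, label, Path(fname).stem))
    return images


def lobe_features(image: LabeledImage, threshold: float = 0.3) -> tuple[float, float]:
    """(mean intensity, uptake-area fraction) — a deliberately crude feature
    pair used to verify that the generated classes carry learnable signal."""
    px = image.pixels
    return float(px.mean()), float((px > threshold).mean())
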