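"""Confusion matrix and one-vs-rest per-class metrics.

The confusion matrix follows the column-=-actual convention: entry (r, c)
counts samples whose actual class is c and predicted class is r, so column
sums are the per-class actual totals.  For each class the one-vs-rest counts
TP/TN/FP/FN yield

    recall      = TP / (TP + FN)
    precision   = TP / (TP + FP)
    accuracy    = (TP + TN) / (TP + FN + FP + TN)
    specificity = TN / (FP + TN)
    F1          = 2·TP / (2·TP + FP + FN)

A metric whose denominator is zero is reported as ``None`` (undefined), never
as 0 or 1, and undefined classes are excluded from macro averages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .augmentation import SoftSample, samples_to_arrays
from .synthetic import CLASS_INDEX, CLASSES

N = len(CLASSES)
METRIC_ROWS = ("Recall", "Precision", "Accuracy", "Specificity", "F1 score")


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows index the predicted class, columns the actual class."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N, N):
            raise ValueError(f"confusion matrix must be {N}x{N}")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix entries must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def actual_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)  # column sums

    def micro_accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else float("nan")


@dataclass
class ClassReport:
    label: str
    tp: int
    tn: int
    fp: int
    fn: int
    recall: float | None = field(init=False)
    precision: float | None = field(init=False)
    accuracy: float | None = field(init=False)
    specificity: float | None = field(init=False)
    f1: float | None = field(init=False)

    def __post_init__(self):
        def ratio(num: int, den: int) -> float | None:
            return num / den if den > 0 else None

        self.recall = ratio(self.tp, self.tp + self.fn)
        self.precision = ratio(self.tp, self.tp + self.fp)
        self.accuracy = ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)
        self.specificity = ratio(self.tn, self.fp + self.tn)
        self.f1 = ratio(2 * self.tp, 2 * self.tp + self.fp + self.fn)

    def metrics(self) -> dict[str, float | None]:
        return {"Recall": self.recall, "Precision": self.precision,
                "Accuracy": self.accuracy, "Specificity": self.specificity,
                "F1 score": self.f1}


def _label_indices(labels: Sequence) -> np.ndarray:
    idx = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            if lab not in CLASS_INDEX:
                raise ValueError(f"unknown label {lab!r}; expected one of {CLASSES}")
            idx[i] = CLASS_INDEX[lab]
        else:
            j = int(lab)
            if not 0 <= j < N:
                raise ValueError(f"label index {j} out of range 0..{N - 1}")
            idx[i] = j
    return idx


def confusion_matrix(predicted: Sequence, actual: Sequence) -> ConfusionMatrix:
    """Tally predictions against actual labels (names or indices)."""
    if len(predicted) != len(actual):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(actual)} actuals")
    p = _label_indices(predicted)
    a = _label_indices(actual)
    counts = np.zeros((N, N), dtype=np.int64)
    np.add.at(counts, (p, a), 1)
    return ConfusionMatrix(counts)


def class_report(cm: ConfusionMatrix, label: str) -> ClassReport:
    """One-vs-rest counts and the five derived metrics for one class."""
    if label not in CLASS_INDEX:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASSES}")
    c = CLASS_INDEX[label]
    tp = int(cm.counts[c, c])
    fn = int(cm.counts[:, c].sum() - tp)   # actual c, predicted elsewhere
    fp = int(cm.counts[c, :].sum() - tp)   # predicted c, actually elsewhere
    tn = int(cm.total - tp - fn - fp)
    return ClassReport(label, tp, tn, fp, fn)


def macro_precision(cm: ConfusionMatrix) -> tuple[float, int]:
    """Unweighted mean of defined per-class precisions and how many classes
    contributed; (nan, 0) when every class precision is undefined."""
    vals = [class_report(cm, c).precision for c in CLASSES]
    defined = [v for v in vals if v is not None]
    if not defined:
        return float("nan"), 0
    return float(np.mean(defined)), len(defined)


@dataclass
class EvaluationResult:
    cm: ConfusionMatrix
    reports: dict[str, ClassReport]
    macro: dict[str, float]

    def metric_table(self) -> list[list[str]]:
        """Rows = metrics, columns = classes, cells = percent to 2 decimals."""
        rows = [["Metric", *CLASSES]]
        for metric in METRIC_ROWS:
            row = [metric]
            for c in CLASSES:
                v = self.reports[c].metrics()[metric]
                row.append("" if v is None else _pct(v))
            rows.append(row)
        return rows


def _pct(v: float) -> str:
    # half-even rounding to 2 decimals, on the percent scale
    return f"{float(np.round(v * 100.0, 2)):.2f}"


def evaluate_predictions(predicted: Sequence, actual: Sequence) -> EvaluationResult:
    cm = confusion_matrix(predicted, actual)
    reports = {c: class_report(cm, c) for c in CLASSES}
    macro: dict[str, float] = {}
    for metric in METRIC_ROWS:
        vals = [reports[c].metrics()[metric] for c in CLASSES]
        defined = [v for v in vals if v is not None]
        macro[metric] = float(np.mean(defined)) if defined else float("nan")
    macro["Micro accuracy"] = cm.micro_accuracy()
    return EvaluationResult(cm, reports, macro)


def evaluate(model, test_samples: Sequence[SoftSample],
             batch_size: int = 64) -> EvaluationResult:
    """Run the model over a test set; a sample's actual class is the argmax of
    its (possibly soft) label vector and the prediction is the argmax of the
    model's probability row."""
    if len(test_samples) == 0:
        raise ValueError("test set is empty")
    x, y = samples_to_arrays(test_samples)
    model.eval()
    preds = []
    for lo in range(0, len(test_samples), batch_size):
        probs = model.predict_proba(x[lo:lo + batch_size])
        preds.append(np.argmax(probs, axis=1))
    predicted = np.concatenate(preds)
    actual = np.argmax(y, axis=1)
    return evaluate_predictions(predicted, actual)


def write_report(result: EvaluationResult, out_dir: str | Path) -> tuple[Path, Path]:
    """Persist a JSON report and a CSV metric table (percentages, 2 decimals)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "confusion_matrix": {
            "convention": "rows=predicted, columns=actual",
            "classes": list(CLASSES),
            "counts": result.cm.counts.tolist(),
        },
        "per_class": {
            c: {"TP": r.tp, "TN": r.tn, "FP": r.fp, "FN": r.fn,
                **{k: (None if v is None else round(v * 100.0, 2))
                   for k, v in r.metrics().items()}}
            for c, r in result.reports.items()
        },
        "macro": {k: (None if np.isnan(v) else round(v * 100.0, 2))
                  for k, v in result.macro.items()},
        "total_samples": result.cm.total,
    }
    json_path = out / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    csv_path = out / "metrics.csv"
    lines = [",".join(row) for row in result.metric_table()]
    csv_path.write_text("\n".join(lines) + "\n")
    return json_path, csv_path


def plot_precision_curve(epoch_records, path: str | Path) -> Path:
    """Macro-precision vs training iteration (epoch) curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    epochs = [r["epoch"] for r in epoch_records]
    prec = [r["val_macro_precision"] for r in epoch_records]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(epochs, prec, marker="o")
    ax.set_xlabel("iteration (epoch)")
    ax.set_ylabel("average precision")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
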