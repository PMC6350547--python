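"""Confusion-matrix convention and the five one-vs-rest metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollenspect.evaluation import (CLASSES, ConfusionMatrix, class_report,
                                    confusion_matrix, evaluate_predictions,
                                    macro_precision, write_report)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        labels = list(CLASSES) * 3
        cm = confusion_matrix(labels, labels)
        assert np.array_equal(cm.counts, np.diag([3, 3, 3, 3]))

    def test_columns_index_actual_class(self):
        actual = ["graves", "graves", "normal"]
        predicted = ["graves", "normal", "normal"]
        cm = confusion_matrix(predicted, actual)
        g, n = CLASSES.index("graves"), CLASSES.index("normal")
        assert cm.counts[g, g] == 1     # graves predicted graves
        assert cm.counts[n, g] == 1     # graves predicted normal
        assert cm.counts[n, n] == 1
        assert cm.counts.sum() == 3
        assert cm.actual_counts()[g] == 2  # column sum = actual count

    def test_empty_input_gives_zero_matrix(self):
        cm = confusion_matrix([], [])
        assert np.array_equal(cm.counts, np.zeros((4, 4), dtype=int))

    def test_length_mismatch_and_unknown_labels_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion_matrix(["graves"], ["graves", "normal"])
        with pytest.raises(ValueError, match="unknown label"):
            confusion_matrix(["cyst"], ["graves"])

    def test_matches_sklearn_transposed(self, rng):
        from sklearn.metrics import confusion_matrix as sk_cm
        p = rng.integers(0, 4, 200)
        a = rng.integers(0, 4, 200)
        cm = confusion_matrix(p, a)
        # scikit-learn uses rows=actual; ours uses columns=actual
        assert np.array_equal(cm.counts, sk_cm(a, p, labels=range(4)).T)


class TestClassReport:
    def test_perfect_one_vs_rest(self):
        cm = ConfusionMatrix(np.diag([50, 50, 50, 50]))
        r = class_report(cm, "graves")
        assert (r.recall, r.precision, r.accuracy, r.specificity, r.f1) == (1, 1, 1, 1, 1)

    def test_hand_computed_counts(self):
        # graves one-vs-rest: TP=95, FN=5, FP=2, TN=98
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 95
        counts[1, 0] = 5     # graves misclassified as hashimoto
        counts[0, 1] = 2     # hashimoto misclassified as graves
        counts[1, 1] = 98
        r = class_report(ConfusionMatrix(counts), "graves")
        assert (r.tp, r.fn, r.fp, r.tn) == (95, 5, 2, 98)
        assert r.recall == pytest.approx(0.95)
        assert r.precision == pytest.approx(95 / 97)
        assert r.accuracy == pytest.approx(0.965)
        assert r.specificity == pytest.approx(0.98)
        assert r.f1 == pytest.approx(190 / 197)

    def test_zero_denominator_is_undefined_not_zero(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[1, 1] = 10  # nothing is, or is predicted, graves
        r = class_report(ConfusionMatrix(counts), "graves")
        assert r.precision is None and r.recall is None
        assert r.specificity == 1.0

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            class_report(ConfusionMatrix(np.zeros((4, 4))), "cyst")

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_identities_and_sklearn_agreement(self, seed):
        """Eq-by-eq metric identities and agreement with scikit-learn on
        random prediction/label sets."""
        from sklearn.metrics import precision_score, recall_score

        r = np.random.default_rng(seed)
        n = int(r.integers(10, 200))
        pred = r.integers(0, 4, n)
        act = r.integers(0, 4, n)
        cm = confusion_matrix(pred, act)
        assert cm.total == n
        assert cm.micro_accuracy() == pytest.approx(np.mean(pred == act))
        for ci, c in enumerate(CLASSES):
            rep = class_report(cm, c)
            assert rep.tp + rep.tn + rep.fp + rep.fn == n
            assert rep.tp + rep.fn == cm.counts[:, ci].sum()
            assert rep.tp + rep.fp == cm.counts[ci, :].sum()
            if rep.precision is not None and rep.recall is not None \
                    and rep.precision + rep.recall > 0:
                harmonic = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
                assert rep.f1 == pytest.approx(harmonic, abs=1e-12)
            skp = precision_score(act, pred, labels=[ci], average="macro",
                                  zero_division=np.nan)
            skr = recall_score(act, pred, labels=[ci], average="macro",
                               zero_division=np.nan)
            assert (rep.precision is None) == bool(np.isnan(skp))
            if rep.precision is not None:
                assert rep.precision == pytest.approx(skp, abs=1e-12)
            if rep.recall is not None:
                assert rep.recall == pytest.approx(skr, abs=1e-12)


class TestMacroPrecision:
    def test_diagonal_is_one(self):
        val, n = macro_precision(ConfusionMatrix(np.diag([5, 5, 5, 5])))
        assert val == 1.0 and n == 4

    def test_mean_of_per_class_precisions(self):
        # columns actual, rows predicted; craft precisions 0.9/1.0/0.8/0.7
        counts = np.array([
            [9, 1, 0, 0],
            [0, 10, 0, 0],
            [1, 0, 8, 1],
            [2, 0, 1, 7],
        ])
        val, n = macro_precision(ConfusionMatrix(counts))
        assert n == 4
        assert val == pytest.approx(np.mean([0.9, 1.0, 0.8, 0.7]))

    def test_random_predictions_near_chance(self):
        rng = np.random.default_rng(6)
        act = np.repeat(np.arange(4), 600)
        pred = rng.integers(0, 4, act.size)
        val, _ = macro_precision(confusion_matrix(pred, act))
        assert val == pytest.approx(0.25, abs=0.03)

    def test_all_undefined_flagged(self):
        val, n = macro_precision(ConfusionMatrix(np.zeros((4, 4))))
        assert np.isnan(val) and n == 0


class TestReports:
    def test_write_report_layout_and_determinism(self, tmp_path):
        rng = np.random.default_rng(0)
        pred, act = rng.integers(0, 4, 100), rng.integers(0, 4, 100)
        result = evaluate_predictions(pred, act)
        j1, c1 = write_report(result, tmp_path / "a")
        j2, c2 = write_report(result, tmp_path / "b")
        assert j1.read_bytes() == j2.read_bytes()
        assert c1.read_bytes() == c2.read_bytes()
        lines = c1.read_text().strip().splitlines()
        assert lines[0] == "Metric," + ",".join(CLASSES)
        assert [l.split(",")[0] for l in lines[1:]] == [
            "Recall", "Precision", "Accuracy", "Specificity", "F1 score"]

    def test_perfect_model_reports_all_100(self, tmp_path):
        labels = list(range(4)) * 10
        result = evaluate_predictions(labels, labels)
        _, csv_path = write_report(result, tmp_path)
        for line in csv_path.read_text().strip().splitlines()[1:]:
            assert line.split(",")[1:] == ["100.00"] * 4

    def test_report_totals_conserved(self):
        rng = np.random.default_rng(1)
        pred, act = rng.integers(0, 4, 123), rng.integers(0, 4, 123)
        result = evaluate_predictions(pred, act)
        assert result.cm.total == 123
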