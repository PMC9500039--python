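"""Metric correctness against independent oracles.

The multiclass MCC is checked against a brute-force oracle that expands a
confusion matrix into per-record one-hot indicator matrices and computes
the Pearson correlation between them directly; AUC is checked against an
all-pairs concordance count. scikit-learn provides a second, independent
cross-check for both.
"""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from octsplit import (ConfusionMatrix, aggregate_reports, confusion_matrix, mcc,
                      per_class_metrics, roc_auc)


def mcc_indicator_oracle(counts: np.ndarray) -> float:
    """Pearson correlation between one-hot true/pred indicator matrices."""
    k = counts.shape[0]
    true_rows, pred_rows = [], []
    for i in range(k):
        for j in range(k):
            for _ in range(int(counts[i, j])):
                true_rows.append(np.eye(k)[i])
                pred_rows.append(np.eye(k)[j])
    x = np.array(true_rows)
    y = np.array(pred_rows)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    num = (xc * yc).sum()
    den = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    return float(num / den) if den > 0 else 0.0


def auc_concordance_oracle(scores, positives) -> float:
    """Concordant-pair fraction with half-credit for tied scores."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    total = concordant = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            if sp > sn:
                concordant += 1
            elif sp == sn:
                concordant += 0.5
    return concordant / total


class TestConfusionMatrix:
    def test_hand_enumeration(self):
        cm = confusion_matrix(["a", "a", "b", "b"], ["a", "b", "b", "b"],
                              ["a", "b"])
        assert cm.counts.tolist() == [[1, 1], [0, 2]]

    def test_perfect_predictions_are_diagonal(self):
        labels = ["a"] * 3 + ["b"] * 5
        cm = confusion_matrix(labels, labels, ["a", "b"])
        assert cm.counts.tolist() == [[3, 0], [0, 5]]

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            confusion_matrix([], [], ["a", "b"])

    def test_label_outside_class_set_raises(self):
        with pytest.raises(ValueError):
            confusion_matrix(["a"], ["z"], ["a", "b"])


class TestMCC:
    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_perfect_agreement_is_one(self, k):
        cm = ConfusionMatrix(np.diag(np.arange(1, k + 1)),
                             [str(i) for i in range(k)])
        assert mcc(cm) == pytest.approx(1.0)

    def test_single_predicted_class_is_zero(self):
        cm = ConfusionMatrix(np.array([[5, 0], [7, 0]]), ["a", "b"])
        assert mcc(cm) == 0.0

    def test_three_class_matrix_matches_indicator_oracle(self):
        counts = np.array([[5, 1, 0], [2, 3, 1], [0, 2, 6]])
        cm = ConfusionMatrix(counts, ["a", "b", "c"])
        assert mcc(cm) == pytest.approx(mcc_indicator_oracle(counts), abs=1e-12)

    def test_matches_oracle_on_1000_random_matrices(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            k = int(rng.integers(2, 5))
            counts = rng.integers(0, 50, size=(k, k))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(counts, [str(i) for i in range(k)])
            assert mcc(cm) == pytest.approx(mcc_indicator_oracle(counts),
                                            abs=1e-12)

    def test_binary_case_matches_classical_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tp, fn, fp, tn = rng.integers(1, 30, size=4)
            cm = ConfusionMatrix(np.array([[tp, fn], [fp, tn]]), ["p", "n"])
            classical = (tp * tn - fp * fn) / np.sqrt(
                float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
            assert mcc(cm) == pytest.approx(classical, abs=1e-12)

    def test_invariant_under_joint_class_permutation(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 20, size=(4, 4))
        perm = rng.permutation(4)
        a = ConfusionMatrix(counts, list("abcd"))
        b = ConfusionMatrix(counts[np.ix_(perm, perm)], list("abcd"))
        assert mcc(a) == pytest.approx(mcc(b), abs=1e-12)

    def test_matches_sklearn_on_random_label_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(k, 80))
            t = rng.integers(0, k, n)
            p = rng.integers(0, k, n)
            cm = confusion_matrix([str(v) for v in t], [str(v) for v in p],
                                  [str(i) for i in range(k)])
            assert mcc(cm) == pytest.approx(matthews_corrcoef(t, p), abs=1e-12)


class TestPerClassMetrics:
    def test_perfect_predictions_give_ones(self):
        cm = ConfusionMatrix(np.diag([3, 4, 5]), ["a", "b", "c"])
        rep = per_class_metrics(cm)
        for name in ("accuracy", "precision", "recall", "f1"):
            np.testing.assert_allclose(getattr(rep, name), 1.0)
        assert rep.accuracy_overall == 1.0

    def test_hand_enumerated_two_class_matrix(self):
        cm = ConfusionMatrix(np.array([[1, 1], [0, 2]]), ["a", "b"])
        rep = per_class_metrics(cm)
        np.testing.assert_allclose(rep.precision, [1.0, 2 / 3])
        np.testing.assert_allclose(rep.recall, [0.5, 1.0])
        np.testing.assert_allclose(rep.f1, [2 / 3, 4 / 5])
        assert rep.accuracy_overall == pytest.approx(0.75)

    def test_macro_recall_equals_overall_accuracy_when_balanced(self):
        rng = np.random.default_rng(3)
        counts = rng.multinomial(30, [1 / 3] * 3, size=3)  # equal row sums
        rep = per_class_metrics(ConfusionMatrix(counts, ["a", "b", "c"]))
        assert rep.macro["recall"] == pytest.approx(rep.accuracy_overall)

    def test_undefined_precision_is_zero(self):
        cm = ConfusionMatrix(np.array([[3, 0], [2, 0]]), ["a", "b"])
        rep = per_class_metrics(cm)
        assert rep.precision[1] == 0.0 and rep.f1[1] == 0.0


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        aucs, macro = roc_auc(["a", "a", "b", "b"], probs, ["a", "b"])
        np.testing.assert_allclose(aucs, 1.0)
        assert macro == 1.0

    def test_constant_scores_give_half(self):
        probs = np.full((6, 2), 0.5)
        aucs, _ = roc_auc(["a", "b", "a", "b", "a", "b"], probs, ["a", "b"])
        np.testing.assert_allclose(aucs, 0.5)

    def test_single_inversion_matches_all_pairs_oracle(self):
        scores = [0.9, 0.7, 0.4, 0.8, 0.3, 0.1]
        truth = ["a", "a", "a", "b", "b", "b"]
        probs = np.column_stack([scores, 1 - np.array(scores)])
        aucs, _ = roc_auc(truth, probs, ["a", "b"])
        expected = auc_concordance_oracle(scores, [t == "a" for t in truth])
        assert aucs[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_oracle_and_sklearn_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 2)  # rounded => ties occur
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                truth[0] = 1 - truth[0]
            probs = np.column_stack([1 - scores, scores])
            aucs, _ = roc_auc([str(v) for v in truth], probs, ["0", "1"])
            oracle = auc_concordance_oracle(scores, truth == 1)
            assert aucs[1] == pytest.approx(oracle, abs=1e-12)
            assert aucs[1] == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    def test_absent_class_excluded_from_macro_with_warning(self):
        probs = np.full((4, 3), 1 / 3)
        with pytest.warns(UserWarning, match="absent"):
            aucs, macro = roc_auc(["a", "a", "b", "b"], probs, ["a", "b", "c"])
        assert np.isnan(aucs[2])
        assert macro == pytest.approx(0.5)


class TestAggregateReports:
    @staticmethod
    def _report_with_mcc(value, rng):
        counts = rng.integers(1, 20, size=(2, 2))
        rep = per_class_metrics(ConfusionMatrix(counts, ["a", "b"]))
        rep.mcc = value
        return rep

    def test_single_report_has_zero_std_for_model_pooled_metrics(self):
        # class-resolved metrics still pool over classes, so their std can
        # be non-zero even for one model; the per-model metrics cannot
        rng = np.random.default_rng(0)
        agg = aggregate_reports([self._report_with_mcc(0.4, rng)])
        assert agg.loc["mcc", "std"] == 0.0
        assert agg.loc["accuracy_overall", "std"] == 0.0

    def test_two_point_formula(self):
        rng = np.random.default_rng(0)
        reports = [self._report_with_mcc(0.4, rng), self._report_with_mcc(0.6, rng)]
        agg = aggregate_reports(reports)
        assert agg.loc["mcc", "mean"] == pytest.approx(0.5)
        assert agg.loc["mcc", "std"] == pytest.approx(np.std([0.4, 0.6], ddof=1))

    def test_pooled_values_match_brute_force_recomputation(self):
        rng = np.random.default_rng(42)
        reports = [per_class_metrics(ConfusionMatrix(rng.integers(1, 20, (3, 3)),
                                                     ["a", "b", "c"]))
                   for _ in range(50)]
        agg = aggregate_reports(reports)
        pooled_f1 = np.concatenate([r.f1 for r in reports])
        assert agg.loc["f1", "mean"] == pytest.approx(pooled_f1.mean())
        assert agg.loc["f1", "std"] == pytest.approx(pooled_f1.std(ddof=1))
        mccs = np.array([r.mcc for r in reports])
        assert agg.loc["mcc", "mean"] == pytest.approx(mccs.mean())

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            aggregate_reports([])
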