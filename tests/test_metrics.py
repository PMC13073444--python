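"""Confusion-matrix metrics and bootstrap machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import f1_score, precision_score, recall_score

from msktriage.metrics import (accuracy, bootstrap_ci, confusion_matrix,
                               evaluate_predictions, macro_f1, macro_precision,
                               macro_recall, metric_accuracy, metric_macro_f1,
                               paired_bootstrap, per_class_prf, weighted_f1)

# external-evaluation-style confusion matrix used as a worked fixture
# (rows = true GREEN/YELLOW/RED, columns = predicted)
EXTERNAL_CM = np.array([[5, 4, 0], [0, 23, 1], [0, 2, 4]])


label_pairs = st.lists(
    st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=1, max_size=60
)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix([0, 1, 2], [0, 1, 2])
        assert np.array_equal(cm, np.eye(3, dtype=int))

    def test_all_yellow_called_red(self):
        cm = confusion_matrix([1] * 4, [2] * 4)
        assert cm[1, 2] == 4 and cm.sum() == 4

    @given(label_pairs)
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_tally(self, pairs):
        yt = [a for a, _ in pairs]
        yp = [b for _, b in pairs]
        cm = confusion_matrix(yt, yp)
        for i in range(3):
            for j in range(3):
                assert cm[i, j] == sum(
                    1 for a, b in pairs if a == i and b == j
                )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0])


class TestDerivedMetrics:
    def test_external_matrix_per_class_values(self):
        p, r, f = per_class_prf(EXTERNAL_CM, 0)
        assert (round(p, 2), round(r, 2), round(f, 2)) == (1.00, 0.56, 0.71)
        p, r, _ = per_class_prf(EXTERNAL_CM, 2)
        assert (round(p, 2), round(r, 2)) == (0.80, 0.67)

    def test_external_matrix_summary_values(self):
        assert round(100 * accuracy(EXTERNAL_CM), 1) == 82.1
        assert round(macro_precision(EXTERNAL_CM), 2) == 0.86
        assert round(macro_recall(EXTERNAL_CM), 2) == 0.73

    def test_empty_class_gets_zero_convention(self):
        cm = np.array([[3, 0, 0], [0, 2, 0], [0, 0, 0]])
        assert per_class_prf(cm, 2) == (0.0, 0.0, 0.0)

    def test_identity_matrix_is_perfect(self):
        cm = np.eye(3, dtype=int) * 5
        assert accuracy(cm) == macro_f1(cm) == weighted_f1(cm) == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.zeros((3, 3), dtype=int))

    @given(label_pairs)
    @settings(max_examples=150, derandomize=True)
    def test_agrees_with_sklearn_aggregates(self, pairs):
        """Independent cross-check of every aggregate against sklearn."""
        yt = [a for a, _ in pairs]
        yp = [b for _, b in pairs]
        cm = confusion_matrix(yt, yp)
        kw = dict(labels=[0, 1, 2], zero_division=0)
        assert macro_f1(cm) == pytest.approx(
            f1_score(yt, yp, average="macro", **kw))
        assert weighted_f1(cm) == pytest.approx(
            f1_score(yt, yp, average="weighted", **kw))
        assert macro_precision(cm) == pytest.approx(
            precision_score(yt, yp, average="macro", **kw))
        assert macro_recall(cm) == pytest.approx(
            recall_score(yt, yp, average="macro", **kw))

    @given(label_pairs)
    @settings(max_examples=150, derandomize=True)
    def test_accuracy_is_support_weighted_recall(self, pairs):
        yt = [a for a, _ in pairs]
        yp = [b for _, b in pairs]
        cm = confusion_matrix(yt, yp)
        support = cm.sum(axis=1)
        recalls = np.array([per_class_prf(cm, c)[1] for c in range(3)])
        assert accuracy(cm) == pytest.approx(
            float((recalls * support).sum() / support.sum()))

    @given(label_pairs, st.randoms(use_true_random=False))
    @settings(max_examples=100, derandomize=True)
    def test_permutation_invariance(self, pairs, rnd):
        yt = [a for a, _ in pairs]
        yp = [b for _, b in pairs]
        order = list(range(len(pairs)))
        rnd.shuffle(order)
        cm1 = confusion_matrix(yt, yp)
        cm2 = confusion_matrix([yt[i] for i in order], [yp[i] for i in order])
        assert np.array_equal(cm1, cm2)


class TestBootstrap:
    def test_degenerate_perfect_agreement(self):
        y = [0, 1, 2, 1, 1]
        point, low, high = bootstrap_ci(y, y, metric_accuracy, 200, seed=0)
        assert (point, low, high) == (1.0, 1.0, 1.0)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(0)
        yt = rng.integers(0, 3, 100)
        yp = np.where(rng.random(100) < 0.7, yt, (yt + 1) % 3)
        point, low, high = bootstrap_ci(yt, yp, metric_accuracy, 500, seed=1)
        assert low <= point <= high

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        yt = rng.integers(0, 3, 50)
        yp = rng.integers(0, 3, 50)
        a = bootstrap_ci(yt, yp, metric_macro_f1, 300, seed=9)
        b = bootstrap_ci(yt, yp, metric_macro_f1, 300, seed=9)
        assert a == b

    def test_interval_shrinks_with_sample_size(self):
        rng = np.random.default_rng(7)

        def width(n):
            yt = rng.integers(0, 3, n)
            yp = np.where(rng.random(n) < 0.8, yt, (yt + 1) % 3)
            _, low, high = bootstrap_ci(yt, yp, metric_accuracy, 500, seed=2)
            return high - low

        assert width(500) < width(50)

    def test_degenerate_resample_uses_zero_convention(self):
        # a single-class sample: macro-F1 resamples hit 0/0 cases but
        # must never be discarded
        yt = [2, 2, 2]
        yp = [2, 2, 1]
        point, low, high = bootstrap_ci(yt, yp, metric_macro_f1, 100, seed=0)
        assert np.isfinite([point, low, high]).all()

    def test_rejects_empty_or_mismatched(self):
        with pytest.raises(ValueError):
            bootstrap_ci([], [], metric_accuracy, 10, 0)
        with pytest.raises(ValueError):
            bootstrap_ci([0, 1], [0], metric_accuracy, 10, 0)


class TestPairedBootstrap:
    def test_identical_models_center_on_zero(self):
        rng = np.random.default_rng(0)
        yt = rng.integers(0, 3, 80)
        yp = rng.integers(0, 3, 80)
        delta, low, high, p_like = paired_bootstrap(
            yt, yp, yp, metric_accuracy, 300, seed=0
        )
        assert delta == 0 and low <= 0 <= high
        assert p_like == 1.0  # all resample deltas are exactly 0 (<= 0)

    def test_perfect_vs_always_wrong(self):
        yt = np.array([0, 1, 2] * 10)
        wrong = (yt + 1) % 3
        delta, low, high, p_like = paired_bootstrap(
            yt, yt, wrong, metric_accuracy, 300, seed=0
        )
        assert delta == 1.0 and low > 0 and p_like == 0.0

    def test_known_accuracy_gap_recovered(self):
        """Simulation oracle: models with a designed 0.1 accuracy gap."""
        rng = np.random.default_rng(42)
        n = 500
        yt = rng.integers(0, 3, n)
        a = np.where(rng.random(n) < 0.9, yt, (yt + 1) % 3)
        b = np.where(rng.random(n) < 0.8, yt, (yt + 1) % 3)
        true_gap = metric_accuracy(yt, a) - metric_accuracy(yt, b)
        delta, low, high, _ = paired_bootstrap(
            yt, a, b, metric_accuracy, 500, seed=1
        )
        assert delta == pytest.approx(true_gap)
        assert abs(delta - 0.1) < 0.05  # within Monte-Carlo error

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_bootstrap([0, 1], [0, 1], [0], metric_accuracy, 10, 0)


class TestEvaluationReport:
    def test_report_fields_consistent(self):
        yt = [0, 0, 1, 1, 1, 2, 2]
        yp = [0, 1, 1, 1, 2, 2, 2]
        rep = evaluate_predictions(yt, yp, n_resamples=100, seed=0)
        assert rep.accuracy == pytest.approx(5 / 7)
        assert rep.macro_f1 == pytest.approx(
            np.mean([row["f1"] for row in rep.per_class]))
        assert set(rep.ci) == {"accuracy", "macro_f1"}
        assert rep.ci["accuracy"]["low"] <= rep.accuracy

    def test_json_is_deterministic(self):
        yt, yp = [0, 1, 2, 1], [0, 1, 2, 2]
        r1 = evaluate_predictions(yt, yp, 50, 3).to_json()
        r2 = evaluate_predictions(yt, yp, 50, 3).to_json()
        assert r1 == r2

    def test_table_shows_percent_accuracy(self):
        rep = evaluate_predictions([0, 1, 2], [0, 1, 2])
        assert "Accuracy: 100.0%" in rep.format_table()
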