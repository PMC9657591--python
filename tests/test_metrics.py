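"""Per-class metrics: confusion rates, one-vs-rest AUC, ANOVA, tables."""

import math

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from mol2mat import anova_oneway, auc_ovr, class_metrics_table, confusion_metrics


def brute_force_auc(scores, labels):
    """Pairwise oracle: fraction of positive-negative pairs ranked correctly,
    ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_count_oracle_case(self):
        # TP=9, FN=1, TN=95, FP=5
        truth = ["+"] * 10 + ["-"] * 100
        pred = ["+"] * 9 + ["-"] + ["+"] * 5 + ["-"] * 95
        assert confusion_metrics(pred, truth, "+") == (0.9, 0.95)

    def test_perfect_predictions(self):
        y = ["a", "b", "a", "c"]
        assert confusion_metrics(y, y, "a") == (1.0, 1.0)

    def test_all_negative_predictions(self):
        sens, spec = confusion_metrics(["n"] * 4, ["p", "p", "n", "n"], "p")
        assert sens == 0.0 and spec == 1.0

    def test_absent_class_is_nan_not_zero(self):
        sens, _ = confusion_metrics(["a", "b"], ["a", "b"], "zzz")
        assert math.isnan(sens)


class TestAucOvr:
    def test_perfect_ranking(self):
        assert auc_ovr([0.9, 0.8, 0.3, 0.2], ["+", "+", "-", "-"], "+") == 1.0

    def test_all_ties(self):
        assert auc_ovr([0.5] * 4, ["+", "+", "-", "-"], "+") == 0.5

    def test_hand_computed(self):
        assert auc_ovr([0.9, 0.4, 0.6, 0.2], ["+", "+", "-", "-"], "+") == 0.75

    def test_degenerate_class_is_nan(self):
        assert math.isnan(auc_ovr([0.1, 0.2], ["+", "+"], "+"))

    def test_matches_brute_force_and_sklearn_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)  # force ties
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            truth = np.where(labels, "+", "-")
            ours = auc_ovr(scores, truth, "+")
            assert ours == pytest.approx(brute_force_auc(scores, labels), abs=1e-9)
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)


class TestAnova:
    def test_identical_groups(self):
        assert anova_oneway([[1, 2, 3], [1, 2, 3]]) == (0.0, 1.0)

    def test_complete_separation_flagged_infinite(self):
        f, p = anova_oneway([[0, 0, 0], [1, 1, 1]])
        assert math.isinf(f) and p == 0.0

    def test_hand_computed_sums_of_squares(self):
        f, p = anova_oneway([[3, 4, 5], [6, 7, 8]])
        assert f == pytest.approx(13.5, abs=1e-12)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(200):
            groups = [rng.normal(size=int(rng.integers(3, 12))) for _ in range(int(rng.integers(2, 5)))]
            f, p = anova_oneway(groups)
            ref = stats.f_oneway(*groups)
            assert f == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestClassMetricsTable:
    def test_oracle_model_scores_all_ones(self):
        truth = np.array(["a", "b", "c"] * 5)
        classes = ["a", "b", "c"]
        scores = np.eye(3)[[classes.index(t) for t in truth]]
        table = class_metrics_table(truth, truth, scores, classes)
        cls_rows = table.loc[classes]
        assert (cls_rows == 1.0).all().all()
        assert (table.loc["mean"] == 1.0).all()

    def test_uniform_model_auc_half(self):
        truth = np.array(["a", "b"] * 10)
        scores = np.full((20, 2), 0.5)
        pred = np.array(["a"] * 20)
        table = class_metrics_table(truth, pred, scores, ["a", "b"])
        assert table.loc["a", "auc"] == 0.5 and table.loc["b", "auc"] == 0.5

    def test_mean_row_is_arithmetic_mean_of_class_rows(self, rng):
        classes = ["a", "b", "c", "d"]
        truth = rng.choice(classes, size=80)
        scores = rng.random((80, 4))
        scores /= scores.sum(axis=1, keepdims=True)
        pred = np.array(classes)[scores.argmax(axis=1)]
        table = class_metrics_table(truth, pred, scores, classes)
        assert np.allclose(
            table.loc["mean"], table.loc[classes].mean(), atol=1e-9, equal_nan=True
        )

    def test_permuting_molecules_leaves_metrics_unchanged(self, rng):
        classes = ["a", "b", "c"]
        truth = rng.choice(classes, size=60)
        scores = rng.random((60, 3))
        pred = np.array(classes)[scores.argmax(axis=1)]
        perm = rng.permutation(60)
        t1 = class_metrics_table(truth, pred, scores, classes)
        t2 = class_metrics_table(truth[perm], pred[perm], scores[perm], classes)
        assert np.allclose(t1.to_numpy(), t2.to_numpy(), equal_nan=True)

    def test_empty_test_class_excluded_from_mean(self):
        truth = np.array(["a", "b"] * 4)
        scores = np.column_stack([np.linspace(1, 0, 8), np.linspace(0, 1, 8), np.zeros(8)])
        pred = np.array(["a", "b"] * 4)
        table = class_metrics_table(truth, pred, scores, ["a", "b", "ghost"])
        assert math.isnan(table.loc["ghost", "sensitivity"])
        assert not math.isnan(table.loc["mean", "sensitivity"])


def test_external_prediction_table_round_trip(tmp_path):
    import pandas as pd

    from mol2mat.metrics import evaluate_prediction_table, read_prediction_table

    frame = pd.DataFrame(
        {
            "molecule_id": ["m1", "m2", "m3", "m4"],
            "predicted_class": ["a", "a", "b", "b"],
            "score_a": [0.9, 0.8, 0.3, 0.1],
            "score_b": [0.1, 0.2, 0.7, 0.9],
        }
    )
    path = tmp_path / "preds.csv"
    frame.to_csv(path, index=False)
    table = evaluate_prediction_table(read_prediction_table(path), ["a", "a", "b", "b"])
    assert (table.loc[["a", "b"]] == 1.0).all().all()
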