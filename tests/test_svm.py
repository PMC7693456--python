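"""LOOCV linear SVM: metrics, permutation significance, weights, top-k."""

import numpy as np
import pytest

from snconn import (
    aggregate_weights,
    loocv_svm,
    metrics_from_confusion,
    permutation_significance,
    top_fraction_edges,
)
from snconn.datasets import DISCRIMINATIVE_WEIGHTS, SIGNIFICANT_EDGE_T


def _separable(rng, n_per_class=10, n_feat=4, gap=6.0):
    x = np.vstack(
        [
            rng.normal(0, 1, (n_per_class, n_feat)) + gap,
            rng.normal(0, 1, (n_per_class, n_feat)) - gap,
        ]
    )
    y = np.array([1] * n_per_class + [-1] * n_per_class)
    return x, y


def auc_pair_count_oracle(decision, labels):
    """Mann-Whitney pair-counting AUC: P(score_pos > score_neg) + ties/2."""
    pos = decision[labels == 1]
    neg = decision[labels == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestLoocvSvm:
    def test_wide_margin_perfect_classification(self, rng):
        x, y = _separable(rng)
        res, w = loocv_svm(x, y)
        assert res.metrics["accuracy"] == 1.0
        assert res.metrics["auc"] == 1.0
        assert w.shape == (20, 4)

    def test_confusion_identities_always_hold(self, rng):
        x = rng.normal(0, 1, (18, 3))
        x[:9] += 0.8
        y = np.array([1] * 9 + [-1] * 9)
        res, _ = loocv_svm(x, y)
        tp, fn, tn, fp = res.confusion
        assert tp + fn == 9 and tn + fp == 9
        m = metrics_from_confusion(tp, fn, tn, fp)
        for k, v in m.items():
            assert res.metrics[k] == pytest.approx(v, nan_ok=True)

    def test_auc_matches_pair_count_oracle(self, rng):
        x = rng.normal(0, 1, (16, 3))
        x[:8] += 0.5
        y = np.array([1] * 8 + [-1] * 8)
        res, _ = loocv_svm(x, y)
        assert res.metrics["auc"] == pytest.approx(
            auc_pair_count_oracle(res.decision_values, y), abs=1e-12
        )

    def test_predictions_invariant_to_subject_order(self, rng):
        x = rng.normal(0, 1, (14, 3))
        x[:7] += 1.0
        y = np.array([1] * 7 + [-1] * 7)
        res, _ = loocv_svm(x, y)
        perm = np.random.default_rng(3).permutation(14)
        res_p, _ = loocv_svm(x[perm], y[perm])
        assert np.array_equal(res_p.predictions, res.predictions[perm])
        # the SMO solver's stopping point shifts slightly with row order
        assert res_p.decision_values == pytest.approx(
            res.decision_values[perm], abs=0.02
        )
        assert res_p.metrics["accuracy"] == res.metrics["accuracy"]

    def test_permuted_labels_yield_chance_accuracy(self, rng):
        # moderately informative features, labels shuffled: LOOCV accuracy
        # averages to chance (a mild pessimistic bias is inherent to
        # balanced-label LOOCV, so the band is +-5 points)
        x = rng.normal(0, 1, (40, 3))
        x[:20] += 1.0
        y = np.array([1] * 20 + [-1] * 20)
        accs = []
        for _ in range(50):
            acc = loocv_svm(x, rng.permutation(y))[0].metrics["accuracy"]
            accs.append(acc)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_single_class_refused(self, rng):
        x = rng.normal(0, 1, (6, 2))
        with pytest.raises(ValueError):
            loocv_svm(x, np.ones(6, dtype=int))


class TestPermutationSignificance:
    def test_strong_signal_hits_permutation_floor(self, rng):
        x, y = _separable(rng, n_per_class=6)
        res = permutation_significance(x, y, n_permutations=60, seed=0)
        assert res.permutation_p["accuracy"] == pytest.approx(1 / 61)

    def test_null_features_rarely_significant(self, rng):
        # seeded null calibration: replicate runs on pure-noise features
        rejections = 0
        n_rep = 12
        for rep in range(n_rep):
            g = np.random.default_rng(500 + rep)
            x = g.normal(0, 1, (12, 3))
            y = np.array([1] * 6 + [-1] * 6)
            res = permutation_significance(x, y, n_permutations=60, seed=rep)
            rejections += res.permutation_p["accuracy"] <= 0.05
        assert rejections <= max(2, int(0.25 * n_rep))

    def test_below_null_median_gives_large_p(self, rng):
        # adversarial label arrangement (alternating along a line) defeats
        # LOOCV entirely, so the observed accuracy sits below the null
        # median and its permutation p exceeds 0.5
        x = np.arange(12, dtype=float)[:, None] + rng.normal(0, 0.1, (12, 1))
        y = np.array([1, -1] * 6)
        assert loocv_svm(x, y)[0].metrics["accuracy"] < 0.5
        res = permutation_significance(x, y, n_permutations=60, seed=1)
        assert res.permutation_p["accuracy"] > 0.5


class TestAggregateWeights:
    def test_reference_weight_column_statistics(self):
        # single-fold aggregation over the 28 published absolute weights
        w = DISCRIMINATIVE_WEIGHTS["weight"].to_numpy()[None, :]
        labels = [
            f"{a}--{b}"
            for a, b in zip(
                DISCRIMINATIVE_WEIGHTS["node_a"], DISCRIMINATIVE_WEIGHTS["node_b"]
            )
        ]
        table, threshold = aggregate_weights(w, labels)
        col = table["mean_abs_weight"]
        assert col.mean() == pytest.approx(0.156, abs=5e-4)
        assert col.std(ddof=1) == pytest.approx(0.106, abs=5e-4)
        selected = set(table.loc[table["selected"], "mean_abs_weight"].round(3))
        assert selected == {0.461, 0.357, 0.286, 0.281, 0.264}

    def test_degenerate_equal_weights_select_nothing(self):
        w = np.full((3, 4), 0.2)
        table, threshold = aggregate_weights(w)
        assert threshold == pytest.approx(0.2)
        assert not table["selected"].any()  # strict inequality

    def test_absolute_vs_signed_averaging(self):
        w = np.array([[1.0, 0.5], [-1.0, 0.5]])
        table, _ = aggregate_weights(w, ["e0", "e1"])
        row = table.set_index("edge").loc["e0"]
        assert row["mean_abs_weight"] == 1.0
        assert row["mean_signed_weight"] == 0.0

    def test_ranks_are_a_permutation(self, rng):
        w = rng.normal(0, 1, (5, 7))
        table, _ = aggregate_weights(w)
        assert sorted(table["rank"]) == list(range(1, 8))


class TestTopFractionEdges:
    def test_reference_edge_table_top_20pct(self):
        stats = [
            (f"{a}--{b}", t)
            for a, b, t in SIGNIFICANT_EDGE_T.itertuples(index=False)
        ]
        top = top_fraction_edges(stats, fraction=0.20)
        assert len(top) == 5
        assert sorted(t for _, t in top) == [4.15, 4.19, 4.22, 4.55, 4.59]

    def test_fraction_one_returns_all(self):
        stats = [("a", 1.0), ("b", 2.0)]
        assert len(top_fraction_edges(stats, fraction=1.0)) == 2

    def test_floor_with_minimum_one(self):
        stats = [("a", 1.0), ("b", 2.0), ("c", 3.0), ("d", 4.0)]
        top = top_fraction_edges(stats, fraction=0.20)
        assert len(top) == 1 and top[0][0] == "d"

    def test_empty_input_empty_output(self):
        assert top_fraction_edges([], fraction=0.2) == []

    def test_deterministic_tie_break(self):
        stats = [("b", 2.0), ("a", 2.0), ("c", 1.0)]
        top = top_fraction_edges(stats, fraction=0.34)
        assert top[0][0] == "a"
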