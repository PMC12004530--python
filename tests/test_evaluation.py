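"""Metric oracles (brute-force reimplementations), identity stratification,
and ligand clustering."""

import numpy as np
import pytest

from plikit.evaluation import (
    EvaluationError, classification_metrics, cluster_ligands,
    identity_stratified_eval, regression_metrics,
)
from plikit.identity import max_identity_to_train, percent_identity
from plikit.model import N_TASKS, TASKS


# -- brute-force oracles (independent of the implementation under test) ------

def naive_r2(pred, truth):
    ss_res = np.sum((truth - pred) ** 2)
    ss_tot = np.sum((truth - truth.mean()) ** 2)
    return 1 - ss_res / ss_tot


def naive_roc_auc(scores, labels):
    """O(n^2) pair counting with half-credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def naive_pr_auc(scores, labels):
    """Step-wise sum over recall increments at each threshold."""
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / y.sum()
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        m = regression_metrics(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert m["r2"] == pytest.approx(1.0)
        assert m["rmsd"] == 0.0
        assert m["p1mag"] == 100.0

    def test_mean_predictor_gives_zero_r2(self):
        truth = np.array([1.0, 2.0, 6.0])
        m = regression_metrics(np.full(3, truth.mean()), truth)
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_example(self):
        preds = np.array([0.0, 2.0, -1.0])
        truths = np.array([0.5, 3.5, -1.5])
        m = regression_metrics(preds, truths)
        assert m["p1mag"] == pytest.approx(100 * 2 / 3)
        assert m["rmsd"] == pytest.approx(np.sqrt((0.25 + 2.25 + 0.25) / 3))

    def test_constant_truths_warn_and_report_missing_r2(self):
        with pytest.warns(UserWarning, match="constant"):
            m = regression_metrics(np.array([1.0, 2.0]), np.array([3.0, 3.0]))
        assert m["r2"] is None
        assert m["rmsd"] is not None

    def test_p1mag_invariant_to_common_shift(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=50)
        t = rng.normal(size=50)
        m1 = regression_metrics(p, t)
        m2 = regression_metrics(p + 7.3, t + 7.3)
        assert m1["p1mag"] == pytest.approx(m2["p1mag"])

    def test_agreement_with_naive_r2_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            t = rng.normal(size=n) * rng.uniform(0.5, 3)
            p = t + rng.normal(size=n)
            m = regression_metrics(p, t)
            assert m["r2"] == pytest.approx(naive_r2(p, t), rel=1e-9)
            assert m["rmsd"] == pytest.approx(np.sqrt(np.mean((p - t) ** 2)), rel=1e-9)


class TestClassificationMetrics:
    def test_perfect_separation(self):
        m = classification_metrics(np.array([0.9, 0.8, 0.2, 0.1]),
                                   np.array([1, 1, 0, 0]))
        assert m["roc_auc"] == pytest.approx(1.0)
        assert m["pr_auc"] == pytest.approx(1.0)
        assert m["precision"] == pytest.approx(1.0)
        assert m["recall"] == pytest.approx(1.0)

    def test_four_point_pair_enumeration(self):
        # pairs (0.9 vs 0.8-neg? no): labels 1,0,1,0 -> pos {0.9, 0.4}, neg {0.8, 0.2}
        # wins: 0.9>0.8, 0.9>0.2, 0.4<0.8, 0.4>0.2 -> 3/4
        m = classification_metrics(np.array([0.9, 0.8, 0.4, 0.2]),
                                   np.array([1, 0, 1, 0]))
        assert m["roc_auc"] == pytest.approx(0.75)

    def test_single_class_rejected_naming_missing_class(self):
        with pytest.raises(EvaluationError, match="positive"):
            classification_metrics(np.array([0.1, 0.2]), np.array([0, 0]))
        with pytest.raises(EvaluationError, match="negative"):
            classification_metrics(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_random_scores_near_null_values(self):
        rng = np.random.default_rng(2)
        n = 10_000
        prevalence = 0.1
        labels = (rng.random(n) < prevalence).astype(int)
        scores = rng.random(n)
        m = classification_metrics(scores, labels)
        n_pos = labels.sum()
        n_neg = n - n_pos
        # SD of the Mann-Whitney AUC under the null
        sd = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(m["roc_auc"] - 0.5) < 3 * sd
        assert abs(m["pr_auc"] - labels.mean()) < 0.03

    def test_agreement_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(8, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.random(n)
            m = classification_metrics(scores, labels)
            assert m["roc_auc"] == pytest.approx(naive_roc_auc(scores, labels), abs=1e-9)
            assert m["pr_auc"] == pytest.approx(naive_pr_auc(scores, labels), abs=1e-9)


class TestIdentity:
    def test_identical_sequences_score_100(self):
        assert percent_identity("MKVLA", "MKVLA") == 100.0

    def test_three_quarters_match(self):
        assert percent_identity("AAAA", "AAAT") == 75.0

    def test_max_identity_over_training_set(self):
        assert max_identity_to_train("AAAA", ["CCCC", "AAAT", "GGGG"]) == 75.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("", "AAA")


class TestIdentityStratifiedEval:
    def _toy(self):
        rng = np.random.default_rng(4)
        n = 40
        truths = rng.normal(size=(n, N_TASKS))
        preds = truths + rng.normal(0, 0.5, size=(n, N_TASKS))
        avail = np.ones((n, N_TASKS), dtype=bool)
        idents = rng.uniform(0, 100, size=n)
        return preds, truths, avail, idents

    def test_bins_are_nested_and_identical_sequences_excluded(self):
        preds, truths, avail, idents = self._toy()
        idents[0] = 100.0  # an exact train duplicate never enters any bin
        report = identity_stratified_eval(preds, truths, avail, idents)
        counts = [report[f"<={b}"]["n_records"] for b in (40, 60, 80, 99)]
        assert counts == sorted(counts)
        assert counts[-1] == int(np.sum(idents <= 99))

    def test_missing_annotation_rejected(self):
        preds, truths, avail, idents = self._toy()
        idents[3] = np.nan
        with pytest.raises(EvaluationError, match="identity"):
            identity_stratified_eval(preds, truths, avail, idents)


class TestClusterLigands:
    def test_two_separated_blobs_give_two_components(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.05, size=(12, 8)) + np.array([1.0] + [0.0] * 7)
        b = rng.normal(0, 0.05, size=(12, 8)) + np.array([0.0] * 7 + [1.0])
        labels = cluster_ligands(np.vstack([a, b]), k=3)
        assert len(set(labels[:12])) == 1
        assert len(set(labels[12:])) == 1
        assert labels[0] != labels[12]
        # brute-force check: intra-blob cosine exceeds inter-blob cosine
        X = np.vstack([a, b])
        Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
        sim = Xn @ Xn.T
        assert sim[:12, :12].min() > sim[:12, 12:].max()

    def test_identical_embeddings_form_one_component(self):
        X = np.tile(np.array([1.0, 2.0, 3.0]), (8, 1))
        labels = cluster_ligands(X, k=3)
        assert len(set(labels)) == 1

    def test_zero_norm_embedding_rejected(self):
        X = np.zeros((6, 4))
        with pytest.raises(EvaluationError, match="zero-norm"):
            cluster_ligands(X, k=2)

    def test_too_few_ligands_rejected(self):
        with pytest.raises(EvaluationError, match="k\\+1"):
            cluster_ligands(np.eye(3), k=3)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 5))
        np.testing.assert_array_equal(cluster_ligands(X, 4), cluster_ligands(X, 4))
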