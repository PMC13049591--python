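"""Metric machinery: confusion tallies, one-vs-rest metrics vs independent
oracles, rank-statistic macro ROC-AUC, and the stratified CV runner."""

import numpy as np
import pytest
from itertools import product

from seizurekit.eval import (
    ConfusionMatrix,
    confusion,
    iter_cv_folds,
    macro_roc_auc,
    mean_and_population_sd,
    metrics_from_confusion,
    run_stratified_cv,
)
from seizurekit.models import ModelSpec
from seizurekit.normalize import fit_stats
from seizurekit.synth import SynthConfig, generate_epoch_set
from seizurekit.preprocess import assemble_dataset


def test_confusion_matches_brute_force_tally():
    rng = np.random.default_rng(0)
    yt = rng.integers(0, 4, 500)
    yp = rng.integers(0, 4, 500)
    cm = confusion(yt, yp, 4)
    for i, j in product(range(4), range(4)):
        assert cm.counts[i, j] == int(np.sum((yt == i) & (yp == j)))
    assert cm.total == 500


def test_confusion_perfect_prediction_is_diagonal():
    y = np.array([0, 1, 2, 2, 1, 0])
    cm = confusion(y, y, 3)
    assert np.array_equal(cm.counts, np.diag([2, 2, 2]))


def test_confusion_validation():
    with pytest.raises(ValueError):
        ConfusionMatrix(np.array([[1, 2, 3]]))
    with pytest.raises(ValueError):
        ConfusionMatrix(np.array([[1, -1], [0, 2]]))


def test_identity_confusion_gives_perfect_metrics():
    rep = metrics_from_confusion(ConfusionMatrix(np.diag([5, 7, 3])))
    assert rep.accuracy == 1.0
    for m in rep.per_class.values():
        assert m["precision"] == m["recall"] == m["f1"] == 1.0


def test_metrics_match_per_sample_oracle_on_random_instances():
    """Counting TP/FP/FN per class directly over 1000 random label pairs
    reproduces the confusion-matrix route exactly."""
    rng = np.random.default_rng(1)
    for _ in range(5):
        k = int(rng.integers(2, 5))
        yt = rng.integers(0, k, 1000)
        yp = rng.integers(0, k, 1000)
        rep = metrics_from_confusion(confusion(yt, yp, k))
        for i in range(k):
            tp = np.sum((yt == i) & (yp == i))
            fp = np.sum((yt != i) & (yp == i))
            fn = np.sum((yt == i) & (yp != i))
            assert rep.per_class[i]["precision"] == pytest.approx(
                tp / (tp + fp) if tp + fp else 0.0
            )
            assert rep.per_class[i]["recall"] == pytest.approx(tp / (tp + fn))
        assert rep.accuracy == pytest.approx(np.mean(yt == yp))


def test_metrics_match_sklearn_report():
    from sklearn.metrics import classification_report

    rng = np.random.default_rng(2)
    yt = rng.integers(0, 3, 400)
    yp = rng.integers(0, 3, 400)
    rep = metrics_from_confusion(confusion(yt, yp, 3))
    sk = classification_report(yt, yp, output_dict=True, zero_division=0)
    for i in range(3):
        for ours, theirs in (("precision", "precision"), ("recall", "recall"), ("f1", "f1-score")):
            assert rep.per_class[i][ours] == pytest.approx(sk[str(i)][theirs])
    assert rep.macro_avg["f1"] == pytest.approx(sk["macro avg"]["f1-score"])
    assert rep.weighted_avg["precision"] == pytest.approx(sk["weighted avg"]["precision"])


def test_zero_predicted_class_warns_and_gets_zero_precision():
    cm = ConfusionMatrix(np.array([[5, 0], [3, 0]]))  # class 1 never predicted
    with pytest.warns(UserWarning, match="never predicted"):
        rep = metrics_from_confusion(cm)
    assert rep.per_class[1]["precision"] == 0.0


def test_empty_confusion_rejected():
    with pytest.raises(ValueError, match="empty"):
        metrics_from_confusion(ConfusionMatrix(np.zeros((2, 2), dtype=int)))


def test_macro_auc_trivial_cases():
    y = np.array([0, 0, 1, 1])
    assert macro_roc_auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
    assert macro_roc_auc(y, np.array([0.5, 0.5, 0.5, 0.5])) == 0.5
    probs = np.full((4, 2), 0.5)
    assert macro_roc_auc(y, probs) == 0.5  # ties contribute one half per class


def _pairwise_auc(y_bin, scores):
    """All-pairs oracle: P(score_pos > score_neg) + 0.5 P(equal)."""
    pos = scores[y_bin]
    neg = scores[~y_bin]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_macro_auc_matches_all_pairs_oracle():
    y = np.array([0, 1, 2, 0, 1, 2])
    rng = np.random.default_rng(3)
    probs = rng.random((6, 3))
    expected = np.mean([_pairwise_auc(y == k, probs[:, k]) for k in range(3)])
    assert macro_roc_auc(y, probs) == pytest.approx(expected, abs=1e-12)


def test_macro_auc_matches_sklearn_on_random_instances():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(4)
    y = rng.integers(0, 3, 120)
    probs = rng.random((120, 3))
    probs /= probs.sum(axis=1, keepdims=True)
    ours = macro_roc_auc(y, probs)
    theirs = roc_auc_score(y, probs, multi_class="ovr", average="macro")
    assert ours == pytest.approx(theirs, abs=1e-12)


def test_macro_auc_excludes_absent_class_with_warning():
    y = np.array([0, 0, 1, 1])
    probs = np.array([[0.8, 0.1, 0.1], [0.7, 0.2, 0.1], [0.2, 0.7, 0.1], [0.1, 0.8, 0.1]])
    with pytest.warns(UserWarning, match="class 2 absent"):
        auc = macro_roc_auc(y, probs)
    assert auc == 1.0  # mean over the two present classes only


def test_mean_and_population_sd_identical_values():
    mean, sd = mean_and_population_sd([0.9, 0.9, 0.9])
    assert mean == pytest.approx(0.9) and sd == 0.0


def test_cv_folds_partition_and_stratify():
    """Every sample lands in exactly one test fold and per-class counts
    across folds differ by at most one, for several seeds."""
    rng = np.random.default_rng(5)
    y = rng.integers(0, 3, 157)
    for seed in range(5):
        seen = np.zeros(len(y), dtype=int)
        for _, te in iter_cv_folds(y, k=5, seed=seed):
            seen[te] += 1
            for label in range(3):
                per_fold = np.sum(y[te] == label)
                total = np.sum(y == label)
                assert abs(per_fold - total / 5) <= 1
        assert (seen == 1).all()


def test_cv_runner_end_to_end_with_tree_model():
    cfg = SynthConfig(n_channels=3, sfreq=50.0, seed=8)
    es = generate_epoch_set(cfg, {0: 60, 2: 60})
    data = assemble_dataset([es], task="binary")
    spec = ModelSpec("XGBOOST", (3, 50), 2, {"n_estimators": 40})
    summary = run_stratified_cv(data, spec, k=3, seed=0)
    assert len(summary.fold_accuracy) == 3
    assert min(summary.fold_accuracy) <= summary.mean_accuracy <= max(summary.fold_accuracy)
    assert all(0.0 <= a <= 1.0 for a in summary.fold_roc_auc)
    # synthetic classes are easily separable even fold-wise
    assert summary.mean_accuracy > 0.9


def test_cv_fold_stats_ignore_held_out_data():
    """Per-fold normalization statistics depend only on the training folds:
    perturbing the held-out fold leaves them untouched."""
    cfg = SynthConfig(n_channels=2, sfreq=10.0, seed=9)
    es = generate_epoch_set(cfg, {0: 20, 1: 20})
    tr, te = next(iter_cv_folds(es.y, k=4, seed=0))
    stats_before = fit_stats(es.subset(tr))
    es.x[te] *= 1e3
    stats_after = fit_stats(es.subset(tr))
    assert stats_after.mu == stats_before.mu
    assert stats_after.sigma == stats_before.sigma


def test_cv_rejects_class_smaller_than_k():
    cfg = SynthConfig(n_channels=2, sfreq=10.0, seed=10)
    es = generate_epoch_set(cfg, {0: 20, 1: 3})
    with pytest.raises(ValueError, match="stratification"):
        run_stratified_cv(es, ModelSpec("XGBOOST", (2, 10), 2), k=5, seed=0)


def test_report_serialization(tmp_path):
    rep = metrics_from_confusion(ConfusionMatrix(np.array([[8, 2], [1, 9]])))
    rep.to_json(tmp_path / "report.json")
    text = rep.to_text()
    assert "precision" in text and "macro avg" in text
    cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]))
    cm.to_csv(tmp_path / "cm.csv")
    assert np.array_equal(np.loadtxt(tmp_path / "cm.csv", delimiter=","), cm.counts)
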