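"""Channel-importance aggregation and attribution backends: hand-computed
Shapley values, equivariance properties, and permutation importance."""

import numpy as np
import pytest
from itertools import chain, combinations

from seizurekit.explain import (
    AttributionSet,
    aggregate_channels,
    compute_attributions,
    permutation_channel_importance,
    tree_shapley_values,
    _tree_expected_value,
)
from seizurekit.models import ModelSpec, build_model, train_model
from seizurekit.normalize import apply_stats, fit_stats
from seizurekit.synth import SynthConfig, generate_epoch_set
from seizurekit.types import EpochSet


def test_aggregate_hand_example():
    # C=2, T=2, one sample, one class, channel-major values [1, -1, 0, 0]
    attr = AttributionSet.from_flat([np.array([[1.0, -1.0, 0.0, 0.0]])], 2, 2)
    ci = aggregate_channels(attr)
    assert ci.scores.tolist() == [1.0, 0.0]
    assert ci.ranking[0] == 0


def test_aggregate_all_zero_keeps_index_order():
    attr = AttributionSet([np.zeros((3, 4, 5))])
    ci = aggregate_channels(attr)
    assert (ci.scores == 0).all()
    assert ci.ranking.tolist() == [0, 1, 2, 3]


def test_aggregate_layout_mismatch_rejected():
    with pytest.raises(ValueError, match="feature count"):
        AttributionSet.from_flat([np.ones((2, 7))], 2, 4)


def test_aggregate_permutation_equivariant_in_channels():
    rng = np.random.default_rng(0)
    arr = rng.standard_normal((4, 5, 6))
    perm = rng.permutation(5)
    base = aggregate_channels(AttributionSet([arr]))
    permuted = aggregate_channels(AttributionSet([arr[:, perm, :]]))
    assert np.allclose(permuted.scores, base.scores[perm])


def test_aggregate_scale_equivariant():
    rng = np.random.default_rng(1)
    arr = rng.standard_normal((3, 4, 5))
    base = aggregate_channels(AttributionSet([arr]))
    scaled = aggregate_channels(AttributionSet([3.5 * arr]))
    assert np.allclose(scaled.scores, 3.5 * base.scores)
    assert np.array_equal(scaled.ranking, base.ranking)


def test_depth_one_tree_matches_hand_shapley():
    """For a single depth-1 tree splitting on feature 0, the only nonzero
    Shapley value is phi_0 = v({0}) - v(empty), where v(empty) is the
    count-weighted average over both leaves."""
    from sklearn.tree import DecisionTreeClassifier

    x = np.array([[0.0, 5.0], [1.0, -3.0], [2.0, 2.0], [3.0, 1.0]])
    y = np.array([0, 0, 1, 1])
    clf = DecisionTreeClassifier(max_depth=1, random_state=0).fit(x, y)
    assert clf.tree_.feature[0] == 0  # splits on the informative feature

    sample = x[0]
    phi = tree_shapley_values(clf, sample)
    leaf_probs = _tree_expected_value(clf.tree_, sample, frozenset({0}))
    base = _tree_expected_value(clf.tree_, sample, frozenset())
    assert np.allclose(phi[:, 0], leaf_probs - base)
    assert np.allclose(phi[:, 1], 0.0)
    # base here is the 50/50 count-weighted mixture of the two pure leaves
    assert np.allclose(base, [0.5, 0.5])


def _brute_force_shapley(est, x):
    """Independent oracle: enumerate coalitions over ALL features."""
    from math import factorial

    f = x.size
    feats = list(range(f))
    k = est.n_classes_
    phi = np.zeros((k, f))
    for member in getattr(est, "estimators_", [est]):
        tree = member.tree_
        for i in feats:
            others = [j for j in feats if j != i]
            for size in range(f):
                w = factorial(size) * factorial(f - size - 1) / factorial(f)
                for sub in combinations(others, size):
                    s = frozenset(sub)
                    phi[:, i] += w * (
                        _tree_expected_value(tree, x, s | {i})
                        - _tree_expected_value(tree, x, s)
                    )
    return phi / len(getattr(est, "estimators_", [est]))


def test_used_feature_enumeration_matches_full_enumeration():
    """Restricting coalitions to the features a tree uses gives the same
    Shapley values as enumerating over every feature."""
    from sklearn.ensemble import ExtraTreesClassifier

    rng = np.random.default_rng(2)
    x = rng.standard_normal((60, 4))
    y = (x[:, 1] + 0.8 * x[:, 3] > 0).astype(int)
    est = ExtraTreesClassifier(n_estimators=5, max_depth=2, random_state=0).fit(x, y)
    sample = x[7]
    assert np.allclose(tree_shapley_values(est, sample), _brute_force_shapley(est, sample))


def test_shapley_local_accuracy():
    """Efficiency: base value + sum of contributions equals the ensemble's
    predicted probability vector."""
    from sklearn.ensemble import ExtraTreesClassifier

    rng = np.random.default_rng(3)
    x = rng.standard_normal((80, 5))
    y = (x[:, 2] > 0).astype(int)
    est = ExtraTreesClassifier(n_estimators=8, max_depth=3, random_state=1).fit(x, y)
    for idx in (0, 11, 42):
        sample = x[idx]
        phi = tree_shapley_values(est, sample)
        base = np.mean(
            [_tree_expected_value(t.tree_, sample, frozenset()) for t in est.estimators_],
            axis=0,
        )
        assert np.allclose(base + phi.sum(axis=1), est.predict_proba(sample[None])[0])


def _planted_set(seed, n_channels=6, sfreq=40.0, planted=2, n=60):
    cfg = SynthConfig(n_channels=n_channels, sfreq=sfreq, seed=seed, planted_channel=planted)
    es = generate_epoch_set(cfg, {0: n, 2: n})
    es = EpochSet(es.x, (es.y > 0).astype(np.int64), es.sfreq,
                  {0: "non-seizure", 1: "seizure"})
    return apply_stats(es, fit_stats(es))


def test_tree_backend_recovers_planted_channel_sklearn():
    std = _planted_set(seed=0)
    spec = ModelSpec("EXTRA_TREES", (6, 40), 2, {"n_estimators": 30, "tree_max_depth": 3})
    tm = train_model(spec, std, seed=0)
    attr = compute_attributions(tm, std, backend="tree_shap", batch_limit=20)
    ci = aggregate_channels(attr)
    assert ci.ranking[0] == 2


def test_xgboost_contributions_recover_planted_channel():
    std = _planted_set(seed=1)
    spec = ModelSpec("XGBOOST", (6, 40), 2, {"n_estimators": 40, "xgb_max_depth": 3})
    tm = train_model(spec, std, seed=0)
    attr = compute_attributions(tm, std, backend="tree_shap")
    ci = aggregate_channels(attr)
    assert ci.ranking[0] == 2


def test_permutation_backend_recovers_planted_channel():
    std = _planted_set(seed=2)
    spec = ModelSpec("XGBOOST", (6, 40), 2, {"n_estimators": 40, "xgb_max_depth": 3})
    tm = train_model(spec, std, seed=0)
    attr = compute_attributions(tm, std, backend="permutation", seed=0)
    ci = aggregate_channels(attr)
    assert ci.ranking[0] == 2
    assert attr.values[0].shape == (1, 6, 40)  # score broadcast over timepoints


class _ConstantModel:
    """Ignores its input entirely."""

    class spec:
        input_shape = (3, 10)
        n_classes = 2

    def predict_proba(self, x):
        return np.full(len(x), 0.7)


def test_permutation_on_input_ignoring_model_is_zero():
    rng = np.random.default_rng(4)
    es = EpochSet(rng.standard_normal((30, 3, 10)), rng.integers(0, 2, 30), 10.0)
    scores = permutation_channel_importance(_ConstantModel(), es, seed=0)
    assert np.allclose(scores, 0.0)


def test_tree_backend_rejects_neural_model(small_binary_sets):
    train, _, _ = small_binary_sets
    model = build_model(
        ModelSpec("EEGNET", (train.n_channels, train.n_times), 2, {"eegnet_kt": 16}),
        seed=0,
    )
    with pytest.raises(ValueError, match="tree-ensemble"):
        compute_attributions(model, train, backend="tree_shap")
    with pytest.raises(ValueError, match="unknown backend"):
        compute_attributions(model, train, backend="gradients")


def test_channel_importance_csv(tmp_path):
    ci = aggregate_channels(AttributionSet([np.ones((1, 3, 2))]))
    ci.to_csv(tmp_path / "imp.csv")
    lines = (tmp_path / "imp.csv").read_text().strip().splitlines()
    assert lines[0] == "channel,score,rank"
    assert len(lines) == 4
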