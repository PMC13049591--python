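"""Channel-level importance from per-timepoint attributions.

Attribution values are computed per class, per sample, and per flattened
feature (channel-major: feature ``f`` maps to channel ``f // T`` and
timepoint ``f % T``). Aggregating the absolute values over timepoints
collapses the temporal dimension to one score per channel and sample; scores
are then averaged over samples and, for multiclass problems, unweighted over
classes.

Two backends:

* ``tree_shap`` — additive Shapley attributions for tree ensembles. For
  xgboost models this delegates to the booster's built-in per-feature
  contributions; for sklearn forests an exact Shapley value is computed by
  exhaustive coalition enumeration over the features each tree actually uses
  (path-dependent expectations weighted by node sample counts), which is
  feasible for shallow trees.
* ``permutation`` — model-agnostic: each channel is scored by the drop in
  accuracy when that channel's values are permuted across samples. This is
  the supported channel-level path for the neural models, whose inputs are
  raw channels rather than tabular features.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .types import EpochSet

__all__ = [
    "AttributionSet",
    "ChannelImportance",
    "aggregate_channels",
    "compute_attributions",
    "tree_shapley_values",
    "permutation_channel_importance",
    "plot_channel_importance",
]

_MAX_EXACT_FEATURES = 14


@dataclass
class AttributionSet:
    """Per-class attribution tensors, each ``(N, C, T)`` (channel-major)."""

    values: list[np.ndarray]

    def __post_init__(self) -> None:
        vals = []
        for arr in self.values:
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3:
                raise ValueError("attribution arrays must be N x C x T")
            if not np.isfinite(arr).all():
                raise ValueError("attributions must be finite")
            vals.append(arr)
        if len({a.shape for a in vals}) > 1:
            raise ValueError("per-class attribution shapes differ")
        self.values = vals

    @classmethod
    def from_flat(cls, flat: list[np.ndarray], n_channels: int, n_times: int) -> "AttributionSet":
        """Reshape ``(N, C*T)`` channel-major matrices into ``(N, C, T)``."""
        out = []
        for arr in flat:
            arr = np.asarray(arr, dtype=float)
            if arr.shape[1] != n_channels * n_times:
                raise ValueError(
                    f"feature count {arr.shape[1]} != C*T = {n_channels * n_times}"
                )
            out.append(arr.reshape(arr.shape[0], n_channels, n_times))
        return cls(out)

    @property
    def n_channels(self) -> int:
        return self.values[0].shape[1]


@dataclass
class ChannelImportance:
    """Non-negative per-channel scores and the descending ranking."""

    scores: np.ndarray
    ranking: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["channel", "score", "rank"])
            rank_of = {int(ch): r for r, ch in enumerate(self.ranking)}
            for ch, score in enumerate(self.scores):
                writer.writerow([ch, float(score), rank_of[ch]])


def aggregate_channels(attr: AttributionSet, signed: bool = False) -> ChannelImportance:
    """Collapse timepoints to one score per channel.

    Default: mean of absolute attributions over timepoints, then mean over
    samples, then unweighted mean over classes. ``signed=True`` skips the
    absolute value (signed contributions may cancel).
    """
    per_class = []
    for arr in attr.values:
        a = arr if signed else np.abs(arr)
        per_class.append(a.mean(axis=2).mean(axis=0))  # (C,)
    scores = np.mean(per_class, axis=0)
    if not signed:
        scores = np.abs(scores)
    ranking = np.argsort(-scores, kind="stable")  # ties broken by channel index
    return ChannelImportance(scores, ranking)


# ---------------------------------------------------------------------------
# exact Shapley values for sklearn decision trees (exhaustive coalitions)
# ---------------------------------------------------------------------------


def _tree_expected_value(tree, x: np.ndarray, coalition: frozenset) -> np.ndarray:
    """Path-dependent expected leaf value when only features in ``coalition``
    are known; unknown splits average children by training sample counts."""

    def rec(node: int) -> np.ndarray:
        f = tree.feature[node]
        if f < 0:  # leaf
            value = tree.value[node].reshape(-1).astype(float)
            total = value.sum()
            return value / total if total > 0 else value
        left, right = tree.children_left[node], tree.children_right[node]
        if f in coalition:
            nxt = left if x[f] <= tree.threshold[node] else right
            return rec(nxt)
        wl = tree.n_node_samples[left]
        wr = tree.n_node_samples[right]
        return (wl * rec(left) + wr * rec(right)) / (wl + wr)

    return rec(0)


def tree_shapley_values(estimator, x: np.ndarray) -> np.ndarray:
    """Exact Shapley values of a fitted sklearn tree ensemble for one sample.

    Returns an array ``(K, F)``: the per-class contribution of every feature.
    Exhaustive enumeration over the features each tree uses; trees touching
    more than 14 distinct features are rejected (use the permutation backend
    or xgboost instead).
    """
    trees = getattr(estimator, "estimators_", None)
    if trees is None:
        trees = [estimator]
    n_classes = estimator.n_classes_
    phi = np.zeros((n_classes, x.size))
    from math import factorial

    for member in trees:
        tree = member.tree_
        used = sorted({int(f) for f in tree.feature if f >= 0})
        if len(used) > _MAX_EXACT_FEATURES:
            raise ValueError(
                f"tree uses {len(used)} features; exact enumeration supports "
                f"<= {_MAX_EXACT_FEATURES}"
            )
        m = len(used)
        cache: dict[frozenset, np.ndarray] = {}

        def value(coal: frozenset, tree=tree) -> np.ndarray:
            if coal not in cache:
                cache[coal] = _tree_expected_value(tree, x, coal)
            return cache[coal]

        for i in used:
            others = [f for f in used if f != i]
            for size in range(m):
                weight = factorial(size) * factorial(m - size - 1) / factorial(m)
                for subset in combinations(others, size):
                    s = frozenset(subset)
                    phi[:, i] += weight * (value(s | {i}) - value(s))
    return phi / len(trees)


def _xgboost_contribs(model, flat_x: np.ndarray, n_classes: int) -> list[np.ndarray]:
    """Per-class additive margin contributions from an xgboost model."""
    import xgboost as xgb

    booster = model.get_booster()
    contribs = booster.predict(xgb.DMatrix(flat_x), pred_contribs=True)
    n = flat_x.shape[0]
    f = flat_x.shape[1]
    if contribs.ndim == 2:  # binary: (N, F+1); same contribution for both classes
        core = contribs[:, :f]
        return [core, core]
    contribs = contribs.reshape(n, n_classes, f + 1)
    return [contribs[:, k, :f] for k in range(n_classes)]


def compute_attributions(
    model,
    es: EpochSet,
    backend: str = "tree_shap",
    seed: int = 0,
    batch_limit: int | None = None,
) -> AttributionSet:
    """Per-class attributions for the epochs in ``es``.

    ``model`` is a :class:`seizurekit.models.TrainedModel` (or the underlying
    classifier). ``tree_shap`` requires a tree-ensemble backend; the
    permutation backend works for any model exposing probabilities and emits
    one channel-constant attribution map (the accuracy drop broadcast over
    timepoints).
    """
    from .models import SeizureClassifier, TrainedModel

    if isinstance(model, TrainedModel):
        model = model.model
    if backend == "permutation":
        scores = permutation_channel_importance(model, es, seed=seed)
        t = es.n_times
        arr = np.tile(scores[:, None], (1, t))[None]  # (1, C, T)
        return AttributionSet([arr])
    if backend != "tree_shap":
        raise ValueError(f"unknown backend {backend!r}")
    if not isinstance(model, SeizureClassifier) or model.spec.is_neural:
        raise ValueError(
            "tree_shap requires a tree-ensemble model; use backend='permutation' "
            "for neural architectures"
        )
    flat = es.x.reshape(len(es.x), -1)
    if batch_limit is not None:
        flat = flat[:batch_limit]
    est = model.estimator
    if model.spec.arch == "XGBOOST":
        per_class = _xgboost_contribs(est, flat, model.spec.n_classes)
    else:
        n_classes = est.n_classes_
        per_class = [np.empty((flat.shape[0], flat.shape[1])) for _ in range(n_classes)]
        for idx in range(flat.shape[0]):
            phi = tree_shapley_values(est, flat[idx])
            for k in range(n_classes):
                per_class[k][idx] = phi[k]
    return AttributionSet.from_flat(per_class, es.n_channels, es.n_times)


def permutation_channel_importance(
    model, es: EpochSet, seed: int = 0, n_repeats: int = 3
) -> np.ndarray:
    """Accuracy drop per channel when that channel is shuffled across samples.

    Per-channel (not per-timepoint): all T values of a channel move together,
    so within-channel temporal structure is preserved while the link to the
    label is broken.
    """
    from .models import predict

    rng = np.random.default_rng(seed)
    labels, _ = predict(model, es)
    base_acc = float(np.mean(labels == es.y))
    scores = np.zeros(es.n_channels)
    for ch in range(es.n_channels):
        drops = []
        for _ in range(n_repeats):
            x_perm = es.x.copy()
            x_perm[:, ch, :] = x_perm[rng.permutation(len(x_perm)), ch, :]
            perm_labels, _ = predict(model, x_perm)
            drops.append(base_acc - float(np.mean(perm_labels == es.y)))
        scores[ch] = np.mean(drops)
    return scores


def plot_channel_importance(ci: ChannelImportance, path: str | Path) -> None:
    """Bar plot of per-channel importance (Ch-0 .. Ch-C-1)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    c = len(ci.scores)
    fig, ax = plt.subplots(figsize=(max(6, c * 0.4), 3.5))
    ax.bar(np.arange(c), ci.scores, color="tab:blue")
    ax.set_xticks(np.arange(c))
    ax.set_xticklabels([f"Ch-{i}" for i in range(c)], rotation=90, fontsize=7)
    ax.set_ylabel("mean |attribution|")
    ax.set_title("Average feature importance per EEG channel")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
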