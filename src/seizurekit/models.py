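"""Classifier zoo behind one training/prediction contract.

Architectures
-------------
* ``MDCBG`` — the hybrid multi-dimensional CNN + bidirectional GRU: the
  ``C x T`` epoch is reshaped to a 3-D volume ``(depth 1, height C, width T)``,
  passed through four 3-D convolution blocks (32 / 64 / 128x2 / 128x2 filters,
  3x3x3 kernels, stride ``(1,2,2)`` in the first block, batch norm and ceil-mode
  ``(1,2,2)`` max pooling per block), flattened along the surviving time axis
  into a sequence, and classified by a bidirectional GRU, dropout, and a dense
  head (sigmoid for binary, softmax otherwise).
* ``EEGNET`` — temporal convolution, depthwise spatial filters over channels,
  separable temporal convolution, with batch norm / ELU / average pooling /
  dropout.
* ``CTNET`` — an EEGNet-style convolutional tokenizer followed by transformer
  encoder blocks (multi-head self-attention + feed-forward, residual + LN).
* Ablations: ``CNN_ONLY`` (conv stack + dense head), ``BIGRU_ONLY``
  (bidirectional GRU straight on the channel sequence), ``MDCBG_NO_DROPOUT``.
* Recurrent baselines: ``BIGRU_ATTENTION`` (softmax-over-time attention
  pooling), ``BILSTM_GRU`` (bidirectional LSTM feeding a GRU).
* Classical baselines on flattened ``C*T`` vectors: ``EXTRA_TREES``,
  ``RANDOM_FOREST``, ``XGBOOST`` (thin adapters over sklearn/xgboost).
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import nn
from .normalize import NormStats
from .types import EpochSet

__all__ = [
    "NEURAL_ARCHS",
    "TREE_ARCHS",
    "ModelSpec",
    "TrainedModel",
    "build_model",
    "train_model",
    "predict",
    "count_parameters",
    "save_model",
    "load_model",
]

NEURAL_ARCHS = (
    "MDCBG",
    "EEGNET",
    "CTNET",
    "CNN_ONLY",
    "BIGRU_ONLY",
    "MDCBG_NO_DROPOUT",
    "BIGRU_ATTENTION",
    "BILSTM_GRU",
)
TREE_ARCHS = ("EXTRA_TREES", "RANDOM_FOREST", "XGBOOST")

_DEFAULT_HYPERPARAMS: dict[str, Any] = {
    "conv_filters": (32, 64, 128, 128),
    "kernel": (3, 3, 3),
    "first_stride": (1, 2, 2),
    "pool": (1, 2, 2),
    "gru_units": 128,
    "attn_units": 64,
    "dense_units": 128,
    "dropout_rate": 0.5,
    "learning_rate": 1e-3,
    "batch_size": 32,
    "max_epochs": 50,
    "patience": 10,
    "val_fraction": 0.1,
    "eegnet_f1": 8,
    "eegnet_d": 2,
    "eegnet_f2": 16,
    "eegnet_kt": 64,
    "eegnet_p1": 4,
    "eegnet_p2": 8,
    "ct_heads": 2,
    "ct_blocks": 2,
    "ct_pool1": 8,
    "ct_pool2": 4,
    "n_estimators": 200,
    "tree_max_depth": None,
    "xgb_max_depth": 4,
    "seed": 0,
}


@dataclass
class ModelSpec:
    """Architecture + input contract + hyperparameters for one classifier."""

    arch: str
    input_shape: tuple[int, int]  # (C, T)
    n_classes: int = 2
    hyperparams: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.arch = self.arch.upper()
        if self.arch not in NEURAL_ARCHS + TREE_ARCHS:
            raise ValueError(f"unknown architecture {self.arch!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        c, t = self.input_shape
        if c < 1 or t < 1:
            raise ValueError("input_shape entries must be positive")
        unknown = set(self.hyperparams) - set(_DEFAULT_HYPERPARAMS)
        if unknown:
            raise ValueError(f"unknown hyperparameters: {sorted(unknown)}")

    @property
    def hp(self) -> dict[str, Any]:
        return {**_DEFAULT_HYPERPARAMS, **self.hyperparams}

    @property
    def is_neural(self) -> bool:
        return self.arch in NEURAL_ARCHS

    def to_dict(self) -> dict:
        return {
            "arch": self.arch,
            "input_shape": list(self.input_shape),
            "n_classes": self.n_classes,
            "hyperparams": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.hyperparams.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        hp = {
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in d.get("hyperparams", {}).items()
        }
        return cls(d["arch"], tuple(d["input_shape"]), d["n_classes"], hp)


def _head_units(spec: ModelSpec) -> int:
    return 1 if spec.n_classes == 2 else spec.n_classes


def _conv_stack(spec: ModelSpec) -> list[nn.Layer]:
    """The four-block 3-D convolution trunk shared by MDCBG / CNN_ONLY."""
    hp = spec.hp
    c, t = spec.input_shape
    layers: list[nn.Layer] = [nn.Reshape((1, 1, c, t))]
    ones = (1, 1, 1)
    for i, f in enumerate(hp["conv_filters"]):
        stride = tuple(hp["first_stride"]) if i == 0 else ones
        n_convs = 1 if i < 2 else 2
        for j in range(n_convs):
            layers.append(
                nn.Conv3D(
                    f,
                    tuple(hp["kernel"]),
                    stride if j == 0 else ones,
                    name=f"block{i + 1}_conv{j + 1}",
                )
            )
        layers.append(nn.BatchNorm(feature_axis=1))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool3D(tuple(hp["pool"]), name=f"block{i + 1}_pool"))
    return layers


def _probe_shape(layers: list[nn.Layer], in_shape: tuple[int, ...]) -> tuple[int, ...]:
    rng = np.random.default_rng(0)
    shape = in_shape
    for layer in layers:
        shape = layer.build(shape, rng)
    return shape


def _make_layers(spec: ModelSpec) -> list[nn.Layer]:
    hp = spec.hp
    c, t = spec.input_shape
    head = _head_units(spec)
    drop = hp["dropout_rate"]
    arch = spec.arch

    if arch in ("MDCBG", "MDCBG_NO_DROPOUT", "CNN_ONLY"):
        f_out, d_out, h_out, w_out = _probe_shape(_conv_stack(spec), (c, t))
        stack = _conv_stack(spec)  # fresh (unbuilt) layers
        if arch == "CNN_ONLY":
            return stack + [
                nn.Flatten(),
                nn.Dense(hp["dense_units"], name="cnn_dense"),
                nn.ReLU(),
                nn.Dropout(drop),
                nn.Dense(head, name="head"),
            ]
        rate = 0.0 if arch == "MDCBG_NO_DROPOUT" else drop
        u = hp["gru_units"]
        return stack + [
            # collapse (F, D, H) into per-timestep features along the time axis
            nn.Reshape((f_out * d_out * h_out, w_out)),
            nn.Transpose((1, 0)),
            nn.Bidirectional(nn.GRU(u), nn.GRU(u), name="bigru"),
            nn.Dropout(rate),
            nn.Dense(head, name="head"),
        ]

    if arch == "EEGNET":
        return [
            nn.Reshape((1, c, t)),
            nn.Conv2D(hp["eegnet_f1"], (1, hp["eegnet_kt"]), name="temporal_conv"),
            nn.BatchNorm(feature_axis=1),
            nn.DepthwiseSpatialConv(hp["eegnet_d"]),
            nn.BatchNorm(feature_axis=1),
            nn.ELU(),
            nn.AvgPoolTime(hp["eegnet_p1"]),
            nn.Dropout(drop),
            nn.DepthwiseTemporalConv(16),
            nn.PointwiseConv(hp["eegnet_f2"]),
            nn.BatchNorm(feature_axis=1),
            nn.ELU(),
            nn.AvgPoolTime(hp["eegnet_p2"]),
            nn.Dropout(drop),
            nn.Flatten(),
            nn.Dense(head, name="head"),
        ]

    if arch == "CTNET":
        layers: list[nn.Layer] = [
            nn.Reshape((1, c, t)),
            nn.Conv2D(hp["eegnet_f1"], (1, hp["eegnet_kt"]), name="tokenizer_conv"),
            nn.BatchNorm(feature_axis=1),
            nn.DepthwiseSpatialConv(hp["eegnet_d"]),
            nn.BatchNorm(feature_axis=1),
            nn.ELU(),
            nn.AvgPoolTime(hp["ct_pool1"]),
            nn.Dropout(drop),
            nn.DepthwiseTemporalConv(16),
            nn.PointwiseConv(hp["eegnet_f2"]),
            nn.BatchNorm(feature_axis=1),
            nn.ELU(),
            nn.AvgPoolTime(hp["ct_pool2"]),
            nn.Dropout(drop),
            nn.Transpose((1, 0)),  # tokens along time: (T', d_model)
        ]
        for b in range(hp["ct_blocks"]):
            layers.append(
                nn.TransformerBlock(hp["ct_heads"], dropout=drop, name=f"encoder{b + 1}")
            )
        layers += [nn.Flatten(), nn.Dropout(drop), nn.Dense(head, name="head")]
        return layers

    if arch == "BIGRU_ONLY":
        u = hp["gru_units"]
        return [
            nn.Transpose((1, 0)),  # (T, C) sequence of channel vectors
            nn.Bidirectional(nn.GRU(u), nn.GRU(u), name="bigru"),
            nn.Dropout(drop),
            nn.Dense(head, name="head"),
        ]

    if arch == "BIGRU_ATTENTION":
        u = hp["gru_units"]
        return [
            nn.Transpose((1, 0)),
            nn.Bidirectional(
                nn.GRU(u, return_sequences=True),
                nn.GRU(u, return_sequences=True),
                name="bigru",
            ),
            nn.AttentionPool(hp["attn_units"]),
            nn.Dropout(drop),
            nn.Dense(head, name="head"),
        ]

    if arch == "BILSTM_GRU":
        u = hp["gru_units"]
        return [
            nn.Transpose((1, 0)),
            nn.Bidirectional(
                nn.LSTM(u, return_sequences=True),
                nn.LSTM(u, return_sequences=True),
                name="bilstm",
            ),
            nn.GRU(u, name="gru"),
            nn.Dropout(drop),
            nn.Dense(head, name="head"),
        ]

    raise ValueError(f"unknown neural architecture {arch!r}")  # pragma: no cover


class SeizureClassifier:
    """A built (possibly untrained) model with a uniform probability API."""

    def __init__(self, spec: ModelSpec, seed: int | None = None) -> None:
        self.spec = spec
        self.seed = spec.hp["seed"] if seed is None else seed
        self.history: nn.History | None = None
        self.estimator = None
        self.net: nn.Network | None = None
        if spec.is_neural:
            self.net = nn.Network(
                _make_layers(spec), spec.input_shape, seed=self.seed
            )
        else:
            self.estimator = _make_estimator(spec, self.seed)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Binary: ``(N,)`` positive-class probabilities; multiclass ``(N, K)``."""
        x = np.asarray(x, dtype=np.float64)
        if self.spec.is_neural:
            outs = []
            for start in range(0, len(x), batch_size):
                logits = self.net.forward(x[start : start + batch_size], train=False)
                if self.spec.n_classes == 2:
                    outs.append(1.0 / (1.0 + np.exp(-logits.reshape(-1))))
                else:
                    z = logits - logits.max(axis=1, keepdims=True)
                    e = np.exp(z)
                    outs.append(e / e.sum(axis=1, keepdims=True))
            return np.concatenate(outs)
        flat = x.reshape(len(x), -1)
        proba = self.estimator.predict_proba(flat)
        if self.spec.n_classes == 2:
            return proba[:, 1]
        return proba


def _make_estimator(spec: ModelSpec, seed: int):
    hp = spec.hp
    if spec.arch == "EXTRA_TREES":
        from sklearn.ensemble import ExtraTreesClassifier

        return ExtraTreesClassifier(
            n_estimators=hp["n_estimators"], max_depth=hp["tree_max_depth"],
            random_state=seed, n_jobs=1,
        )
    if spec.arch == "RANDOM_FOREST":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=hp["n_estimators"], max_depth=hp["tree_max_depth"],
            random_state=seed, n_jobs=1,
        )
    if spec.arch == "XGBOOST":
        import xgboost as xgb

        return xgb.XGBClassifier(
            n_estimators=hp["n_estimators"], max_depth=hp["xgb_max_depth"],
            random_state=seed, n_jobs=1, learning_rate=0.3,
            objective="binary:logistic" if spec.n_classes == 2 else "multi:softprob",
            eval_metric="logloss",
        )
    raise ValueError(f"unknown tree architecture {spec.arch!r}")


def build_model(spec: ModelSpec, seed: int | None = None) -> SeizureClassifier:
    """Construct an untrained classifier; weight init is seeded."""
    return SeizureClassifier(spec, seed=seed)


@dataclass
class TrainedModel:
    """A fitted classifier plus its training history and normalization ref."""

    model: SeizureClassifier
    history: nn.History
    norm_stats: NormStats | None = None

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(x)


def train_model(
    spec_or_model: ModelSpec | SeizureClassifier,
    train: EpochSet,
    val_fraction: float = 0.1,
    early_stopping: tuple[str, int] = ("val_loss", 10),
    seed: int = 0,
    norm_stats: NormStats | None = None,
) -> TrainedModel:
    """Fit a classifier on (already standardized) training epochs.

    A validation subset is carved from the *training* data only, used for
    early stopping (monitor, patience). Classical tree models ignore the
    validation split and train on everything.
    """
    if isinstance(spec_or_model, ModelSpec):
        model = build_model(spec_or_model, seed=seed)
    else:
        model = spec_or_model
    spec = model.spec
    if len(np.unique(train.y)) < 2:
        raise ValueError("training labels contain a single class")
    if not spec.is_neural:
        model.estimator.fit(train.x.reshape(len(train.x), -1), train.y)
        return TrainedModel(model, nn.History(), norm_stats)
    if not 0.0 < val_fraction < 0.5:
        raise ValueError("val_fraction must be in (0, 0.5)")
    monitor, patience = early_stopping
    if monitor != "val_loss":
        raise ValueError("only val_loss monitoring is supported")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(train.n_epochs)
    n_val = max(1, int(round(val_fraction * train.n_epochs)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    hp = spec.hp
    loss_fn = nn.sigmoid_bce if spec.n_classes == 2 else nn.softmax_ce
    history = nn.fit(
        model.net,
        loss_fn,
        train.x[tr_idx],
        train.y[tr_idx],
        x_val=train.x[val_idx],
        y_val=train.y[val_idx],
        epochs=hp["max_epochs"],
        batch_size=hp["batch_size"],
        lr=hp["learning_rate"],
        patience=patience,
        seed=seed,
    )
    model.history = history
    return TrainedModel(model, history, norm_stats)


def predict(
    model: TrainedModel | SeizureClassifier,
    es: EpochSet | np.ndarray,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and probabilities for an epoch set.

    Binary: label 1 iff probability >= threshold. Multiclass: argmax with
    ties broken toward the lowest class index.
    """
    x = es.x if isinstance(es, EpochSet) else np.asarray(es)
    probs = model.predict_proba(x)
    if probs.ndim == 1:
        labels = (probs >= threshold).astype(np.int64)
    else:
        labels = probs.argmax(axis=1).astype(np.int64)
    return labels, probs


def count_parameters(model: TrainedModel | SeizureClassifier | nn.Network) -> int:
    """Exact count of trainable parameters of a neural classifier."""
    if isinstance(model, nn.Network):
        return model.n_params()
    if isinstance(model, TrainedModel):
        model = model.model
    if not model.spec.is_neural:
        raise ValueError("parameter counting applies to neural architectures")
    return model.net.n_params()


def save_model(trained: TrainedModel, path: str | Path) -> None:
    """Persist spec JSON + weights + normalization stats to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "spec.json").write_text(json.dumps(trained.spec.to_dict(), indent=2))
    if trained.norm_stats is not None:
        trained.norm_stats.save(path / "norm_stats.json")
    if trained.spec.is_neural:
        with open(path / "weights.pkl", "wb") as fh:
            pickle.dump(trained.model.net.get_weights(), fh)
    else:
        with open(path / "estimator.pkl", "wb") as fh:
            pickle.dump(trained.model.estimator, fh)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    spec = ModelSpec.from_dict(json.loads((path / "spec.json").read_text()))
    stats = None
    if (path / "norm_stats.json").exists():
        stats = NormStats.load(path / "norm_stats.json")
    model = build_model(spec)
    if spec.is_neural:
        with open(path / "weights.pkl", "rb") as fh:
            model.net.set_weights(pickle.load(fh))
    else:
        with open(path / "estimator.pkl", "rb") as fh:
            model.estimator = pickle.load(fh)
    return TrainedModel(model, nn.History(), stats)
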