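"""Global z-score standardization with train-only statistics.

One grand mean and one population standard deviation are computed over all
``N * C * T`` elements of the *training* tensor and applied to every split,
so held-out data never influences the scaling. Per-channel statistics are
available as a non-default mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .types import EpochSet

__all__ = ["NormStats", "fit_stats", "apply_stats"]

_SIGMA_TOL = 1e-12


@dataclass(frozen=True)
class NormStats:
    """Fitted standardization parameters (microvolts).

    ``mu``/``sigma`` are scalars in global mode or length-C arrays in
    per-channel mode. ``sigma`` uses the population convention (divide by
    the element count, no Bessel correction).
    """

    mu: float | np.ndarray
    sigma: float | np.ndarray
    per_channel: bool = False

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("sigma must be positive")

    def to_dict(self) -> dict:
        return {
            "mu": np.asarray(self.mu).tolist(),
            "sigma": np.asarray(self.sigma).tolist(),
            "per_channel": self.per_channel,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        if d["per_channel"]:
            return cls(np.asarray(d["mu"]), np.asarray(d["sigma"]), True)
        return cls(float(np.asarray(d["mu"])), float(np.asarray(d["sigma"])), False)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "NormStats":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_stats(train: EpochSet, per_channel: bool = False) -> NormStats:
    """Fit the grand mean and population SD on training data only.

    Raises on degenerate (near-constant) data, where standardization is
    undefined.
    """
    if train.n_epochs == 0:
        raise ValueError("cannot fit statistics on an empty training set")
    if per_channel:
        mu = train.x.mean(axis=(0, 2))
        sigma = train.x.std(axis=(0, 2))  # population SD
        if np.any(sigma < _SIGMA_TOL):
            raise ValueError("degenerate training data: a channel is constant")
        return NormStats(mu, sigma, True)
    mu = float(train.x.mean())
    sigma = float(train.x.std())  # population SD over all N*C*T elements
    if sigma < _SIGMA_TOL:
        raise ValueError("degenerate training data: standard deviation is ~0")
    return NormStats(mu, sigma, False)


def apply_stats(es: EpochSet, stats: NormStats) -> EpochSet:
    """Standardize ``(x - mu) / sigma`` elementwise; labels/shape unchanged."""
    if stats.per_channel:
        mu = np.asarray(stats.mu)[None, :, None]
        sigma = np.asarray(stats.sigma)[None, :, None]
    else:
        mu, sigma = stats.mu, stats.sigma
    return EpochSet((es.x - mu) / sigma, es.y.copy(), es.sfreq, dict(es.label_map))
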