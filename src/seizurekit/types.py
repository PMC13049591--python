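"""Core domain containers shared by every stage of the pipeline.

An :class:`EEGRecord` is a continuous multichannel recording; a
:class:`SeizureEvent` is one annotated seizure (onset and duration in
seconds plus a category); an :class:`EpochSet` is the tensor of fixed-length
windows (``N x C x T``) with integer labels that every classifier consumes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SeizureCategory",
    "EEGRecord",
    "SeizureEvent",
    "EpochSet",
    "DEFAULT_LABEL_MAP",
]


class SeizureCategory(enum.IntEnum):
    """Seizure categories; integer values double as class labels (0 = normal)."""

    CPS = 1
    ELECTROGRAPHIC = 2
    VIDEO = 3


#: label -> human-readable class name used throughout the four-class task
DEFAULT_LABEL_MAP = {0: "normal", 1: "CPS", 2: "electrographic", 3: "video"}


@dataclass
class EEGRecord:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    sfreq
        Sampling frequency in Hz.
    channel_names
        One name per row of ``data``.
    """

    data: np.ndarray
    sfreq: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("EEGRecord.data must be 2-D (channels x samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if not self.channel_names:
            self.channel_names = [f"Ch-{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq


@dataclass(frozen=True)
class SeizureEvent:
    """One annotated seizure: onset/duration in seconds and its category."""

    onset_s: float
    duration_s: float
    category: SeizureCategory

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        object.__setattr__(self, "category", SeizureCategory(self.category))

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class EpochSet:
    """Labelled fixed-length EEG windows: ``x`` is ``N x C x T``, ``y`` is ``N``."""

    x: np.ndarray
    y: np.ndarray
    sfreq: float
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.x.ndim != 3:
            raise ValueError("EpochSet.x must be 3-D (epochs x channels x samples)")
        if self.y.shape != (self.x.shape[0],):
            raise ValueError("len(y) must equal the number of epochs")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.y.size and not set(np.unique(self.y)) <= set(self.label_map):
            raise ValueError("labels outside label_map")

    @property
    def n_epochs(self) -> int:
        return self.x.shape[0]

    @property
    def n_channels(self) -> int:
        return self.x.shape[1]

    @property
    def n_times(self) -> int:
        return self.x.shape[2]

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, idx: np.ndarray) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(self.x[idx], self.y[idx], self.sfreq, dict(self.label_map))

    def __len__(self) -> int:
        return self.n_epochs
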