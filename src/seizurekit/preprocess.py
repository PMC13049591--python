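"""Annotation-driven epoching of continuous EEG.

Turns a continuous recording plus seizure annotations into labelled 1-second
epoch tensors: onset/duration annotations are converted to sample indices
(floor, half-open spans), seizure segments are sliced per category, an equal
amount of normal signal is drawn from the non-seizure remainder, segments are
chopped into non-straddling epochs, classes are merged/excluded per task, and
the pooled set is split 90:10 with a seeded shuffle. Arrays persist as .npy
plus a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import (
    DEFAULT_LABEL_MAP,
    EEGRecord,
    EpochSet,
    SeizureCategory,
    SeizureEvent,
)

__all__ = [
    "event_to_sample_span",
    "slice_segments",
    "extract_normal_segments",
    "epoch_segments",
    "assemble_dataset",
    "train_test_split",
    "save_epochs",
    "load_epochs",
    "epochs_from_recording",
    "read_edf",
]


def event_to_sample_span(ev: SeizureEvent, sfreq: float) -> tuple[int, int]:
    """Map an annotation in seconds to a half-open sample interval.

    ``start = floor(onset * sfreq)``, ``stop = floor((onset + duration) * sfreq)``;
    the interval ``[start, stop)`` is guaranteed non-empty.
    """
    if sfreq <= 0:
        raise ValueError("sfreq must be positive")
    start = int(np.floor(ev.onset_s * sfreq))
    stop = int(np.floor((ev.onset_s + ev.duration_s) * sfreq))
    if stop <= start:  # sub-sample duration still occupies one sample
        stop = start + 1
    return start, stop


def slice_segments(
    rec: EEGRecord, events: list[SeizureEvent]
) -> dict[SeizureCategory, list[np.ndarray]]:
    """Slice each event's sub-matrix from the record, keyed by category."""
    out: dict[SeizureCategory, list[np.ndarray]] = {c: [] for c in SeizureCategory}
    for ev in events:
        start, stop = event_to_sample_span(ev, rec.sfreq)
        if stop > rec.n_samples:
            raise ValueError(
                f"event (onset {ev.onset_s} s, duration {ev.duration_s} s) spans "
                f"samples [{start}, {stop}) beyond record length {rec.n_samples}"
            )
        out[ev.category].append(rec.data[:, start:stop])
    return out


def _free_runs(n_samples: int, events: list[SeizureEvent], sfreq: float) -> list[tuple[int, int]]:
    """Maximal half-open runs of samples not covered by any event."""
    covered = sorted(event_to_sample_span(ev, sfreq) for ev in events)
    runs, cursor = [], 0
    for start, stop in covered:
        if start > cursor:
            runs.append((cursor, min(start, n_samples)))
        cursor = max(cursor, stop)
    if cursor < n_samples:
        runs.append((cursor, n_samples))
    return runs


def extract_normal_segments(
    rec: EEGRecord,
    events: list[SeizureEvent],
    total_len_samples: int,
) -> list[np.ndarray]:
    """Draw non-seizure signal totalling ``total_len_samples`` samples.

    Segments are taken greedily from the start of each seizure-free run and
    are disjoint from every event span and from each other.
    """
    if total_len_samples == 0:
        return []
    runs = _free_runs(rec.n_samples, events, rec.sfreq)
    available = sum(stop - start for start, stop in runs)
    if available < total_len_samples:
        raise ValueError(
            f"only {available} non-seizure samples available, "
            f"{total_len_samples} requested"
        )
    segments, remaining = [], total_len_samples
    for start, stop in runs:
        if remaining == 0:
            break
        take = min(stop - start, remaining)
        segments.append(rec.data[:, start : start + take])
        remaining -= take
    return segments


def epoch_segments(
    segments: list[np.ndarray], sfreq: float, label: int
) -> EpochSet:
    """Chop segments into non-overlapping 1-second epochs (``T = sfreq``).

    A trailing remainder shorter than one epoch is discarded so every epoch
    has exactly ``T`` samples and never straddles two segments.
    """
    if sfreq <= 0:
        raise ValueError("sfreq must be positive")
    t_len = int(round(sfreq))
    epochs = []
    for seg in segments:
        n_full = seg.shape[1] // t_len
        for k in range(n_full):
            epochs.append(seg[:, k * t_len : (k + 1) * t_len])
    if epochs:
        x = np.stack(epochs)
    else:
        n_ch = segments[0].shape[0] if segments else 0
        x = np.empty((0, n_ch, t_len))
    y = np.full(x.shape[0], label, dtype=np.int64)
    return EpochSet(x, y, sfreq, dict(DEFAULT_LABEL_MAP))


def assemble_dataset(epoch_sets: list[EpochSet], task: str = "four_class") -> EpochSet:
    """Stack epoch sets and apply the task's class merge/exclusion rule.

    * ``binary``: labels {1,2,3} merge into 1 (seizure vs non-seizure);
    * ``three_class``: the scarce video-detected class (3) is dropped and
      labels {0,1,2} are kept;
    * ``four_class``: passthrough.
    """
    if task not in ("binary", "three_class", "four_class"):
        raise ValueError(f"unknown task {task!r}")
    non_empty = [es for es in epoch_sets if es.n_epochs > 0]
    if not non_empty:
        base = epoch_sets[0] if epoch_sets else None
        c = base.n_channels if base is not None else 0
        t = base.n_times if base is not None else 0
        sf = base.sfreq if base is not None else 1.0
        return EpochSet(np.empty((0, c, t)), np.empty(0, dtype=np.int64), sf)
    shapes = {(es.n_channels, es.n_times) for es in non_empty}
    sfreqs = {es.sfreq for es in non_empty}
    if len(shapes) > 1 or len(sfreqs) > 1:
        raise ValueError(f"mixed epoch shapes {shapes} / sampling rates {sfreqs}")
    x = np.concatenate([es.x for es in non_empty])
    y = np.concatenate([es.y for es in non_empty])
    if task == "binary":
        y = np.where(y > 0, 1, 0)
        label_map = {0: "non-seizure", 1: "seizure"}
    elif task == "three_class":
        keep = y != 3
        x, y = x[keep], y[keep]
        label_map = {k: DEFAULT_LABEL_MAP[k] for k in (0, 1, 2)}
    else:
        label_map = dict(DEFAULT_LABEL_MAP)
    return EpochSet(x, y, non_empty[0].sfreq, label_map)


def train_test_split(
    es: EpochSet,
    train_frac: float = 0.9,
    seed: int = 0,
    stratify: bool = False,
) -> tuple[EpochSet, EpochSet]:
    """Seeded 90:10 (by default) shuffle-split into train and test sets.

    The default is a plain uniform shuffle; ``stratify=True`` splits each
    class separately with the same fraction.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if es.n_epochs == 0:
        raise ValueError("cannot split an empty epoch set")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx, test_idx = [], []
        for label in np.unique(es.y):
            members = np.flatnonzero(es.y == label)
            members = rng.permutation(members)
            n_train = int(round(train_frac * members.size))
            train_idx.append(members[:n_train])
            test_idx.append(members[n_train:])
        train_idx = np.concatenate(train_idx)
        test_idx = np.concatenate(test_idx)
    else:
        perm = rng.permutation(es.n_epochs)
        n_train = int(round(train_frac * es.n_epochs))
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    return es.subset(np.sort(train_idx)), es.subset(np.sort(test_idx))


def save_epochs(es: EpochSet, path: str | Path, extra_manifest: dict | None = None) -> None:
    """Persist an epoch set as ``x.npy`` + ``y.npy`` + ``manifest.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "x.npy", es.x)
    np.save(path / "y.npy", es.y)
    manifest = {
        "sfreq": es.sfreq,
        "label_map": {str(k): v for k, v in es.label_map.items()},
        "n_epochs": es.n_epochs,
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    x = np.load(path / "x.npy")
    y = np.load(path / "y.npy")
    manifest = json.loads((path / "manifest.json").read_text())
    label_map = {int(k): v for k, v in manifest["label_map"].items()}
    return EpochSet(x, y, manifest["sfreq"], label_map)


def epochs_from_recording(
    rec: EEGRecord,
    events: list[SeizureEvent],
    balance_normal: bool = True,
    channel_selection: list[int] | None = None,
) -> list[EpochSet]:
    """Full single-recording pipeline: slice seizures, draw matched normal
    signal, epoch everything, and return one labelled set per class present.

    ``channel_selection`` restricts/reorders channels (indices into the
    record), mirroring per-recording montage harmonisation.
    """
    if channel_selection is not None:
        rec = EEGRecord(
            rec.data[channel_selection],
            rec.sfreq,
            [rec.channel_names[i] for i in channel_selection],
        )
    by_cat = slice_segments(rec, events)
    sets = []
    seizure_len = 0
    for cat, segs in by_cat.items():
        if segs:
            seizure_len += sum(s.shape[1] for s in segs)
            sets.append(epoch_segments(segs, rec.sfreq, int(cat)))
    if balance_normal:
        t_len = int(round(rec.sfreq))
        runs = _free_runs(rec.n_samples, events, rec.sfreq)
        available = sum(stop - start for start, stop in runs)
        want = min(seizure_len, available) if seizure_len else available
        want -= want % t_len  # whole epochs only
        normal_segs = extract_normal_segments(rec, events, want)
    else:
        normal_segs = extract_normal_segments(
            rec, events, sum(b - a for a, b in _free_runs(rec.n_samples, events, rec.sfreq))
        )
    if normal_segs:
        sets.insert(0, epoch_segments(normal_segs, rec.sfreq, 0))
    return sets


def read_edf(path: str | Path) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord` (requires ``mne``).

    Signals are converted from volts (mne's unit) to microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecord(raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names))
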