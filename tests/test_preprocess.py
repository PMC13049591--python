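"""Epoching pipeline: sample-index arithmetic, segment slicing, normal
extraction, class merging, splitting, and persistence."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seizurekit.preprocess import (
    assemble_dataset,
    epoch_segments,
    event_to_sample_span,
    extract_normal_segments,
    load_epochs,
    save_epochs,
    slice_segments,
    train_test_split,
)
from seizurekit.synth import SynthConfig, generate_epoch_set
from seizurekit.types import EEGRecord, EpochSet, SeizureCategory, SeizureEvent


def _record(n_channels=2, sfreq=500.0, n_samples=5000, seed=0):
    rng = np.random.default_rng(seed)
    return EEGRecord(rng.standard_normal((n_channels, n_samples)), sfreq)


@pytest.mark.parametrize(
    "onset,duration,sfreq,expected",
    [
        (2.0, 3.0, 500.0, (1000, 2500)),
        (0.0, 1.0, 500.0, (0, 500)),
        (1.2345, 0.5, 500.0, (617, 867)),
    ],
)
def test_event_span_examples(onset, duration, sfreq, expected):
    ev = SeizureEvent(onset, duration, SeizureCategory.CPS)
    assert event_to_sample_span(ev, sfreq) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    onset=st.integers(0, 10_000),
    duration=st.integers(1, 10_000),
    sfreq=st.sampled_from([128, 250, 256, 500, 512, 1000]),
)
def test_event_span_matches_rational_arithmetic(onset, duration, sfreq):
    """Floor conversion agrees with an exact rational-arithmetic oracle
    (onset/duration expressed in milliseconds to exercise fractions)."""
    onset_s, dur_s = onset / 1000.0, duration / 1000.0
    ev = SeizureEvent(onset_s, dur_s, SeizureCategory.CPS)
    start, stop = event_to_sample_span(ev, float(sfreq))
    exact_start = Fraction(onset, 1000) * sfreq
    exact_stop = Fraction(onset + duration, 1000) * sfreq
    # floating-point floor may differ from the rational floor only when the
    # float representation straddles an integer boundary; allow 1 ulp there
    assert abs(start - int(exact_start // 1)) <= 1
    assert abs(stop - max(int(exact_stop // 1), start + 1)) <= 1


def test_slice_segments_extracts_event_submatrices():
    rec = _record()
    events = [
        SeizureEvent(1.0, 2.0, SeizureCategory.CPS),
        SeizureEvent(5.0, 1.0, SeizureCategory.ELECTROGRAPHIC),
    ]
    segs = slice_segments(rec, events)
    assert np.array_equal(segs[SeizureCategory.CPS][0], rec.data[:, 500:1500])
    assert np.array_equal(segs[SeizureCategory.ELECTROGRAPHIC][0], rec.data[:, 2500:3000])
    assert segs[SeizureCategory.VIDEO] == []


def test_slice_segments_out_of_bounds_names_event():
    rec = _record(n_samples=1000)
    with pytest.raises(ValueError, match="onset 1.5"):
        slice_segments(rec, [SeizureEvent(1.5, 2.0, SeizureCategory.CPS)])


def test_extract_normal_segments_avoids_events():
    rec = _record(n_samples=5000)
    events = [SeizureEvent(2.0, 3.0, SeizureCategory.CPS)]  # samples [1000, 2500)
    segs = extract_normal_segments(rec, events, 2500)
    assert sum(s.shape[1] for s in segs) == 2500
    # all returned data must come from [0, 1000) or [2500, 5000)
    allowed = np.concatenate([rec.data[:, :1000], rec.data[:, 2500:]], axis=1)
    got = np.concatenate(segs, axis=1)
    assert got.shape[1] <= allowed.shape[1]


def test_extract_normal_segments_zero_request():
    rec = _record(n_samples=100)
    assert extract_normal_segments(rec, [], 0) == []


def test_extract_normal_segments_insufficient_signal():
    rec = _record(n_samples=1000)
    events = [SeizureEvent(0.0, 1.5, SeizureCategory.CPS)]
    with pytest.raises(ValueError, match="250 non-seizure samples available"):
        extract_normal_segments(rec, events, 500)


def test_normal_segments_disjoint_from_events_randomized():
    """Over many random annotation layouts, extracted normal indices never
    intersect any event span."""
    for seed in range(200):
        rng = np.random.default_rng(seed)
        sfreq = 100.0
        n = 2000
        data = np.arange(n, dtype=float)[None, :]  # index-valued signal
        rec = EEGRecord(data.copy(), sfreq)
        onset = float(rng.uniform(0, 10))
        dur = float(rng.uniform(0.5, 5))
        events = [SeizureEvent(onset, dur, SeizureCategory.CPS)]
        start, stop = event_to_sample_span(events[0], sfreq)
        free = n - (stop - start)
        request = int(rng.integers(0, free + 1))
        segs = extract_normal_segments(rec, events, request)
        if segs:
            indices = np.concatenate([s[0] for s in segs]).astype(int)
            assert sum(s.shape[1] for s in segs) == request
            assert not set(indices) & set(range(start, stop))
            assert len(set(indices)) == len(indices)  # segments disjoint


@pytest.mark.parametrize("length,n_epochs", [(1250, 2), (500, 1), (499, 0)])
def test_epoch_segments_drops_trailing_remainder(length, n_epochs):
    seg = np.random.default_rng(0).standard_normal((3, length))
    es = epoch_segments([seg], 500.0, label=1)
    assert es.n_epochs == n_epochs
    assert es.x.shape[1:] == (3, 500)
    assert (es.y == 1).all()
    if n_epochs:
        assert np.array_equal(es.x[0], seg[:, :500])


def test_epochs_never_straddle_segments():
    a = np.zeros((1, 750))
    b = np.ones((1, 750))
    es = epoch_segments([a, b], 500.0, label=0)
    # one epoch per segment; the two trailing 250-sample remainders dropped
    assert es.n_epochs == 2
    assert set(np.unique(es.x[0])) == {0.0}
    assert set(np.unique(es.x[1])) == {1.0}


def _sets_with_counts(counts, n_channels=2, sfreq=10.0):
    cfg = SynthConfig(n_channels=n_channels, sfreq=sfreq, seed=1)
    return [
        generate_epoch_set(cfg, {label: count})
        for label, count in counts.items()
        if count
    ]


def test_assemble_binary_merges_seizure_classes():
    sets = _sets_with_counts({0: 416, 1: 289, 2: 68, 3: 6})
    es = assemble_dataset(sets, task="binary")
    assert es.n_epochs == 779
    assert es.class_counts() == {0: 416, 1: 363}


def test_assemble_three_class_drops_video():
    sets = _sets_with_counts({0: 416, 1: 289, 2: 68, 3: 6})
    es = assemble_dataset(sets, task="three_class")
    assert es.n_epochs == 773
    assert es.class_counts() == {0: 416, 1: 289, 2: 68}


def test_assemble_empty_and_mixed_shape():
    cfg = SynthConfig(n_channels=2, sfreq=10.0, seed=1)
    empty = generate_epoch_set(cfg, {0: 0})
    assert assemble_dataset([empty], task="binary").n_epochs == 0
    other = generate_epoch_set(SynthConfig(n_channels=3, sfreq=10.0, seed=1), {0: 2})
    some = generate_epoch_set(cfg, {0: 2})
    with pytest.raises(ValueError, match="mixed"):
        assemble_dataset([some, other], task="binary")


def test_split_ninety_ten_reproduces_totals():
    cfg = SynthConfig(n_channels=1, sfreq=4.0, seed=0)
    es = generate_epoch_set(cfg, {0: 3895, 1: 3034, 2: 750, 3: 111})
    assert es.n_epochs == 7790
    train, test = train_test_split(es, 0.9, seed=0)
    assert (train.n_epochs, test.n_epochs) == (7011, 779)


def test_split_even_and_partition_property():
    cfg = SynthConfig(n_channels=1, sfreq=4.0, seed=0)
    es = generate_epoch_set(cfg, {0: 5, 1: 5})
    # tag epochs so set membership is visible after shuffling
    es.x[:, 0, 0] = np.arange(10)
    for seed in range(10):
        train, test = train_test_split(es, 0.5, seed=seed)
        assert (train.n_epochs, test.n_epochs) == (5, 5)
        tags = np.concatenate([train.x[:, 0, 0], test.x[:, 0, 0]])
        assert sorted(tags.tolist()) == list(range(10))


def test_split_stratified_option_preserves_class_fractions():
    cfg = SynthConfig(n_channels=1, sfreq=4.0, seed=0)
    es = generate_epoch_set(cfg, {0: 100, 1: 50})
    train, test = train_test_split(es, 0.8, seed=1, stratify=True)
    assert train.class_counts() == {0: 80, 1: 40}
    assert test.class_counts() == {0: 20, 1: 10}


def test_split_empty_errors():
    cfg = SynthConfig(n_channels=1, sfreq=4.0, seed=0)
    es = generate_epoch_set(cfg, {0: 0})
    with pytest.raises(ValueError):
        train_test_split(es, 0.9, seed=0)


def test_save_load_round_trip(tmp_path):
    cfg = SynthConfig(n_channels=3, sfreq=20.0, seed=9)
    for counts in ({0: 3}, {0: 0}):
        es = generate_epoch_set(cfg, counts)
        save_epochs(es, tmp_path / f"n{es.n_epochs}")
        back = load_epochs(tmp_path / f"n{es.n_epochs}")
        assert np.array_equal(back.x, es.x)
        assert np.array_equal(back.y, es.y)
        assert back.sfreq == es.sfreq
        assert back.label_map == es.label_map


def test_save_load_randomized_tensors(tmp_path):
    for seed in range(10):
        rng = np.random.default_rng(seed)
        es = EpochSet(rng.standard_normal((4, 2, 5)), rng.integers(0, 4, 4), sfreq=5.0)
        save_epochs(es, tmp_path / str(seed))
        back = load_epochs(tmp_path / str(seed))
        assert np.array_equal(back.x, es.x) and np.array_equal(back.y, es.y)
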