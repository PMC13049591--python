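"""Shared fixtures: small synthetic epoch sets kept cheap to generate."""

import numpy as np
import pytest

from seizurekit.preprocess import assemble_dataset, train_test_split
from seizurekit.normalize import apply_stats, fit_stats
from seizurekit.synth import SynthConfig, generate_epoch_set


@pytest.fixture(scope="session")
def small_binary_sets():
    """Standardized binary train/test sets at a small size (C=4, T=50)."""
    cfg = SynthConfig(n_channels=4, sfreq=50.0, record_len_s=10.0, seed=21)
    es = generate_epoch_set(cfg, {0: 80, 2: 80})
    ds = assemble_dataset([es], task="binary")
    train, test = train_test_split(ds, 0.75, seed=4)
    stats = fit_stats(train)
    return apply_stats(train, stats), apply_stats(test, stats), stats


@pytest.fixture(scope="session")
def separable_fixture():
    """The scaled-down two-class learning fixture: >=200 one-second
    19-channel epochs per class (normal vs electrographic), standardized
    with train-only statistics."""
    cfg = SynthConfig(seed=11)
    es = generate_epoch_set(cfg, {0: 260, 2: 260})
    ds = assemble_dataset([es], task="binary")
    train, test = train_test_split(ds, 0.77, seed=3)
    stats = fit_stats(train)
    return apply_stats(train, stats), apply_stats(test, stats)
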