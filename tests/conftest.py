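"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from erders_bmi import (
    SynthConfig,
    TrialTimeline,
    generate_recording,
    preprocess_pipeline,
)

FEATURE_WINDOW = (4.0, 7.0)


def make_session(classes, n_per_class, seed, **overrides):
    """Generate, filter and epoch one synthetic session."""
    cfg = SynthConfig(
        classes=classes, n_trials_per_class=n_per_class, seed=seed, **overrides
    )
    rec, events, truth = generate_recording(cfg)
    epochs = preprocess_pipeline(rec, events)
    return cfg, rec, events, truth, epochs


def feature_data(epochs, window=FEATURE_WINDOW):
    """Band+window-restricted retained trials and labels for CSP fitting."""
    data = epochs.data[:, :, epochs.clock_slice(window)][epochs.retained()]
    labels = epochs.labels[epochs.retained()]
    return data, labels


@pytest.fixture(scope="session")
def small_session():
    """30 trials/class, left hand vs both feet: the workhorse fixture."""
    return make_session(("left_hand", "both_feet"), 30, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_session):
    return small_session[1]


@pytest.fixture(scope="session")
def small_epochs(small_session):
    return small_session[4]


@pytest.fixture(scope="session")
def timeline():
    return TrialTimeline()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
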