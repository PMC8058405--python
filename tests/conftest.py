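"""Shared fixtures: small synthetic sessions generated once per run."""

from __future__ import annotations

import numpy as np
import pytest

import lamstate as ls
from lamstate import behavior


def make_labeled_session(**overrides):
    """Generate a session and fill in trial state labels (analysis rule)."""
    params = ls.GeneratorParams(**overrides)
    session, truth = ls.generate_session(params)
    smoothed = behavior.smooth_running(session.running)
    labeling = behavior.label_trials(session.trials, smoothed)
    session.trials = behavior.apply_labels(session.trials, labeling)
    return session, truth, labeling


@pytest.fixture(scope="session")
def small_session():
    """30 units, 30 trials/combo, with LFP and pupil; labeled."""
    session, truth, labeling = make_labeled_session(
        n_units=30, n_trials_per_combo=30, seed=7
    )
    return session, truth, labeling


@pytest.fixture(scope="session")
def rich_session():
    """100 units, 100 trials/combo, no LFP; labeled and included."""
    seed = 0
    while True:
        session, truth, labeling = make_labeled_session(
            n_units=100, n_trials_per_combo=100, seed=seed,
            include_lfp=False, include_pupil=False,
        )
        if labeling.included:
            return session, truth, labeling
        seed += 1


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
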