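"""Shared synthetic fixtures (session-scoped to amortize simulation cost)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from attnrhythm.attention import attentional_vector
from attnrhythm.design import enumerate_design
from attnrhythm.encoding import invert_model, train_encoding_model
from attnrhythm.synth import (
    AttentionProcessSpec,
    make_forward_model,
    sample_attention_process,
    simulate_decision_session,
    simulate_localizer,
)

FS = 400.0
STIM_DURATION = 3.8


@pytest.fixture(scope="session")
def fm():
    return make_forward_model(24, seed=7)


@pytest.fixture(scope="session")
def localizer(fm):
    return simulate_localizer(fm, n_blocks=6, snr=1.0, seed=11)


@pytest.fixture(scope="session")
def trained_model(localizer):
    return train_encoding_model(localizer, training_window=(0.14, 0.17))


@pytest.fixture(scope="session")
def decision_session(fm):
    design = enumerate_design()
    return simulate_decision_session(
        design, fm, AttentionProcessSpec(), n_trials=60, seed=13
    )


@pytest.fixture(scope="session")
def decision_trace(trained_model, decision_session):
    epochs, _, _ = decision_session
    return attentional_vector(invert_model(trained_model, epochs))


def make_ground_truth_events(spec: AttentionProcessSpec, n_trials: int,
                             seed: int, duration: float = STIM_DURATION,
                             fs: float = FS) -> pd.DataFrame:
    """Event table straight from the latent process (no sensor stage)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_trials):
        p = sample_attention_process(spec, duration, fs, rng)
        for t, lab, lc in zip(p.event_times, p.event_labels, p.event_loci):
            rows.append(dict(trial=i, onset=t, locus=lc, label=lab,
                             source="ground_truth"))
    return pd.DataFrame(rows)


def make_poisson_events(n_trials: int, rate: float, seed: int,
                        duration: float = STIM_DURATION,
                        fs: float = FS) -> pd.DataFrame:
    """Temporally unstructured (homogeneous Poisson) event trains."""
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * fs))
    rows = []
    for i in range(n_trials):
        n = rng.poisson(rate * duration)
        for s in np.unique(rng.integers(0, n_samples, size=n)):
            rows.append(dict(trial=i, onset=s / fs,
                             locus=float(rng.choice([0.0, 120.0, 240.0])),
                             label="", source="ground_truth"))
    return pd.DataFrame(rows)
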