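"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import icptrack as it
from icptrack.preprocess import preprocess_pulse


@pytest.fixture(scope="session")
def default_model():
    return it.PulseGMM.default()


@pytest.fixture(scope="session")
def short_sequence(default_model):
    """120-beat sequence with default sine dynamics (fixed seed)."""
    return it.generate_sequence(default_model, n_pulses=120, seed=11)


@pytest.fixture(scope="session")
def patient_set():
    """Four synthetic patients (independent model draws), 75 beats each."""
    rng = np.random.default_rng(202)
    return [
        it.generate_sequence(
            it.sample_patient_model(rng), n_pulses=75, seed=300 + i, patient_id=f"p{i}"
        )
        for i in range(4)
    ]


def flatten_beats(sequences):
    """(features, latency targets, pulses) for every available beat."""
    X, Y, pulses = [], [], []
    for s in sequences:
        for i in s.available_indices():
            X.append(preprocess_pulse(s.pulses[i]).vector)
            a = s.annotations[i]
            Y.append(np.where(a.missing, np.nan, a.latencies_ms))
            pulses.append(s.pulses[i])
    return np.vstack(X), np.vstack(Y), pulses


@pytest.fixture(scope="session")
def patient_beats(patient_set):
    return flatten_beats(patient_set)
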