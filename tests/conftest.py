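"""Shared fixtures: everything is generated, nothing is loaded from disk."""

from __future__ import annotations

import numpy as np
import pytest

from canicoh import stimulus, synth


@pytest.fixture(scope="session")
def call_train_2hz():
    return synth.gen_call_sequence(
        synth.CallTrainSpec(rate_hz=2.0, duration_s=10.0, jitter_sd_s=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def prosodic_words():
    """Five synthetic words with a mild F0 contour (enough prosody to flatten)."""
    return [
        synth.gen_word(n, 4.0, f0_hz=220.0, f0_excursion=0.05)
        for n in (2, 1, 2, 2, 1)
    ]


@pytest.fixture(scope="session")
def base_stream(prosodic_words):
    return stimulus.build_stream(prosodic_words, seed=3)


@pytest.fixture(scope="session")
def sine_envelope_2p5hz():
    """2 s stimulus envelope at 100 Hz with a 2.5 Hz modulation."""
    sr = 100.0
    t = np.arange(int(2.0 * sr)) / sr
    return (1.0 + 0.5 * np.sin(2 * np.pi * 2.5 * t)), sr


@pytest.fixture(scope="session")
def coupled_epochs(sine_envelope_2p5hz):
    env, sr = sine_envelope_2p5hz
    return synth.gen_locked_eeg(
        synth.LockedEEGSpec(
            envelope=env, coupling=2.0, n_trials=12, sample_rate=sr, seed=5
        )
    )
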