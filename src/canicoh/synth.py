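"""Seeded synthetic fixtures: call trains, command-word streams, envelope-locked
EEG epochs, and paired speaker tables.

Every generator takes an explicit integer seed and is bitwise deterministic,
so downstream analyses can be tested against known ground truth without any
recorded data. Ground-truth parameters are stored in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .audio import AudioSequence
from .eeg import EpochSet
from .errors import InvalidInputError, InvalidSpecError

__all__ = [
    "CallTrainSpec",
    "LockedEEGSpec",
    "gen_call_sequence",
    "gen_word",
    "gen_word_stream",
    "gen_locked_eeg",
    "gen_paired_speech_table",
]


# ---------------------------------------------------------------------------
# call trains
# ---------------------------------------------------------------------------


@dataclass
class CallTrainSpec:
    """Parameters of a pulse-train vocal sequence with a known repetition rate.

    ``jitter_sd_s`` perturbs each inter-call interval with Gaussian noise;
    with zero jitter the onsets are exactly ``1/rate_hz`` apart.
    """

    rate_hz: float
    duration_s: float
    carrier_hz: float = 400.0
    call_dur_s: float = 0.15
    jitter_sd_s: float = 0.0
    sample_rate: float = 8000.0
    seed: int = 0

    def validate(self) -> None:
        if self.rate_hz <= 0:
            raise InvalidSpecError(f"rate_hz must be > 0, got {self.rate_hz}")
        if self.call_dur_s >= 1.0 / self.rate_hz:
            raise InvalidSpecError(
                f"calls overlap: call_dur_s={self.call_dur_s} >= "
                f"1/rate_hz={1.0 / self.rate_hz:.4f}"
            )
        if self.duration_s < 3.0 / self.rate_hz:
            raise InvalidSpecError(
                f"duration_s={self.duration_s} holds fewer than 3 calls at "
                f"{self.rate_hz} Hz"
            )


def gen_call_sequence(spec: CallTrainSpec) -> AudioSequence:
    """Gaussian-windowed carrier bursts at a known mean repetition rate.

    The call envelope is a Gaussian whose full width at half maximum equals
    ``call_dur_s``, which keeps the amplitude envelope smooth and free of
    spectral splatter.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    n = int(round(spec.duration_s * sr))
    period = 1.0 / spec.rate_hz
    # first onset half a period in, so the train is centred in the clip
    onsets = np.arange(period / 2.0, spec.duration_s - spec.call_dur_s / 2.0, period)
    if spec.jitter_sd_s > 0:
        onsets = onsets + rng.normal(0.0, spec.jitter_sd_s, size=onsets.size)
    t = np.arange(n) / sr
    x = np.zeros(n)
    sigma = spec.call_dur_s / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for onset in onsets:
        centre = onset + spec.call_dur_s / 2.0
        x += np.exp(-((t - centre) ** 2) / (2.0 * sigma**2)) * np.sin(
            2.0 * np.pi * spec.carrier_hz * (t - onset)
        )
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return AudioSequence(
        samples=x,
        sample_rate=sr,
        meta={
            "generator": "call_train",
            "true_rate_hz": spec.rate_hz,
            "carrier_hz": spec.carrier_hz,
            "call_dur_s": spec.call_dur_s,
            "jitter_sd_s": spec.jitter_sd_s,
            "onsets_s": [float(o) for o in onsets],
            "seed": spec.seed,
        },
    )


# ---------------------------------------------------------------------------
# command-word streams
# ---------------------------------------------------------------------------


def _harmonic_voice(
    f0_inst_hz: np.ndarray, sample_rate: float, n_harmonics: int = 4
) -> np.ndarray:
    """Harmonic source with instantaneous F0 track (1/k amplitude roll-off)."""
    phase = 2.0 * np.pi * np.cumsum(f0_inst_hz) / sample_rate
    x = np.zeros_like(phase)
    for k in range(1, n_harmonics + 1):
        x += np.sin(k * phase) / k
    return x


def gen_word(
    n_syllables: int,
    syllable_rate_hz: float,
    sample_rate: float = 8000.0,
    f0_hz: float = 220.0,
    f0_excursion: float = 0.0,
    n_harmonics: int = 4,
) -> AudioSequence:
    """One synthetic "word": Hann-enveloped voiced syllables at a fixed rate.

    ``f0_excursion`` adds a half-sine F0 contour over the word (fractional
    peak deviation from ``f0_hz``), giving prosody the stimulus module can
    flatten, reverse or re-impose.
    """
    if n_syllables < 1:
        raise InvalidSpecError("n_syllables must be >= 1")
    if syllable_rate_hz <= 0 or f0_hz <= 0:
        raise InvalidSpecError("syllable_rate_hz and f0_hz must be > 0")
    sr = sample_rate
    syll_n = int(round(sr / syllable_rate_hz))
    n = syll_n * n_syllables
    t = np.arange(n) / sr
    dur = n / sr
    f0_inst = f0_hz * (1.0 + f0_excursion * np.sin(np.pi * t / dur))
    voice = _harmonic_voice(f0_inst, sr, n_harmonics=n_harmonics)
    env = np.zeros(n)
    win = np.hanning(syll_n)
    for s in range(n_syllables):
        env[s * syll_n : (s + 1) * syll_n] = win
    x = voice * env
    x = 0.9 * x / np.max(np.abs(x))
    return AudioSequence(
        samples=x,
        sample_rate=sr,
        meta={
            "generator": "word",
            "n_syllables": n_syllables,
            "syllable_rate_hz": syllable_rate_hz,
            "f0_hz": f0_hz,
            "f0_excursion": f0_excursion,
            "syllable_onsets_s": [s * syll_n / sr for s in range(n_syllables)],
        },
    )


def gen_word_stream(
    n_words: int,
    syllable_rate_hz: float = 4.0,
    silence_ms: float = 300.0,
    silence_jitter_ms: float = 50.0,
    seed: int = 0,
    sample_rate: float = 8000.0,
    f0_hz: float = 220.0,
    f0_excursion: float = 0.0,
    syllable_pattern: tuple[int, ...] = (2, 1, 2, 2, 1),
) -> AudioSequence:
    """Stream of synthetic words separated by uniform-jittered silences.

    Silences are drawn uniformly from ``silence_ms ± silence_jitter_ms``
    (the ``±`` read as a half-range). Word and syllable onsets are recorded
    in ``meta['word_onsets_s']`` / ``meta['syllable_onsets_s']``.
    """
    if n_words < 1:
        raise InvalidSpecError("n_words must be >= 1")
    if syllable_rate_hz <= 0:
        raise InvalidSpecError("syllable_rate_hz must be > 0")
    if silence_jitter_ms < 0 or silence_ms - silence_jitter_ms < 0:
        raise InvalidSpecError("silence window must be non-negative")
    rng = np.random.default_rng(seed)
    sr = sample_rate
    words = [
        gen_word(
            n_syllables=syllable_pattern[i % len(syllable_pattern)],
            syllable_rate_hz=syllable_rate_hz,
            sample_rate=sr,
            f0_hz=f0_hz,
            f0_excursion=f0_excursion,
        )
        for i in range(n_words)
    ]
    gaps_s = (
        rng.uniform(
            silence_ms - silence_jitter_ms,
            silence_ms + silence_jitter_ms,
            size=max(n_words - 1, 0),
        )
        / 1000.0
    )
    pieces: list[np.ndarray] = []
    word_onsets: list[float] = []
    syll_onsets: list[float] = []
    cursor = 0
    for i, w in enumerate(words):
        word_onsets.append(cursor / sr)
        syll_onsets.extend(cursor / sr + np.asarray(w.meta["syllable_onsets_s"]))
        pieces.append(w.samples)
        cursor += w.n_samples
        if i < n_words - 1:
            gap_n = int(round(gaps_s[i] * sr))
            pieces.append(np.zeros(gap_n))
            cursor += gap_n
    x = np.concatenate(pieces)
    return AudioSequence(
        samples=x,
        sample_rate=sr,
        meta={
            "generator": "word_stream",
            "n_words": n_words,
            "syllable_rate_hz": syllable_rate_hz,
            "silence_ms": silence_ms,
            "silence_jitter_ms": silence_jitter_ms,
            "gaps_s": [float(g) for g in gaps_s],
            "word_onsets_s": word_onsets,
            "syllable_onsets_s": syll_onsets,
            "f0_hz": f0_hz,
            "f0_excursion": f0_excursion,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# envelope-locked EEG
# ---------------------------------------------------------------------------


@dataclass
class LockedEEGSpec:
    """Trials = ``coupling`` x band-passed, lag-shifted stimulus envelope plus
    unit-variance 1/f^``noise_exponent`` background noise.

    ``coupling = 0`` yields pure noise independent of the envelope.
    ``pre_s`` seconds of noise-only baseline are prepended when requested
    (epoch time zero stays at stimulus onset).
    """

    envelope: np.ndarray = field(default_factory=lambda: np.zeros(0))
    coupling: float = 1.0
    lag_s: float = 0.1
    band_hz: tuple[float, float] = (1.0, 7.0)
    n_trials: int = 20
    noise_exponent: float = 1.0
    sample_rate: float = 500.0
    seed: int = 0
    pre_s: float = 0.0

    def validate(self) -> None:
        if np.asarray(self.envelope).size == 0:
            raise InvalidInputError("envelope is empty")
        if self.n_trials < 1:
            raise InvalidSpecError("n_trials must be >= 1")
        if self.coupling < 0:
            raise InvalidSpecError("coupling must be >= 0")


def one_over_f_noise(
    n: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def gen_locked_eeg(spec: LockedEEGSpec) -> EpochSet:
    """EEG epochs phase-locked to a stimulus envelope at a known coupling."""
    spec.validate()
    env = np.asarray(spec.envelope, dtype=np.float64)
    sr = spec.sample_rate
    lo, hi = spec.band_hz
    sos = butter(4, [lo, hi], btype="band", fs=sr, output="sos")
    locked = sosfiltfilt(sos, env - env.mean())
    lag_n = int(round(spec.lag_s * sr))
    locked = np.roll(locked, lag_n)
    sd = np.std(locked)
    if sd > 0:
        locked = locked / sd
    pre_n = int(round(spec.pre_s * sr))
    n_total = pre_n + env.size
    rng = np.random.default_rng(spec.seed)
    trials = np.empty((spec.n_trials, n_total))
    for i in range(spec.n_trials):
        noise = one_over_f_noise(n_total, spec.noise_exponent, rng)
        trials[i] = noise
        trials[i, pre_n:] += spec.coupling * locked
    return EpochSet(
        trials=trials,
        sample_rate=sr,
        t0_s=-spec.pre_s,
        condition="synthetic",
        meta={
            "generator": "locked_eeg",
            "coupling": spec.coupling,
            "lag_s": spec.lag_s,
            "band_hz": list(spec.band_hz),
            "noise_exponent": spec.noise_exponent,
            "seed": spec.seed,
        },
    )


# ---------------------------------------------------------------------------
# paired speaker tables
# ---------------------------------------------------------------------------


def gen_paired_speech_table(
    n_pairs: int,
    rate_effect_hz: float = 1.0,
    sd_hz: float = 1.0,
    seed: int = 0,
    f0_effect_hz: float = 40.0,
    f0_sd_hz: float = 30.0,
) -> pd.DataFrame:
    """Paired per-speaker table of ADS vs DDS speech rate and mean F0.

    ``rate_effect_hz`` is the mean of the paired difference ADS − DDS (the
    pet-directed register is the slower one when positive); differences are
    Normal(rate_effect_hz, sd_hz). DDS F0 exceeds ADS F0 by
    Normal(f0_effect_hz, f0_sd_hz).
    """
    if n_pairs < 2:
        raise InvalidSpecError(f"n_pairs must be >= 2, got {n_pairs}")
    rng = np.random.default_rng(seed)
    ads_rate = rng.normal(4.0, 0.8, size=n_pairs)
    dds_rate = ads_rate - rng.normal(rate_effect_hz, sd_hz, size=n_pairs)
    ads_f0 = rng.normal(200.0, 25.0, size=n_pairs)
    dds_f0 = ads_f0 + rng.normal(f0_effect_hz, f0_sd_hz, size=n_pairs)
    return pd.DataFrame(
        {
            "speaker": [f"S{i + 1:02d}" for i in range(n_pairs)],
            "ads_rate_hz": ads_rate,
            "dds_rate_hz": dds_rate,
            "ads_f0_hz": ads_f0,
            "dds_f0_hz": dds_f0,
        }
    )
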