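"""Cerebro-acoustic coherence: frequency-resolved phase locking between an
EEG channel and a stimulus amplitude envelope, with its surrogate null.

Coherence pools Morlet cross-spectral terms over time points (within an
analysis window) and trials before a single normalisation:

    C(f) = |sum_{trials,t} Sxy(t,f)| / sqrt(sum Sxx * sum Syy)

Pooling time points is what keeps single-trial coherence strictly below 1
unless the phase relation is constant. The chance floor is estimated by
re-pairing trials with randomly drawn, circularly shifted envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg import EpochSet
from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    InvalidInputError,
)
from .wavelet import cwt_morlet

__all__ = [
    "CoherenceSpectrum",
    "NullCoherence",
    "BandSummary",
    "default_grid",
    "cacoh_spectrum",
    "surrogate_null",
    "summarize",
]

DELTA_BAND = (1.0, 3.0)
THETA_BAND = (4.0, 7.0)


def default_grid(step_hz: float = 0.1) -> np.ndarray:
    """The 1–20 Hz analysis grid (0.1 Hz steps by default)."""
    return np.arange(1.0, 20.0 + step_hz / 2.0, step_hz)


@dataclass
class CoherenceSpectrum:
    """C(f) on a frequency grid, for a given analysis window."""

    freqs_hz: np.ndarray
    coh: np.ndarray
    window_s: tuple[float, float]
    n_trials: int

    def __post_init__(self) -> None:
        self.coh = np.asarray(self.coh, dtype=np.float64)
        if np.any(self.coh < -1e-12) or np.any(self.coh > 1.0 + 1e-9):
            raise InvalidInputError("coherence outside [0, 1]")
        self.coh = np.clip(self.coh, 0.0, 1.0)


@dataclass
class NullCoherence:
    """Per-frequency mean/SD of coherence under randomised envelope pairings."""

    freqs_hz: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_runs: int
    seed: int


@dataclass
class BandSummary:
    """Band means and rate-centred coherence values."""

    delta: float
    theta: float
    word_coh: float | None = None
    syll_coh: float | None = None


def _window_tfr(
    epochs_data: np.ndarray,
    envelope: np.ndarray,
    sample_rate: float,
    freqs: np.ndarray,
    t0_s: float,
    window_s: tuple[float, float],
    n_cycles: float,
    time_step_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Morlet transforms of trials and envelope restricted to the window."""
    n_times = epochs_data.shape[1]
    times = t0_s + np.arange(n_times) / sample_rate
    w0, w1 = window_s
    if w0 < times[0] - 1e-9 or w1 > times[-1] + 1e-9:
        raise InvalidInputError(f"window {window_s} not covered by epochs")
    env = np.asarray(envelope, dtype=np.float64)
    if env.size < n_times:
        raise InvalidInputError("envelope does not cover the epoch")
    env = env[:n_times]
    step = max(int(round(time_step_s * sample_rate)), 1)
    sel = np.where((times >= w0 - 1e-9) & (times <= w1 + 1e-9))[0][::step]
    x = epochs_data - epochs_data.mean(axis=-1, keepdims=True)
    wx = cwt_morlet(x, sample_rate, freqs, n_cycles=n_cycles,
                    mode="circular")[..., sel]
    wy = cwt_morlet(env - env.mean(), sample_rate, freqs, n_cycles=n_cycles,
                    mode="circular")[..., sel]
    return wx, wy


def cacoh_spectrum(
    epochs: EpochSet,
    envelope: np.ndarray,
    freqs_hz: np.ndarray | None = None,
    window_s: tuple[float, float] = (0.6, 1.3),
    n_cycles: float = 7.0,
    time_step_s: float = 0.01,
) -> CoherenceSpectrum:
    """Cerebro-acoustic coherence spectrum of an epoch set and an envelope.

    ``envelope`` must be sampled at the epoch rate and aligned with the
    epoch start (``epochs.t0_s``). Only kept trials enter the estimate.
    """
    kept = epochs.kept
    if kept.shape[0] < 2:
        raise InsufficientDataError("coherence needs at least 2 trials")
    freqs = default_grid() if freqs_hz is None else np.asarray(freqs_hz, float)
    wx, wy = _window_tfr(
        kept, envelope, epochs.sample_rate, freqs, epochs.t0_s, window_s,
        n_cycles, time_step_s,
    )
    sxy = np.sum(wx * np.conj(wy[np.newaxis]), axis=(0, 2))
    sxx = np.sum(np.abs(wx) ** 2, axis=(0, 2))
    syy = kept.shape[0] * np.sum(np.abs(wy) ** 2, axis=1)
    denom = np.sqrt(sxx * syy)
    coh = np.where(denom > 0, np.abs(sxy) / np.maximum(denom, 1e-300), 0.0)
    return CoherenceSpectrum(
        freqs_hz=freqs, coh=coh, window_s=window_s, n_trials=kept.shape[0]
    )


def surrogate_null(
    epochs: EpochSet,
    envelope_pool: list[np.ndarray],
    n_runs: int = 100,
    seed: int = 0,
    freqs_hz: np.ndarray | None = None,
    window_s: tuple[float, float] = (0.6, 1.3),
    n_cycles: float = 7.0,
    time_step_s: float = 0.01,
) -> NullCoherence:
    """Chance-level coherence from randomised envelope pairings.

    Each run pairs every trial with an envelope drawn at random from the
    pool and circularly shifted by a random offset; the per-frequency mean
    and SD over runs define the null. Because the transform is circular,
    the shifted envelope's transform is exactly the rolled transform, so
    pool envelopes are transformed only once.
    """
    if not envelope_pool:
        raise InvalidInputError("empty envelope pool")
    kept = epochs.kept
    if kept.shape[0] < 2:
        raise InsufficientDataError("coherence needs at least 2 trials")
    rng = np.random.default_rng(seed)
    freqs = default_grid() if freqs_hz is None else np.asarray(freqs_hz, float)
    sr = epochs.sample_rate
    n_times = kept.shape[1]

    # precompute trial transforms once; only the envelope side is randomised
    times = epochs.t0_s + np.arange(n_times) / sr
    w0, w1 = window_s
    step = max(int(round(time_step_s * sr)), 1)
    sel = np.where((times >= w0 - 1e-9) & (times <= w1 + 1e-9))[0][::step]
    x = kept - kept.mean(axis=-1, keepdims=True)
    wx = cwt_morlet(x, sr, freqs, n_cycles=n_cycles, mode="circular")[..., sel]
    sxx = np.sum(np.abs(wx) ** 2, axis=(0, 2))

    pool = []
    for e in envelope_pool:
        e = np.asarray(e, dtype=np.float64)[:n_times]
        if e.size < n_times:
            raise InvalidInputError("pool envelope does not cover the epoch")
        pool.append(
            cwt_morlet(e - e.mean(), sr, freqs, n_cycles=n_cycles, mode="circular")
        )

    runs = np.empty((n_runs, freqs.size))
    for run in range(n_runs):
        sxy = np.zeros(freqs.size, dtype=np.complex128)
        syy = np.zeros(freqs.size)
        for i in range(kept.shape[0]):
            wfull = pool[rng.integers(len(pool))]
            shift = int(rng.integers(n_times))
            wy = np.roll(wfull, shift, axis=-1)[..., sel]
            sxy += np.sum(wx[i] * np.conj(wy), axis=-1)
            syy += np.sum(np.abs(wy) ** 2, axis=-1)
        denom = np.sqrt(sxx * syy)
        runs[run] = np.where(denom > 0, np.abs(sxy) / np.maximum(denom, 1e-300), 0.0)
    return NullCoherence(
        freqs_hz=freqs,
        mean=runs.mean(axis=0),
        sd=runs.std(axis=0),
        n_runs=n_runs,
        seed=seed,
    )


def band_mean(spec: CoherenceSpectrum, band: tuple[float, float]) -> float:
    """Arithmetic mean of C(f) over a closed frequency band."""
    lo, hi = band
    mask = (spec.freqs_hz >= lo - 1e-9) & (spec.freqs_hz <= hi + 1e-9)
    if not mask.any():
        raise InvalidArgumentError(f"band {band} outside the grid")
    return float(spec.coh[mask].mean())


def summarize(
    spec: CoherenceSpectrum,
    word_rate_hz: float | None = None,
    syll_rate_hz: float | None = None,
    summary_step_hz: float = 0.5,
) -> BandSummary:
    """Delta/theta band means plus rate-centred coherence values.

    Rate-centred values are means over a ``± summary_step_hz`` window on a
    ``summary_step_hz``-spaced grid (interpolated from the analysis grid).
    """

    def rate_value(rate: float) -> float:
        if not spec.freqs_hz[0] <= rate <= spec.freqs_hz[-1]:
            raise InvalidArgumentError(f"rate {rate} Hz outside the grid")
        grid = np.arange(rate - summary_step_hz, rate + summary_step_hz + 1e-9,
                         summary_step_hz)
        grid = grid[(grid >= spec.freqs_hz[0]) & (grid <= spec.freqs_hz[-1])]
        return float(np.mean(np.interp(grid, spec.freqs_hz, spec.coh)))

    return BandSummary(
        delta=band_mean(spec, DELTA_BAND),
        theta=band_mean(spec, THETA_BAND),
        word_coh=None if word_rate_hz is None else rate_value(word_rate_hz),
        syll_coh=None if syll_rate_hz is None else rate_value(syll_rate_hz),
    )
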