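"""Envelope-based rhythm estimation, spectral features and the
potential-for-identity-coding (PIC) statistic for vocal sequences.

The rhythm of a sequence is read as the highest peak of the Morlet
modulation spectrum of its Hilbert amplitude envelope — a unit-counting-free
estimate that works across call types of very different length and shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .audio import AudioSequence
from .errors import (
    DegenerateVarianceError,
    InsufficientDurationError,
    InvalidInputError,
    NoPeakError,
    UnvoicedInputError,
)
from .wavelet import cwt_power

__all__ = [
    "Envelope",
    "RhythmEstimate",
    "SpectralFeatures",
    "PICResult",
    "compute_envelope",
    "envelope_rate",
    "dominant_frequency",
    "f0_contour",
    "pitch_track",
    "pic_index",
    "small_sample_cv",
]


@dataclass
class Envelope:
    """Non-negative amplitude envelope of a waveform."""

    values: np.ndarray
    sample_rate: float
    lowpass_hz: float
    filter_order: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise InvalidInputError("envelope values must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sample_rate


@dataclass
class RhythmEstimate:
    """Peak modulation frequency plus the spectrum it came from."""

    peak_hz: float
    freqs_hz: np.ndarray
    power: np.ndarray
    search_range_hz: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.search_range_hz
        if not lo <= self.peak_hz <= hi:
            raise InvalidInputError("peak_hz outside search range")


@dataclass
class SpectralFeatures:
    """Dominant frequency and/or fundamental-frequency summary of a sequence."""

    dominant_hz: float | None = None
    f0_mean_hz: float | None = None
    f0_iqr_hz: float | None = None


@dataclass
class PICResult:
    """Between/within coefficient-of-variation ratio of an acoustic feature."""

    cv_between: float
    cv_within_by_individual: list[float]
    pic: float


# ---------------------------------------------------------------------------
# envelope and rhythm
# ---------------------------------------------------------------------------


def compute_envelope(
    audio: AudioSequence,
    band_hz: tuple[float, float] = (100.0, 10_000.0),
    env_lowpass_hz: float = 20.0,
    order: int = 4,
) -> Envelope:
    """Hilbert amplitude envelope after band-pass pre-filtering.

    Defaults follow the vocal-sequence settings (0.1–10 kHz band, 20 Hz
    fourth-order envelope low-pass); word streams use 30 Hz / order 8. All
    filtering is zero-phase (forward-backward Butterworth), and the filtered
    envelope is clipped at zero to preserve non-negativity.
    """
    if audio.n_samples == 0:
        raise InvalidInputError("empty audio")
    nyq = audio.sample_rate / 2.0
    if env_lowpass_hz >= nyq:
        raise InvalidInputError(f"envelope cutoff {env_lowpass_hz} >= Nyquist {nyq}")
    x = audio.samples
    lo, hi = band_hz
    hi = min(hi, 0.99 * nyq)
    if lo > 0 and hi > lo:
        sos = butter(4, [lo, hi], btype="band", fs=audio.sample_rate, output="sos")
        x = sosfiltfilt(sos, x)
    env = np.abs(hilbert(x))
    sos_lp = butter(order, env_lowpass_hz, btype="low", fs=audio.sample_rate,
                    output="sos")
    env = sosfiltfilt(sos_lp, env)
    return Envelope(
        values=np.clip(env, 0.0, None),
        sample_rate=audio.sample_rate,
        lowpass_hz=env_lowpass_hz,
        filter_order=order,
    )


def envelope_rate(
    env: Envelope,
    search_range_hz: tuple[float, float] = (0.5, 20.0),
    grid_step_hz: float = 0.05,
    n_cycles: float = 6.0,
    decimate_to_hz: float = 200.0,
) -> RhythmEstimate:
    """Peak modulation frequency of a (mean-removed) amplitude envelope.

    The envelope is decomposed with Morlet wavelets on a fixed grid, power is
    averaged over time, and the peak within ``search_range_hz`` is returned;
    exact ties break toward the lower frequency (argmax of an ascending
    grid). The estimate is invariant to positive amplitude scaling.
    """
    lo, hi = search_range_hz
    if lo <= 0:
        raise InvalidInputError("search range must start above 0 Hz")
    if env.duration_s < 2.0 / lo:
        raise InsufficientDurationError(
            f"envelope of {env.duration_s:.2f} s is shorter than 2 cycles "
            f"of {lo} Hz"
        )
    values = env.values
    sr = env.sample_rate
    if decimate_to_hz and sr > 2 * decimate_to_hz:
        step = int(sr // decimate_to_hz)
        values = values[::step]
        sr = sr / step
    x = values - values.mean()
    if np.max(np.abs(x)) < 1e-12 * max(np.max(np.abs(values)), 1e-300) or np.all(
        x == 0
    ):
        raise NoPeakError("flat envelope has no modulation peak")
    scale = np.max(np.abs(x))
    x = x / scale  # amplitude-scale invariance, and keeps power well-conditioned
    freqs = np.arange(lo, hi + grid_step_hz / 2.0, grid_step_hz)
    # L1-normalised wavelets: flat amplitude response across the grid, so the
    # arg-max is not skewed toward low frequencies by the 1/f energy factor
    power = cwt_power(x, sr, freqs, n_cycles=n_cycles, norm="l1").mean(axis=-1)
    peak_idx = int(np.argmax(power))
    return RhythmEstimate(
        peak_hz=float(freqs[peak_idx]),
        freqs_hz=freqs,
        power=power,
        search_range_hz=search_range_hz,
    )


def dominant_frequency(
    audio: AudioSequence, band_hz: tuple[float, float] = (50.0, 2000.0)
) -> float:
    """Frequency of the peak of the time-averaged magnitude spectrum in band."""
    if audio.duration_s < 0.1:
        raise InvalidInputError("audio must be at least 100 ms")
    sr = audio.sample_rate
    # average magnitude spectra over 50%-overlapping Hann segments
    nseg = min(audio.n_samples, int(sr))  # 1 s segments -> >= 1 Hz resolution
    hop = nseg // 2
    win = np.hanning(nseg)
    mags = []
    for start in range(0, audio.n_samples - nseg + 1, max(hop, 1)):
        seg = audio.samples[start : start + nseg] * win
        mags.append(np.abs(np.fft.rfft(seg)))
    mag = np.mean(mags, axis=0)
    freqs = np.fft.rfftfreq(nseg, d=1.0 / sr)
    lo, hi = band_hz
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise InvalidInputError(f"band {band_hz} outside spectrum")
    if np.max(mag[mask]) <= 1e-10 * max(np.max(mag), 1e-300) or np.max(mag) == 0:
        raise NoPeakError("silent input has no spectral peak")
    return float(freqs[mask][np.argmax(mag[mask])])


# ---------------------------------------------------------------------------
# pitch
# ---------------------------------------------------------------------------


def f0_contour(
    audio: AudioSequence,
    f0_range_hz: tuple[float, float] = (75.0, 600.0),
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    voicing_threshold: float = 0.45,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise F0 by normalised autocorrelation.

    Returns ``(frame_centre_times_s, f0_hz)`` with NaN in unvoiced frames.
    The lag of the autocorrelation maximum inside the F0 search range is
    refined by parabolic interpolation.
    """
    sr = audio.sample_rate
    lo, hi = f0_range_hz
    frame_n = int(round(frame_s * sr))
    hop_n = max(int(round(hop_s * sr)), 1)
    lag_min = max(int(np.floor(sr / hi)), 1)
    lag_max = int(np.ceil(sr / lo))
    if audio.n_samples < 3.0 * sr / lo:
        raise InvalidInputError(
            "audio shorter than 3 periods of the lowest F0 candidate"
        )
    times, f0s = [], []
    x = audio.samples
    global_peak = np.max(np.abs(x)) if x.size else 0.0
    for start in range(0, x.size - frame_n + 1, hop_n):
        frame = x[start : start + frame_n]
        frame = frame - frame.mean()
        e0 = np.dot(frame, frame)
        times.append((start + frame_n / 2.0) / sr)
        # silence gate: frames far below the global peak are unvoiced
        if e0 == 0 or np.max(np.abs(frame)) < 0.02 * global_peak:
            f0s.append(np.nan)
            continue
        ac = np.correlate(frame, frame, mode="full")[frame_n - 1 :]
        ac = ac / ac[0]
        hi_lag = min(lag_max, frame_n - 2)
        if hi_lag <= lag_min:
            f0s.append(np.nan)
            continue
        seg = ac[lag_min : hi_lag + 1]
        k = int(np.argmax(seg)) + lag_min
        if ac[k] < voicing_threshold:
            f0s.append(np.nan)
            continue
        # parabolic refinement around the peak lag
        if 1 <= k < ac.size - 1:
            y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            k_ref = k + float(np.clip(delta, -0.5, 0.5))
        else:
            k_ref = float(k)
        f0s.append(sr / k_ref)
    return np.asarray(times), np.asarray(f0s)


def pitch_track(
    audio: AudioSequence,
    f0_range_hz: tuple[float, float] = (75.0, 600.0),
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    voicing_threshold: float = 0.45,
) -> SpectralFeatures:
    """Mean and interquartile range of F0 over voiced frames."""
    _, f0 = f0_contour(
        audio,
        f0_range_hz=f0_range_hz,
        frame_s=frame_s,
        hop_s=hop_s,
        voicing_threshold=voicing_threshold,
    )
    voiced = f0[np.isfinite(f0)]
    if voiced.size == 0:
        raise UnvoicedInputError("no voiced frames found")
    q1, q3 = np.percentile(voiced, [25, 75])
    return SpectralFeatures(
        f0_mean_hz=float(np.mean(voiced)), f0_iqr_hz=float(q3 - q1)
    )


# ---------------------------------------------------------------------------
# potential for identity coding
# ---------------------------------------------------------------------------


def small_sample_cv(values: np.ndarray) -> float:
    """Coefficient of variation (%) with the small-sample correction
    ``(1 + 1/(4n))`` applied."""
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 2:
        raise InvalidInputError("CV needs at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise InvalidInputError("CV undefined for non-positive means")
    sd = values.std(ddof=1)
    return float(sd / mean * 100.0 * (1.0 + 1.0 / (4.0 * n)))


def pic_index(values_by_individual: dict[str, np.ndarray] | list) -> PICResult:
    """Potential-for-identity-coding ratio CVb / mean(CVw).

    ``CVw`` is the small-sample-corrected CV of each individual's values;
    ``CVb`` the corrected CV of the individual means. Values > 1 indicate
    individual distinctiveness of the feature.
    """
    if isinstance(values_by_individual, dict):
        groups = list(values_by_individual.values())
    else:
        groups = list(values_by_individual)
    if len(groups) < 2:
        raise InvalidInputError("PIC needs at least 2 individuals")
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    for g in groups:
        if g.size < 2:
            raise InvalidInputError("each individual needs at least 2 values")
        if g.mean() <= 0:
            raise InvalidInputError("feature means must be > 0")
    cvw = [small_sample_cv(g) for g in groups]
    mean_cvw = float(np.mean(cvw))
    if mean_cvw == 0:
        raise DegenerateVarianceError(
            "all within-individual variances are zero; PIC undefined"
        )
    means = np.asarray([g.mean() for g in groups])
    cvb = small_sample_cv(means)
    return PICResult(
        cv_between=cvb, cv_within_by_individual=cvw, pic=cvb / mean_cvw
    )
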