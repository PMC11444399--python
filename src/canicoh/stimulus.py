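"""Command-word stream construction and the speech-type x speech-rate
stimulus manipulations.

Three speech types are supported:

``normal``
    flatten-then-restore round trip of the pitch contour, so the control
    stream carries the same resynthesis artefacts as the altered ones;
``content_only``
    pitch contour flattened to a reference F0 and the per-word intensity
    contour time-reversed (prosody removed, words left forward);
``prosody_only``
    each word time-reversed in place (content destroyed), then the original
    per-word pitch and intensity contours re-imposed.

Pitch manipulation is a phase-warp resynthesis: the unwrapped Hilbert phase
of the fundamental band serves as an exact cumulative pitch contour, and a
monotone time warp maps the input phase track onto the target one. Because
warps between integral-matched contours are exact inverses of one another,
flatten->restore and reverse->reverse round trips cancel up to interpolation
error. Tempo change uses a phase-vocoder time-scale modification, which
changes duration without shifting pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, hilbert, sosfiltfilt

from .acoustics import compute_envelope, f0_contour
from .audio import AudioSequence
from .errors import (
    InsufficientDurationError,
    InvalidArgumentError,
    InvalidInputError,
)

__all__ = [
    "SPEECH_TYPES",
    "RATE_FACTORS",
    "WordStream",
    "build_stream",
    "apply_speech_type",
    "change_tempo",
    "stream_rates",
    "condition_grid",
]

SPEECH_TYPES = ("normal", "content_only", "prosody_only")
RATE_FACTORS = (1, 2, 4)

#: peak level words are normalised to before concatenation
_PEAK_DBFS = -2.0
#: gain excursion limit for intensity-contour manipulation
_MAX_GAIN_DB = 12.0


@dataclass
class WordStream:
    """A concatenated word stream plus its manipulation state."""

    audio: AudioSequence
    word_onsets_s: list[float]
    word_durs_s: list[float]
    speech_type: str = "normal"
    rate_factor: int = 1
    silence_spec: tuple[float, float] = (300.0, 50.0)  # mean ms, half-range ms
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.speech_type not in SPEECH_TYPES:
            raise InvalidArgumentError(f"unknown speech type {self.speech_type!r}")
        if self.rate_factor not in RATE_FACTORS:
            raise InvalidArgumentError(f"rate_factor must be one of {RATE_FACTORS}")
        onsets = np.asarray(self.word_onsets_s)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise InvalidInputError("word onsets must be strictly increasing")

    @property
    def n_words(self) -> int:
        return len(self.word_onsets_s)

    def word_slices(self) -> list[slice]:
        sr = self.audio.sample_rate
        out = []
        for onset, dur in zip(self.word_onsets_s, self.word_durs_s):
            a = int(round(onset * sr))
            b = min(a + int(round(dur * sr)), self.audio.n_samples)
            out.append(slice(a, b))
        return out


# ---------------------------------------------------------------------------
# stream construction
# ---------------------------------------------------------------------------


def build_stream(
    words: list[AudioSequence],
    silence_ms: float = 300.0,
    half_range_ms: float = 50.0,
    seed: int = 0,
    highpass_hz: float = 100.0,
) -> WordStream:
    """High-pass, peak-normalise and concatenate words with jittered silences.

    Each word is zero-phase high-pass filtered at ``highpass_hz`` and
    peak-normalised to −2 dBFS; silences are drawn uniformly from
    ``silence_ms ± half_range_ms``.
    """
    if not words:
        raise InvalidInputError("need at least one word")
    rates = {w.sample_rate for w in words}
    if len(rates) != 1:
        raise InvalidInputError(f"words have mixed sample rates: {sorted(rates)}")
    sr = words[0].sample_rate
    rng = np.random.default_rng(seed)
    sos = butter(4, highpass_hz, btype="high", fs=sr, output="sos")
    target_peak = 10.0 ** (_PEAK_DBFS / 20.0)

    pieces: list[np.ndarray] = []
    onsets: list[float] = []
    durs: list[float] = []
    cursor = 0
    for i, w in enumerate(words):
        x = sosfiltfilt(sos, w.samples)
        peak = np.max(np.abs(x))
        if peak == 0:
            raise InvalidInputError(f"word {i} is silent")
        x = x * (target_peak / peak)
        onsets.append(cursor / sr)
        durs.append(x.size / sr)
        pieces.append(x)
        cursor += x.size
        if i < len(words) - 1:
            gap_s = rng.uniform(silence_ms - half_range_ms,
                                silence_ms + half_range_ms) / 1000.0
            gap_n = int(round(gap_s * sr))
            pieces.append(np.zeros(gap_n))
            cursor += gap_n
    audio = AudioSequence(
        samples=np.concatenate(pieces),
        sample_rate=sr,
        meta={"generator": "stream", "seed": seed},
    )
    return WordStream(
        audio=audio,
        word_onsets_s=onsets,
        word_durs_s=durs,
        speech_type="normal",
        rate_factor=1,
        silence_spec=(silence_ms, half_range_ms),
        meta={"seed": seed},
    )


# ---------------------------------------------------------------------------
# phase-warp pitch machinery
# ---------------------------------------------------------------------------


def _fundamental_band(word: AudioSequence,
                      f0_range_hz: tuple[float, float]) -> tuple[float, float]:
    """Octave-ish band around the word's median F0 (fallback: full range)."""
    try:
        _, f0 = f0_contour(word, f0_range_hz=f0_range_hz)
        voiced = f0[np.isfinite(f0)]
        med = float(np.median(voiced)) if voiced.size else None
    except InvalidInputError:
        med = None
    if med is None:
        return f0_range_hz
    return (0.66 * med, 1.5 * med)


def _cumulative_phase(x: np.ndarray, sr: float,
                      band_hz: tuple[float, float]) -> np.ndarray:
    """Unwrapped, monotone Hilbert phase of the fundamental band (cycles).

    The raw analytic phase is only trusted where the fundamental has
    amplitude (>= 10% of its peak); across weak stretches (inter-syllable
    gaps, word edges) the track is bridged by linear interpolation so the
    result is a smooth, strictly increasing pitch integral that is symmetric
    under time reversal of the input.
    """
    lo, hi = band_hz
    hi = min(hi, 0.45 * sr)
    sos = butter(4, [lo, hi], btype="band", fs=sr, output="sos")
    fund = sosfiltfilt(sos, x)
    analytic = hilbert(fund)
    phase = np.unwrap(np.angle(analytic)) / (2.0 * np.pi)
    amp = np.abs(analytic)
    idx = np.arange(x.size, dtype=np.float64)
    strong = amp >= 0.1 * np.max(amp)
    if strong.sum() >= 2:
        si = idx[strong]
        sp = phase[strong]
        bridged = np.interp(idx, si, sp)
        # linear edge extrapolation with the slope of the nearest voiced 10 ms
        k = max(int(0.01 * sr), 2)
        k = min(k, si.size - 1)
        lo_slope = (sp[k] - sp[0]) / max(si[k] - si[0], 1.0)
        hi_slope = (sp[-1] - sp[-1 - k]) / max(si[-1] - si[-1 - k], 1.0)
        head = idx < si[0]
        tail = idx > si[-1]
        bridged[head] = sp[0] - (si[0] - idx[head]) * lo_slope
        bridged[tail] = sp[-1] + (idx[tail] - si[-1]) * hi_slope
        phase = bridged
    phase = np.maximum.accumulate(phase)
    # break flat runs so the track is strictly increasing and invertible
    return phase + np.arange(phase.size) * 1e-9


def _warp_to_phase(x: np.ndarray, phase_in: np.ndarray,
                   phase_out: np.ndarray) -> np.ndarray:
    """Resample x so its phase track becomes ``phase_out``.

    Phase tracks are only defined up to an additive constant, so both are
    aligned at their first value; the target is rescaled so the total spans
    match exactly (they must agree to within a few cycles — integral-matched
    contours). Output has len(phase_out) samples.
    """
    n = x.size
    idx = np.arange(n)
    pin = phase_in - phase_in[0]
    pout = phase_out - phase_out[0]
    if pin[-1] <= 0 or pout[-1] <= 0:
        raise InvalidInputError("degenerate phase track")
    pout = pout * (pin[-1] / pout[-1])
    positions = np.interp(pout, pin, idx)
    return CubicSpline(idx, x)(np.clip(positions, 0, n - 1))


def _smooth_envelope(x: np.ndarray, sr: float, smooth_s: float = 0.01) -> np.ndarray:
    """Hilbert magnitude envelope with ~10 ms moving-average smoothing."""
    env = np.abs(hilbert(x))
    win = max(int(round(smooth_s * sr)), 1)
    kernel = np.ones(win) / win
    return np.convolve(env, kernel, mode="same")


def _impose_intensity(x: np.ndarray, target_env: np.ndarray, sr: float) -> np.ndarray:
    """Multiply x by a clipped gain trajectory moving its envelope to target."""
    cur = _smooth_envelope(x, sr)
    floor = 0.01 * np.max(cur)
    gain = target_env / np.maximum(cur, floor)
    lim = 10.0 ** (_MAX_GAIN_DB / 20.0)
    return x * np.clip(gain, 1.0 / lim, lim)


def _pv_tsm(x: np.ndarray, speed: float, n_fft: int = 1024) -> np.ndarray:
    """Phase-vocoder time-scale modification; output length ~= len(x)/speed."""
    if speed == 1.0:
        return x.copy()
    hop_syn = n_fft // 4
    hop_ana = hop_syn * speed
    win = np.hanning(n_fft)
    out_len = int(round(x.size / speed))
    # enough frames that every output sample is covered by ~4 windows
    n_frames = max(int(np.ceil(out_len / hop_syn)) + 1, 2)
    pad_len = int(np.ceil(n_frames * hop_ana)) + n_fft + 2
    pad = np.concatenate([x, np.zeros(max(pad_len - x.size, 0))])
    omega = 2.0 * np.pi * np.arange(n_fft // 2 + 1) * hop_ana / n_fft

    out = np.zeros(out_len + 2 * n_fft)
    norm = np.zeros(out_len + 2 * n_fft)
    phase_acc = None
    prev_phase = None
    for m in range(n_frames):
        a = int(round(m * hop_ana))
        frame = pad[a : a + n_fft] * win
        spec = np.fft.rfft(frame)
        mag, phase = np.abs(spec), np.angle(spec)
        if phase_acc is None:
            phase_acc = phase.copy()
        else:
            dphi = phase - prev_phase - omega
            dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
            true_freq = omega + dphi
            phase_acc = phase_acc + true_freq * (hop_syn / hop_ana)
        prev_phase = phase
        frame_out = np.fft.irfft(mag * np.exp(1j * phase_acc), n=n_fft) * win
        b = m * hop_syn
        out[b : b + n_fft] += frame_out
        norm[b : b + n_fft] += win**2
    # hann^2 at 4x overlap sums to 1.5; never amplify sparsely covered edges
    out = out[:out_len] / np.maximum(norm[:out_len], 0.1)
    return out


def _pitch_shift(x: np.ndarray, factor: float) -> np.ndarray:
    """Multiply all frequencies by ``factor`` keeping duration (PV + resample)."""
    if factor == 1.0:
        return x.copy()
    stretched = _pv_tsm(x, 1.0 / factor)  # duration * factor
    idx = np.arange(stretched.size)
    # resampling by `factor` brings duration back and scales pitch
    pos = np.minimum(np.arange(x.size) * factor, stretched.size - 1)
    return CubicSpline(idx, stretched)(pos)


# ---------------------------------------------------------------------------
# speech-type manipulation
# ---------------------------------------------------------------------------


def _per_word_apply(stream: WordStream, fn) -> AudioSequence:
    """Apply ``fn(word_samples) -> samples`` to each word span in place."""
    x = stream.audio.samples.copy()
    for sl in stream.word_slices():
        seg = fn(x[sl])
        if seg.size != sl.stop - sl.start:
            raise InvalidInputError("word manipulation changed word length")
        x[sl] = seg
    return AudioSequence(samples=x, sample_rate=stream.audio.sample_rate,
                         meta=dict(stream.audio.meta))


def apply_speech_type(
    stream: WordStream,
    mode: str,
    reference_f0_hz: float | None = None,
    f0_range_hz: tuple[float, float] = (75.0, 600.0),
) -> WordStream:
    """Produce the normal / content-only / prosody-only version of a stream.

    ``reference_f0_hz`` is the flat pitch target of the content-only mode
    (typically the speaker's adult-directed median pitch); when omitted each
    word is flattened to its own mean rate, which changes no durations.
    Total duration is preserved exactly for every mode.
    """
    if mode not in SPEECH_TYPES:
        raise InvalidArgumentError(
            f"unknown mode {mode!r}; expected one of {SPEECH_TYPES}"
        )
    sr = stream.audio.sample_rate

    def flatten_restore(seg: np.ndarray) -> np.ndarray:
        band = _fundamental_band(
            AudioSequence(seg, sr), f0_range_hz=f0_range_hz
        )
        phase = _cumulative_phase(seg, sr, band)
        flat = np.linspace(phase[0], phase[-1], phase.size)
        flattened = _warp_to_phase(seg, phase, flat)
        return _warp_to_phase(flattened, flat, phase)

    def content_only(seg: np.ndarray) -> np.ndarray:
        band = _fundamental_band(AudioSequence(seg, sr), f0_range_hz=f0_range_hz)
        phase = _cumulative_phase(seg, sr, band)
        flat = np.linspace(phase[0], phase[-1], phase.size)
        out = _warp_to_phase(seg, phase, flat)
        mean_f0 = (phase[-1] - phase[0]) / (seg.size / sr)
        if reference_f0_hz is not None and mean_f0 > 0:
            out = _pitch_shift(out, reference_f0_hz / mean_f0)
        # reverse the natural intensity contour, keeping speech forward
        target = _smooth_envelope(seg, sr)[::-1]
        return _impose_intensity(out, target, sr)

    def prosody_only(seg: np.ndarray) -> np.ndarray:
        band = _fundamental_band(AudioSequence(seg, sr), f0_range_hz=f0_range_hz)
        phase = _cumulative_phase(seg, sr, band)
        rev = seg[::-1].copy()
        # phase track of the reversed word is the reflected contour
        phase_rev = phase[-1] - phase[::-1]
        out = _warp_to_phase(rev, phase_rev, phase)
        # reinstate the original intensity contour
        target = _smooth_envelope(seg, sr)
        return _impose_intensity(out, target, sr)

    fn = {"normal": flatten_restore, "content_only": content_only,
          "prosody_only": prosody_only}[mode]
    audio = _per_word_apply(stream, fn)
    return replace(stream, audio=audio, speech_type=mode,
                   meta={**stream.meta, "reference_f0_hz": reference_f0_hz})


# ---------------------------------------------------------------------------
# tempo
# ---------------------------------------------------------------------------


def change_tempo(
    stream: WordStream, factor: int, allow_any_factor: bool = False
) -> WordStream:
    """Accelerate the stream by ``factor`` without shifting pitch.

    Duration becomes ``original / factor`` (exact in samples); onsets and
    silence spec are rescaled accordingly.
    """
    if not allow_any_factor and factor not in RATE_FACTORS:
        raise InvalidArgumentError(
            f"factor must be one of {RATE_FACTORS}, got {factor}"
        )
    if factor == 1:
        return replace(stream)
    x = stream.audio.samples
    out = _pv_tsm(x, float(factor))
    target_len = int(round(x.size / factor))
    if out.size < target_len:
        out = np.concatenate([out, np.zeros(target_len - out.size)])
    out = out[:target_len]
    audio = AudioSequence(samples=out, sample_rate=stream.audio.sample_rate,
                          meta=dict(stream.audio.meta))
    mean_ms, half_ms = stream.silence_spec
    return replace(
        stream,
        audio=audio,
        word_onsets_s=[o / factor for o in stream.word_onsets_s],
        word_durs_s=[d / factor for d in stream.word_durs_s],
        rate_factor=stream.rate_factor * factor,
        silence_spec=(mean_ms / factor, half_ms / factor),
    )


# ---------------------------------------------------------------------------
# rate extraction
# ---------------------------------------------------------------------------


def stream_rates(
    stream: WordStream,
    word_band_hz: tuple[float, float] = (0.5, 3.0),
    syllable_band_hz: tuple[float, float] = (3.0, 10.0),
    env_lowpass_hz: float = 30.0,
    env_order: int = 8,
    resolution_hz: float = 0.05,
) -> tuple[float, float]:
    """Word and syllable rate from the envelope power spectrum.

    The Hilbert envelope (low-passed below 30 Hz, eighth order) is taken from
    the first word onset on; the word rate is the spectral peak in the slow
    band and the syllable rate the peak in the fast band. ``resolution_hz``
    sets the zero-padded FFT bin width.
    """
    audio = stream.audio
    if audio.duration_s < 1.0:
        raise InsufficientDurationError("stream must be at least 1 s")
    sr = audio.sample_rate
    start = int(round(stream.word_onsets_s[0] * sr))
    seg = AudioSequence(audio.samples[start:], sr)
    env = compute_envelope(seg, band_hz=(0.0, sr), env_lowpass_hz=env_lowpass_hz,
                           order=env_order)
    # decimate: everything of interest lives below 30 Hz
    step = max(int(sr // 200), 1)
    v = env.values[::step]
    esr = sr / step
    v = v - v.mean()
    n_fft = int(2 ** np.ceil(np.log2(max(esr / resolution_hz, v.size))))
    power = np.abs(np.fft.rfft(v, n=n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / esr)

    def peak_in(band: tuple[float, float]) -> float:
        mask = (freqs >= band[0]) & (freqs <= band[1])
        if not mask.any():
            raise InvalidArgumentError(f"band {band} not resolvable")
        return float(freqs[mask][np.argmax(power[mask])])

    return peak_in(word_band_hz), peak_in(syllable_band_hz)


# ---------------------------------------------------------------------------
# the 3 x 3 condition grid
# ---------------------------------------------------------------------------


def condition_grid(
    words: list[AudioSequence],
    reference_f0_hz: float | None = None,
    silence_ms: float = 300.0,
    half_range_ms: float = 50.0,
    seed: int = 0,
) -> dict[tuple[str, int], WordStream]:
    """All nine (speech type x rate factor) streams from one set of words."""
    base = build_stream(words, silence_ms=silence_ms, half_range_ms=half_range_ms,
                        seed=seed)
    grid: dict[tuple[str, int], WordStream] = {}
    for mode in SPEECH_TYPES:
        typed = apply_speech_type(base, mode, reference_f0_hz=reference_f0_hz)
        for factor in RATE_FACTORS:
            grid[(mode, factor)] = change_tempo(typed, factor)
    return grid
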