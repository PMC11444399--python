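"""Morlet continuous wavelet transform.

The time-frequency primitives here back the envelope rhythm estimate, the
evoked-power maps, and the cerebro-acoustic coherence spectra. The transform
is a straight FFT convolution with L2-normalised complex Morlet wavelets;
bandwidth is set per call through the ``n_cycles`` parameter (cycles of the
carrier inside one Gaussian SD-pair, so larger = narrower in frequency).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .errors import InvalidInputError

__all__ = ["morlet_wavelet", "cwt_morlet", "cwt_power"]


def morlet_wavelet(
    freq_hz: float, sample_rate: float, n_cycles: float = 7.0, norm: str = "l2"
) -> np.ndarray:
    """Complex Morlet wavelet at ``freq_hz``, zero-mean.

    The Gaussian SD in time is ``n_cycles / (2*pi*freq_hz)`` and the support
    is truncated at ±5 SD. ``norm='l2'`` gives unit energy (the usual choice
    for power maps and coherence, where normalisation cancels); ``norm='l1'``
    gives a flat amplitude response to sinusoids across frequencies, which is
    what peak-picking on a line spectrum needs.
    """
    if freq_hz <= 0:
        raise InvalidInputError(f"wavelet frequency must be > 0, got {freq_hz}")
    sigma_t = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(np.ceil(5.0 * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    gauss = np.exp(-(t**2) / (2.0 * sigma_t**2))
    osc = np.exp(2j * np.pi * freq_hz * t)
    # subtract the (tiny) DC leakage so a constant input maps to ~0
    osc = osc - np.sum(osc * gauss) / np.sum(gauss)
    w = osc * gauss
    if norm == "l1":
        return w / np.sum(np.abs(w))
    if norm == "l2":
        return w / np.sqrt(np.sum(np.abs(w) ** 2))
    raise InvalidInputError(f"unknown norm {norm!r}")


def cwt_morlet(
    data: np.ndarray,
    sample_rate: float,
    freqs_hz: np.ndarray,
    n_cycles: float = 7.0,
    norm: str = "l2",
    mode: str = "same",
) -> np.ndarray:
    """Morlet CWT of ``data`` (last axis = time).

    Returns a complex array of shape ``data.shape[:-1] + (n_freqs, n_times)``.

    ``mode='same'`` is ordinary (zero-padded) convolution truncated to the
    input length; ``mode='circular'`` treats the signal as periodic, which
    makes the transform commute exactly with circular shifts — the property
    the surrogate-null construction relies on.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.size == 0:
        raise InvalidInputError("empty input to cwt_morlet")
    if mode not in ("same", "circular"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=np.float64))
    lead = data.shape[:-1]
    n_times = data.shape[-1]
    flat = data.reshape(-1, n_times)
    out = np.empty((flat.shape[0], freqs_hz.size, n_times), dtype=np.complex128)
    if mode == "circular":
        fdata = np.fft.fft(flat, axis=-1)
    for j, f in enumerate(freqs_hz):
        w = morlet_wavelet(f, sample_rate, n_cycles=n_cycles, norm=norm)
        if mode == "same":
            out[:, j, :] = fftconvolve(flat, w[np.newaxis, :], mode="same", axes=-1)
        else:
            half = w.size // 2
            wrapped = np.zeros(n_times, dtype=np.complex128)
            # centre the wavelet at index 0, wrapping its support
            np.add.at(wrapped, (np.arange(w.size) - half) % n_times, w)
            out[:, j, :] = np.fft.ifft(fdata * np.fft.fft(wrapped), axis=-1)
    return out.reshape(lead + (freqs_hz.size, n_times))


def cwt_power(
    data: np.ndarray,
    sample_rate: float,
    freqs_hz: np.ndarray,
    n_cycles: float = 7.0,
    norm: str = "l2",
) -> np.ndarray:
    """Squared-magnitude Morlet transform (same shape semantics as cwt_morlet)."""
    return (
        np.abs(cwt_morlet(data, sample_rate, freqs_hz, n_cycles=n_cycles, norm=norm))
        ** 2
    )
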