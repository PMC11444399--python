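"""Mono audio container and WAV (PCM 16-bit) I/O.

WAV reading/writing is delegated to :mod:`scipy.io.wavfile`; this module only
adds float conversion, mono enforcement and provenance metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import InvalidInputError

__all__ = ["AudioSequence", "read_wav", "write_wav"]


@dataclass
class AudioSequence:
    """A mono waveform with sampling rate and provenance metadata.

    Parameters
    ----------
    samples
        1-D float array of audio samples (full scale is ±1.0).
    sample_rate
        Sampling rate in Hz.
    meta
        Free-form provenance: species, vocal class, subject, body weight,
        ground-truth generator parameters, ...
    """

    samples: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidInputError(
                f"audio must be mono (1-D), got shape {self.samples.shape}"
            )
        if self.sample_rate <= 0:
            raise InvalidInputError(f"sample_rate must be > 0, got {self.sample_rate}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


def read_wav(path: str | Path) -> AudioSequence:
    """Read a WAV file as a float mono :class:`AudioSequence`.

    Integer PCM is rescaled to ±1.0; multichannel input is averaged to mono.
    A ``<name>.json`` sidecar, when present, is loaded into ``meta``.
    """
    path = Path(path)
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        info = np.iinfo(data.dtype)
        data = (data.astype(np.float64) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return AudioSequence(samples=data, sample_rate=float(rate), meta=meta)


def write_wav(path: str | Path, audio: AudioSequence, sidecar: bool = True) -> None:
    """Write PCM 16-bit WAV plus an optional JSON metadata sidecar."""
    path = Path(path)
    clipped = np.clip(audio.samples, -1.0, 1.0)
    pcm = np.round(clipped * np.iinfo(np.int16).max).astype(np.int16)
    wavfile.write(path, int(round(audio.sample_rate)), pcm)
    if sidecar and audio.meta:
        path.with_suffix(".json").write_text(
            json.dumps(audio.meta, indent=2, default=float)
        )
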