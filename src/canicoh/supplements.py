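"""Readers and analyses for the deposited supplementary tables.

The deposited tables are XLSX workbooks; these loaders accept either XLSX
or CSV exports, matching columns case-insensitively. Expected canonical
layouts (extra columns are ignored):

``paired speech`` (S1-style)
    speaker, ads_rate_hz, dds_rate_hz, ads_f0_hz, dds_f0_hz
``band coherence`` (S3-style)
    subject, species (dog/human), band (delta/theta), real, random
``register pitch`` (S5-style)
    speaker, register (command/ads/dds), mean_f0_hz, f0_iqr_hz
``subject TFR`` (S8/S9-style)
    subject, time_s, freq_hz, power  (long format)
``perception`` (S2-style)
    subject, species, speech_type, rate_factor, intelligibility,
    word_coh, syll_coh, word_rate_hz, syll_rate_hz

Each ``analyze_*`` function reproduces one of the printed statistics from
the corresponding table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .stats import StatResult, fit_lmm, kruskal_dunn, mann_whitney, paired_t

__all__ = [
    "load_table",
    "analyze_paired_speech",
    "analyze_band_coherence",
    "analyze_register_pitch",
    "analyze_peak_power",
    "analyze_intelligibility_lmm",
    "peak_frequency_from_tfr_table",
]


def load_table(path: str | Path, sheet: int | str = 0) -> pd.DataFrame:
    """Load a CSV or XLSX table with normalised (lowercase) column names."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path)
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    return df


def _require(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{what} table missing columns {missing}")


def analyze_paired_speech(df: pd.DataFrame) -> dict[str, StatResult]:
    """Paired t tests of ADS vs DDS speech rate and mean F0 (ADS − DDS)."""
    _require(df, ("ads_rate_hz", "dds_rate_hz", "ads_f0_hz", "dds_f0_hz"),
             "paired speech")
    return {
        "rate": paired_t(df["ads_rate_hz"], df["dds_rate_hz"]),
        "f0": paired_t(df["ads_f0_hz"], df["dds_f0_hz"]),
    }


def analyze_band_coherence(df: pd.DataFrame) -> dict[tuple[str, str], StatResult]:
    """Paired t (random − real) per species x band."""
    _require(df, ("subject", "species", "band", "real", "random"), "band coherence")
    out: dict[tuple[str, str], StatResult] = {}
    for (species, band), sub in df.groupby(["species", "band"]):
        sub = sub.sort_values("subject")
        out[(str(species).lower(), str(band).lower())] = paired_t(
            sub["random"], sub["real"]
        )
    return out


def analyze_register_pitch(df: pd.DataFrame) -> dict[str, StatResult]:
    """Kruskal–Wallis H across the three speech registers for mean and IQR F0."""
    _require(df, ("register", "mean_f0_hz", "f0_iqr_hz"), "register pitch")
    registers = sorted(df["register"].str.lower().unique())
    out = {}
    for measure in ("mean_f0_hz", "f0_iqr_hz"):
        groups = [
            df[df["register"].str.lower() == r][measure].to_numpy()
            for r in registers
        ]
        omnibus, _ = kruskal_dunn(groups, labels=registers)
        out[measure] = omnibus
    return out


def peak_frequency_from_tfr_table(
    df: pd.DataFrame,
    range_hz: tuple[float, float] = (1.0, 7.0),
    window_s: tuple[float, float] = (0.0, 1.3),
) -> pd.Series:
    """Per-subject arg-max frequency of window-averaged, peak-normalised power."""
    _require(df, ("subject", "time_s", "freq_hz", "power"), "subject TFR")
    peaks = {}
    for subject, sub in df.groupby("subject"):
        sub = sub[(sub["time_s"] >= window_s[0]) & (sub["time_s"] <= window_s[1])]
        spec = sub.groupby("freq_hz")["power"].mean()
        spec = spec / spec.abs().max()
        spec = spec[(spec.index >= range_hz[0]) & (spec.index <= range_hz[1])]
        peaks[subject] = float(spec.idxmax())
    return pd.Series(peaks, name="peak_hz")


def analyze_peak_power(dog_df: pd.DataFrame, human_df: pd.DataFrame) -> StatResult:
    """Mann–Whitney U on the species difference in peak evoked frequency."""
    dog_peaks = peak_frequency_from_tfr_table(dog_df)
    human_peaks = peak_frequency_from_tfr_table(human_df)
    return mann_whitney(dog_peaks.to_numpy(), human_peaks.to_numpy())


def analyze_intelligibility_lmm(
    df: pd.DataFrame,
    species: str = "dog",
    coherence_term: str = "word_coh",
) -> StatResult:
    """Mixed-model F for the coherence slope on intelligibility.

    Intelligibility ~ coherence + speech type, random intercept per subject,
    REML, restricted to one species.
    """
    _require(df, ("subject", "species", "speech_type", "intelligibility",
                  coherence_term), "perception")
    sub = df[df["species"].str.lower() == species].copy()
    if sub.empty:
        raise InvalidInputError(f"no rows for species {species!r}")
    fit = fit_lmm(
        sub,
        formula=f"intelligibility ~ {coherence_term} + C(speech_type)",
        groups="subject",
    )
    return fit.results[coherence_term]
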