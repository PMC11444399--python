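"""Behavioural intelligibility indices on a common 0–1 scale.

Humans: proportion of correctly comprehended words out of five. Dogs: mean
over commands of the best response score (1–5 scale: 1 = no response within
10 s ... 5 = complete response within 5 s) across up to three presentations,
rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidInputError, NotFoundError

__all__ = [
    "IntelligibilityIndex",
    "load_dog_responses",
    "human_intelligibility",
    "dog_intelligibility",
]

REQUIRED_COLUMNS = ("subject", "condition", "command_word", "presentation", "score")


@dataclass
class IntelligibilityIndex:
    subject: str
    condition: str
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise InvalidInputError(f"index {self.value} outside [0, 1]")


def load_dog_responses(path_or_df) -> pd.DataFrame:
    """Validate (and, from CSV, load) a long-format dog response table.

    When both ``score`` and ``score_rater2`` columns are present, rater
    disagreements are resolved toward the lower score.
    """
    df = (
        path_or_df.copy()
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df)
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"response table missing columns {missing}")
    if "score_rater2" in df.columns:
        df["score"] = df[["score", "score_rater2"]].min(axis=1)
        df = df.drop(columns=["score_rater2"])
    if not df["score"].isin([1, 2, 3, 4, 5]).all():
        raise InvalidInputError("scores must be integers 1..5")
    n_pres = df.groupby(["subject", "condition", "command_word"]).size()
    if (n_pres > 3).any():
        raise InvalidInputError("more than 3 presentations for a command")
    return df


def human_intelligibility(
    words_understood: int, total: int = 5, subject: str = "", condition: str = ""
) -> IntelligibilityIndex:
    """Proportion of correctly comprehended words."""
    if not 0 <= words_understood <= total:
        raise InvalidInputError(
            f"words_understood={words_understood} outside [0, {total}]"
        )
    return IntelligibilityIndex(
        subject=subject, condition=condition, value=words_understood / total
    )


def dog_intelligibility(
    table: pd.DataFrame,
    subject: str,
    condition: str,
    scale: str = "affine",
) -> IntelligibilityIndex:
    """Mean best-response score per command, rescaled to [0, 1].

    For each command the maximum score over its (up to three) presentations
    is taken; the command-wise maxima are averaged and mapped to [0, 1] by
    the fixed affine map ``(mean − 1)/4`` (``scale='affine'``). The
    empirical alternative ``scale='minmax'`` rescales by the observed range
    across this subject's conditions instead.
    """
    df = load_dog_responses(table)
    sub = df[(df["subject"] == subject) & (df["condition"] == condition)]
    if sub.empty:
        raise NotFoundError(f"no rows for subject={subject!r} condition={condition!r}")

    def mean_best(rows: pd.DataFrame) -> float:
        return float(rows.groupby("command_word")["score"].max().mean())

    mean_max = mean_best(sub)
    if scale == "affine":
        value = (mean_max - 1.0) / 4.0
    elif scale == "minmax":
        mine = df[df["subject"] == subject]
        per_cond = [mean_best(rows) for _, rows in mine.groupby("condition")]
        lo, hi = min(per_cond), max(per_cond)
        value = 0.0 if hi == lo else (mean_max - lo) / (hi - lo)
    else:
        raise InvalidArgumentError(f"unknown scale {scale!r}")
    return IntelligibilityIndex(
        subject=subject, condition=condition, value=float(np.clip(value, 0.0, 1.0))
    )
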