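"""Statistical layer: paired t, Mann–Whitney, Kruskal–Wallis with Dunn post
hocs, and linear mixed models with per-term F tests.

The elementary tests are written out from their textbook formulas (they are
cross-checked against brute-force enumeration in the test suite); the mixed
model delegates estimation to :mod:`statsmodels` (REML) and adds Wald F
tests per fixed term. Kenward–Roger denominator degrees of freedom are not
available in this stack; the default is a between-within (containment)
approximation, which coincides with the classical balanced-design df.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    InvalidArgumentError,
    InvalidInputError,
)

__all__ = [
    "StatResult",
    "paired_t",
    "mann_whitney",
    "kruskal_dunn",
    "fit_lmm",
    "LMMFit",
]


@dataclass
class StatResult:
    """A test statistic with df, two-sided p-value and an effect size."""

    statistic_name: str  # one of {"t", "U", "H", "F", "W"}
    statistic: float
    df: float
    p: float
    effect_name: str = "none"
    effect: float | None = None
    df_num: float | None = None  # numerator df for F tests
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise InvalidInputError(f"p-value {self.p} outside [0, 1]")


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


def paired_t(x, y) -> StatResult:
    """Two-sided paired t test with Cohen's d = mean(diff)/SD(diff)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("paired samples must be 1-D and equal length")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise InvalidInputError("missing values in paired samples")
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"paired t needs n >= 3, got {n}")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(
        statistic_name="t",
        statistic=float(t),
        df=float(df),
        p=float(p),
        effect_name="cohens_d",
        effect=float(d.mean() / sd),
    )


def mann_whitney(x, y) -> StatResult:
    """Mann–Whitney U (reported as max(U1, U2)) with rank effect r = |z|/sqrt(N).

    Uses the normal approximation with tie correction (no continuity
    correction); df is reported as N − 2 for parity with common reporting.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("both samples need at least 2 values")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = max(u1, u2)
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        raise DegenerateInputError("all observations tied; U test degenerate")
    z = (u - n1 * n2 / 2.0) / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return StatResult(
        statistic_name="U",
        statistic=float(u),
        df=float(n - 2),
        p=float(min(p, 1.0)),
        effect_name="rank_r",
        effect=float(abs(z) / np.sqrt(n)),
    )


def kruskal_dunn(
    groups: list, labels: list[str] | None = None
) -> tuple[StatResult, pd.DataFrame]:
    """Kruskal–Wallis H (tie-corrected) plus Bonferroni-adjusted Dunn post hocs.

    Returns the omnibus result (effect size: epsilon squared) and a data
    frame of pairwise Dunn z statistics with adjusted p-values.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    k = len(groups)
    if k < 3:
        raise InvalidInputError(f"Kruskal–Wallis needs >= 3 groups, got {k}")
    for g in groups:
        if g.size < 2:
            raise InvalidInputError("each group needs at least 2 values")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(k)]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum([0] + [g.size for g in groups])
    rank_groups = [ranks[bounds[i] : bounds[i + 1]] for i in range(k)]
    h = 12.0 / (n * (n + 1)) * sum(
        rg.sum() ** 2 / rg.size for rg in rank_groups
    ) - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie_corr == 0:
        raise DegenerateInputError("all observations tied")
    h /= tie_corr
    df = k - 1
    p = sps.chi2.sf(h, df)
    omnibus = StatResult(
        statistic_name="H",
        statistic=float(h),
        df=float(df),
        p=float(p),
        effect_name="epsilon_sq",
        effect=float(h / (n - 1)),
    )

    mean_ranks = [rg.mean() for rg in rank_groups]
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    m = k * (k - 1) / 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(base_var * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": float(z),
                "p_raw": float(p_raw),
                "p_bonferroni": float(min(p_raw * m, 1.0)),
            }
        )
    return omnibus, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linear mixed models
# ---------------------------------------------------------------------------


@dataclass
class LMMFit:
    """A fitted mixed model plus per-term F tests and metadata."""

    results: dict[str, StatResult]
    params: pd.Series
    conf_int: pd.DataFrame
    n_obs: int
    n_groups: int
    singular: bool
    model: object = None


def _term_f_tests(
    fitted, design_info, n_obs: int, n_groups: int, ddf_method: str
) -> dict[str, StatResult]:
    params = np.asarray(fitted.fe_params)
    cov = np.asarray(fitted.cov_params())[: params.size, : params.size]
    names = list(design_info.column_names)
    p_fixed = params.size
    results: dict[str, StatResult] = {}
    for term in design_info.terms:
        tname = term.name()
        if tname == "Intercept":
            continue
        sl = design_info.slice(tname)
        idx = np.arange(p_fixed)[sl]
        c = params[idx]
        v = cov[np.ix_(idx, idx)]
        q = idx.size
        try:
            fstat = float(c @ np.linalg.solve(v, c) / q)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular covariance for term {tname}") from exc
        if ddf_method == "between_within":
            ddf = max(n_obs - n_groups - (p_fixed - 1), 1)
        elif ddf_method == "residual":
            ddf = max(n_obs - p_fixed, 1)
        else:
            raise InvalidArgumentError(f"unknown ddf_method {ddf_method!r}")
        p = sps.f.sf(fstat, q, ddf)
        results[tname] = StatResult(
            statistic_name="F",
            statistic=fstat,
            df=float(ddf),
            df_num=float(q),
            p=float(p),
            note=f"ddf={ddf_method} (Kenward–Roger unavailable in this stack)",
        )
    _ = names  # kept for debugging symmetry with the design matrix
    return results


def fit_lmm(
    table: pd.DataFrame,
    formula: str,
    groups: str,
    reml: bool = True,
    ddf_method: str = "between_within",
) -> LMMFit:
    """Random-intercept linear mixed model with per-term Wald F tests.

    ``formula`` is a fixed-effects formula (e.g. ``"y ~ coh + C(speech_type)"``)
    and ``groups`` names the random-intercept grouping factor. Denominator
    df use a between-within (containment) approximation by default; singular
    fits (zero group variance) are flagged, not hidden.
    """
    import statsmodels.formula.api as smf

    if groups not in table.columns:
        raise InvalidInputError(f"grouping column {groups!r} not in table")
    if table[groups].nunique() < 3:
        raise InvalidInputError("grouping factor needs >= 3 levels")
    model = smf.mixedlm(formula, data=table, groups=table[groups])
    import warnings

    fitted = None
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "powell", "cg"):
            try:
                if method is None:
                    fitted = model.fit(reml=reml)
                else:
                    fitted = model.fit(reml=reml, method=method)
                break
            except Exception as exc:  # noqa: BLE001 - try the next optimizer
                last_exc = exc
    if fitted is None:
        raise ConvergenceError(
            f"mixed model failed to converge: {last_exc}"
        ) from last_exc
    if not np.all(np.isfinite(np.asarray(fitted.fe_params))):
        raise ConvergenceError("non-finite fixed-effect estimates")
    singular = bool(
        np.diag(np.asarray(fitted.cov_re)).min() <= 1e-6 * float(fitted.scale)
    )
    design_info = model.data.design_info
    n_obs = int(model.nobs)
    n_groups = int(table[groups].nunique())
    results = _term_f_tests(fitted, design_info, n_obs, n_groups, ddf_method)
    fe = fitted.fe_params
    ci = fitted.conf_int().iloc[: len(fe)]
    ci.columns = ["low", "high"]
    return LMMFit(
        results=results,
        params=fe,
        conf_int=ci,
        n_obs=n_obs,
        n_groups=n_groups,
        singular=singular,
        model=fitted,
    )
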