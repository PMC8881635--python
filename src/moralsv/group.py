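"""Group-level behavioral statistics across subjects.

Covers the cross-domain question — do people who discount money steeply
also discount lives steeply? — via a Spearman rank correlation between the
two discount constants, plus the paired RT comparison and a serializable
cohort summary.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, ttest_rel

from .errors import ValidationError

__all__ = ["CohortSummary", "correlate_discount_factors", "paired_rt_test", "summarize_cohort"]

#: Columns summarize_cohort expects in the per-subject fit table.
FIT_TABLE_COLUMNS = (
    "subject_id",
    "k_f",
    "k_m",
    "r2_f",
    "r2_m",
    "mean_rt_f",
    "mean_rt_m",
)


def correlate_discount_factors(k_f, k_m) -> tuple[float, float]:
    """Spearman rank correlation (rho, two-sided p) between K_f and K_m.

    Rank-based, so invariant to any strictly monotone transform of either
    vector; ties receive average ranks.
    """
    k_f = np.asarray(k_f, float)
    k_m = np.asarray(k_m, float)
    if k_f.shape != k_m.shape:
        raise ValidationError("discount-factor vectors must have equal length")
    if k_f.size < 3:
        raise ValidationError("need at least 3 paired subjects")
    rho, p = spearmanr(k_f, k_m)
    return float(rho), float(p)


def paired_rt_test(rt_financial, rt_moral) -> tuple[float, int, float]:
    """Two-sided paired t-test on per-subject mean RTs: (t, df, p)."""
    a = np.asarray(rt_financial, float)
    b = np.asarray(rt_moral, float)
    if a.shape != b.shape:
        raise ValidationError("RT vectors must have equal length")
    if a.size < 2:
        raise ValidationError("need at least 2 paired subjects")
    if np.allclose(a, b):
        return 0.0, a.size - 1, 1.0
    t, p = ttest_rel(a, b)
    return float(t), a.size - 1, float(p)


@dataclass
class CohortSummary:
    """Group statistics of one fitted cohort; serializable to JSON."""

    n_subjects: int
    k_f_range: tuple[float, float]
    k_m_range: tuple[float, float]
    r2_f_mean: float
    r2_f_sd: float
    r2_m_mean: float
    r2_m_sd: float
    rt_f_mean: float
    rt_f_sem: float
    rt_m_mean: float
    rt_m_sem: float
    spearman_rho: float
    spearman_p: float
    paired_rt_t: float
    paired_rt_df: int
    paired_rt_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_cohort(fit_table: pd.DataFrame) -> CohortSummary:
    """Assemble the group statistics from a per-subject fit table.

    ``fit_table`` needs one row per subject with columns
    ``FIT_TABLE_COLUMNS``; missing or NaN fits raise a
    :class:`ValidationError` naming the offending subjects.
    """
    missing_cols = [c for c in FIT_TABLE_COLUMNS if c not in fit_table.columns]
    if missing_cols:
        raise ValidationError(f"fit table is missing columns {missing_cols}")
    check = fit_table[list(FIT_TABLE_COLUMNS[1:])]
    bad = fit_table.loc[check.isna().any(axis=1), "subject_id"].tolist()
    if bad:
        raise ValidationError(f"missing fits for subjects {bad}")

    n = len(fit_table)
    rho, p = correlate_discount_factors(fit_table["k_f"], fit_table["k_m"])
    t, df, p_rt = paired_rt_test(fit_table["mean_rt_f"], fit_table["mean_rt_m"])
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n))  # noqa: E731
    return CohortSummary(
        n_subjects=n,
        k_f_range=(float(fit_table["k_f"].min()), float(fit_table["k_f"].max())),
        k_m_range=(float(fit_table["k_m"].min()), float(fit_table["k_m"].max())),
        r2_f_mean=float(fit_table["r2_f"].mean()),
        r2_f_sd=float(fit_table["r2_f"].std(ddof=1)),
        r2_m_mean=float(fit_table["r2_m"].mean()),
        r2_m_sd=float(fit_table["r2_m"].std(ddof=1)),
        rt_f_mean=float(fit_table["mean_rt_f"].mean()),
        rt_f_sem=sem(fit_table["mean_rt_f"]),
        rt_m_mean=float(fit_table["mean_rt_m"].mean()),
        rt_m_sem=sem(fit_table["mean_rt_m"]),
        spearman_rho=rho,
        spearman_p=p,
        paired_rt_t=t,
        paired_rt_df=df,
        paired_rt_p=p_rt,
    )
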