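"""Choice-certainty matching between the financial and moral tasks.

The two tasks can only be compared fairly if they are matched on how far
choices sit from indifference.  The procedure drops the financial
trial types with the most extreme choice certainty (in the study: all
trials offering 20 or 22 CHF as the larger-later reward, which are
near-certain rejections), then verifies with paired two-sided t-tests that
the standardized choice-probability and RT slopes no longer differ between
tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel

from .behavior import choice_slope, rt_slope
from .data import ChoiceDataset
from .errors import ValidationError

__all__ = [
    "MatchReport",
    "trial_type_certainty",
    "exclude_extreme_certainty",
    "cohort_slopes",
    "compare_task_slopes",
]

#: Larger-later amounts the study identified as extreme-certainty types.
PAPER_EXCLUDED_AMOUNTS = (20.0, 22.0)


@dataclass
class MatchReport:
    """Outcome of the cross-task matching procedure."""

    excluded_trial_types: list[float]
    t_choice: float
    p_choice: float
    t_rt: float
    p_rt: float
    df: int
    alpha: float
    matched: bool
    mode: str = "paper"

    def to_dict(self) -> dict:
        return asdict(self)


def trial_type_certainty(datasets: list[ChoiceDataset]) -> pd.DataFrame:
    """Choice certainty per financial trial type (larger-later amount).

    A trial type is all trials sharing an LL amount, collapsed across
    delays.  Certainty is |mean P(chose target) − 0.5| where the mean pools
    subjects' per-type choice frequencies.  Ties — common when low offers
    are rejected without exception — are broken deterministically: lower
    acceptance rate first (certain rejections are the dominated options),
    then smaller amount first.
    """
    frames = []
    for ds in datasets:
        per_type = ds.trials.groupby("magnitude")["chose_target"].mean()
        frames.append(per_type.rename(ds.subject_id))
    table = pd.concat(frames, axis=1)
    mean_p = table.mean(axis=1)
    out = pd.DataFrame({"mean_p": mean_p, "certainty": (mean_p - 0.5).abs()})
    out["certainty"] = out["certainty"].round(12)  # drop float fuzz before ranking
    out = out.reset_index().sort_values(
        ["certainty", "mean_p", "magnitude"], ascending=[False, True, True]
    )
    return out.set_index("magnitude")


def exclude_extreme_certainty(
    datasets: list[ChoiceDataset],
    n_types: int = 2,
    mode: str = "paper",
) -> tuple[list[ChoiceDataset], list[float]]:
    """Drop the ``n_types`` most extreme-certainty financial trial types.

    ``mode="paper"`` removes the types the study reports (LL of 20 and
    22 CHF); ``mode="data_driven"`` ranks the types by the cohort's own
    choice certainty and removes the top ``n_types``.  Rows of surviving
    types are returned unchanged.
    """
    if not datasets:
        raise ValidationError("no datasets to filter")
    amounts = sorted(
        set().union(*[set(ds.trials["magnitude"].unique()) for ds in datasets])
    )
    if n_types >= len(amounts):
        raise ValidationError(
            f"cannot exclude {n_types} of {len(amounts)} trial types"
        )
    if n_types == 0:
        return list(datasets), []

    if mode == "paper":
        excluded = list(PAPER_EXCLUDED_AMOUNTS)[:n_types]
    elif mode == "data_driven":
        ranking = trial_type_certainty(datasets)
        excluded = sorted(float(a) for a in ranking.index[:n_types])
    else:
        raise ValidationError(f"unknown exclusion mode {mode!r}")

    filtered = [
        ChoiceDataset(
            subject_id=ds.subject_id,
            task=ds.task,
            trials=ds.trials[~ds.trials["magnitude"].isin(excluded)].reset_index(drop=True),
        )
        for ds in datasets
    ]
    return filtered, excluded


def cohort_slopes(datasets: list[ChoiceDataset]) -> pd.DataFrame:
    """Per-subject standardized choice and RT slopes, indexed by subject."""
    rows = {}
    for ds in datasets:
        rows[ds.subject_id] = {
            "choice_slope": choice_slope(ds).beta1,
            "rt_slope": rt_slope(ds).beta1,
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def compare_task_slopes(
    financial_slopes: pd.DataFrame,
    moral_slopes: pd.DataFrame,
    alpha: float = 0.05,
    excluded_trial_types: list[float] | None = None,
    mode: str = "paper",
) -> MatchReport:
    """Paired two-sided t-tests of the standardized slopes across tasks.

    Inputs are per-subject tables from :func:`cohort_slopes`; subjects must
    pair exactly.  The tasks count as matched when both tests fail to
    reject at ``alpha``.
    """
    if sorted(financial_slopes.index) != sorted(moral_slopes.index):
        raise ValidationError("financial and moral slope tables have different subjects")
    if len(financial_slopes) < 2:
        raise ValidationError("need at least two paired subjects")
    moral_slopes = moral_slopes.loc[financial_slopes.index]

    def paired(col: str) -> tuple[float, float]:
        a = financial_slopes[col].to_numpy(float)
        b = moral_slopes[col].to_numpy(float)
        if np.allclose(a, b):
            return 0.0, 1.0  # degenerate equality: no evidence of difference
        t, p = ttest_rel(a, b)
        return float(t), float(p)

    t_choice, p_choice = paired("choice_slope")
    t_rt, p_rt = paired("rt_slope")
    return MatchReport(
        excluded_trial_types=list(excluded_trial_types or []),
        t_choice=t_choice,
        p_choice=p_choice,
        t_rt=t_rt,
        p_rt=p_rt,
        df=len(financial_slopes) - 1,
        alpha=alpha,
        matched=bool(p_choice > alpha and p_rt > alpha),
        mode=mode,
    )
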