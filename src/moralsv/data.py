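"""Core data containers shared by the simulation and analysis stages.

The two choice tasks are deliberately isomorphic:

* **financial** — accept 20 CHF today (reference) or a larger-later amount
  (20–120 CHF) paid after one of six delays (1–180 days).  The delay enters
  the value model through the subject's own 0–100 rating of how long the
  delay feels (``T``).
* **moral** — spare one person (reference, worth one life) or sacrifice them
  to save a larger group (1–10 lives).  The sacrificed person carries one of
  six criminal-record ranks, entering the model through the subject's 0–100
  rating of how wrong the crime was (``D``).

Each trial is therefore a (magnitude, discounter-level) pair, and both tasks
share the container types below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

FINANCIAL = "financial"
MORAL = "moral"
TASKS = (FINANCIAL, MORAL)

#: Immediate reference option: 20 CHF today.
FINANCIAL_REFERENCE = 20.0
#: Moral reference option: sparing the one person (one life).
MORAL_REFERENCE = 1.0

#: Default larger-later amount grid (CHF).  Covers the printed 20–120 range
#: and includes the 20 and 22 CHF types needed by the certainty-matching
#: stage.
FINANCIAL_AMOUNTS = (20.0, 22.0, 25.0, 30.0, 35.0, 45.0, 60.0, 80.0, 100.0, 120.0)
#: Default delay grid (days), spanning the printed 1–180 day range.
FINANCIAL_DELAYS = (1, 7, 14, 30, 90, 180)
#: Group sizes for the moral task (lives saved), printed range 1–10.
MORAL_LIVES = tuple(float(n) for n in range(1, 11))
#: Criminal-record ranks, from no record (1) to serial killer (6).
MORAL_RANKS = (1, 2, 3, 4, 5, 6)

#: Printed across-participant range of the financial discount constant
#: (per rating unit).
K_F_RANGE = (3.78e-5, 0.043)
#: Printed across-participant range of the moral discount constant.
K_M_RANGE = (0.093, 7.08)

TRIAL_COLUMNS = ("magnitude", "level", "perceived", "sv_target", "chose_target", "rt_ms")


def reference_value(task: str) -> float:
    if task == FINANCIAL:
        return FINANCIAL_REFERENCE
    if task == MORAL:
        return MORAL_REFERENCE
    raise ValidationError(f"unknown task {task!r}; expected one of {TASKS}")


def default_delay_rating(delay_days) -> np.ndarray | float:
    """Default perceived temporal distance on the 0–100 scale.

    Logarithmic in clock time (Weber–Fechner compression of subjective
    duration), anchored so that 180 days maps to 100.
    """
    frac = np.log1p(np.asarray(delay_days, dtype=float)) / np.log1p(180.0)
    return np.minimum(100.0 * frac, 100.0)


def default_deservingness_rating(rank) -> np.ndarray | float:
    """Default perceived wrongness of the criminal record, 0–100, linear in rank."""
    return 100.0 * (np.asarray(rank, dtype=float) - 1.0) / 5.0


@dataclass
class PerceptionRatings:
    """Per-subject ratings of the discounting attributes.

    ``delay`` maps delay in days to a rating in [0, 100] (0 = extremely
    short, 100 = extremely long); ``deservingness`` maps criminal-record
    rank to a rating in [0, 100] (0 = not at all wrong, 100 = extremely
    wrong).  Synthetic ratings are monotone non-decreasing in their key.
    """

    delay: dict[int, float] = field(default_factory=dict)
    deservingness: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (("delay", self.delay), ("deservingness", self.deservingness)):
            for key, value in table.items():
                if not 0.0 <= value <= 100.0:
                    raise ValidationError(
                        f"{name} rating for level {key} is {value}; must lie in [0, 100]"
                    )

    def table(self, task: str) -> Mapping[int, float]:
        return self.delay if task == FINANCIAL else self.deservingness

    def rating(self, task: str, level) -> float:
        table = self.table(task)
        try:
            return table[level]
        except KeyError:
            raise ValidationError(
                f"no {task} perception rating for level {level!r}"
            ) from None

    def is_monotone(self, task: str) -> bool:
        table = self.table(task)
        values = [table[k] for k in sorted(table)]
        return bool(np.all(np.diff(values) >= 0.0))

    @classmethod
    def default(
        cls,
        delays=FINANCIAL_DELAYS,
        ranks=MORAL_RANKS,
    ) -> "PerceptionRatings":
        return cls(
            delay={int(d): float(default_delay_rating(d)) for d in delays},
            deservingness={int(r): float(default_deservingness_rating(r)) for r in ranks},
        )

    def to_frame(self, subject_id: str = "") -> pd.DataFrame:
        rows = [
            {"subject_id": subject_id, "attribute": "delay", "level": k, "rating": v}
            for k, v in sorted(self.delay.items())
        ] + [
            {"subject_id": subject_id, "attribute": "deservingness", "level": k, "rating": v}
            for k, v in sorted(self.deservingness.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PerceptionRatings":
        delay = {
            int(r.level): float(r.rating)
            for r in frame[frame["attribute"] == "delay"].itertuples()
        }
        deserv = {
            int(r.level): float(r.rating)
            for r in frame[frame["attribute"] == "deservingness"].itertuples()
        }
        return cls(delay=delay, deservingness=deserv)


@dataclass
class TaskDesign:
    """Full-factorial trial list for one task.

    ``trials`` has columns ``magnitude`` (CHF or lives) and ``level``
    (delay in days, or deservingness rank 1–6).
    """

    task: str
    trials: pd.DataFrame

    @property
    def reference_value(self) -> float:
        return reference_value(self.task)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.unique(self.trials["magnitude"].to_numpy())

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.trials["level"].to_numpy())

    def cell_counts(self) -> pd.Series:
        return self.trials.groupby(["magnitude", "level"]).size()


@dataclass
class ChoiceDataset:
    """Per-subject, per-task trial records.

    ``trials`` columns: ``magnitude``, ``level``, ``perceived`` (the
    subject's 0–100 rating of the level), ``sv_target`` (subjective value
    of the discounted option), ``chose_target`` (financial: chose the
    larger-later reward; moral: chose to sacrifice), ``rt_ms``.
    """

    subject_id: str
    task: str
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValidationError(f"trial table is missing columns {missing}")
        if len(self.trials) and (self.trials["rt_ms"] <= 0).any():
            raise ValidationError("reaction times must be positive")

    @property
    def reference_value(self) -> float:
        return reference_value(self.task)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        out = self.trials.copy()
        out.insert(0, "task", self.task)
        out.insert(0, "subject_id", self.subject_id)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ChoiceDataset":
        subjects = frame["subject_id"].unique()
        tasks = frame["task"].unique()
        if len(subjects) != 1 or len(tasks) != 1:
            raise ValidationError(
                "from_frame expects rows for exactly one subject and one task"
            )
        trials = frame.drop(columns=["subject_id", "task"]).reset_index(drop=True)
        return cls(subject_id=str(subjects[0]), task=str(tasks[0]), trials=trials)


def write_choice_tsv(datasets: list[ChoiceDataset], path: str | Path) -> None:
    frame = pd.concat([d.to_frame() for d in datasets], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False)


def read_choice_tsv(path: str | Path) -> list[ChoiceDataset]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for (_, _), grp in frame.groupby(["subject_id", "task"], sort=True):
        out.append(ChoiceDataset.from_frame(grp.reset_index(drop=True)))
    return out
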