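"""Readers and writers for the package's on-disk formats.

Tabular data is TSV throughout (choice datasets, perception ratings,
BIDS-style events), volumes are NIfTI-1, and configuration/reports are
JSON with sorted keys so equal content always produces equal bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ChoiceDataset, PerceptionRatings, read_choice_tsv, write_choice_tsv
from .errors import ValidationError

__all__ = [
    "read_choice_tsv",
    "write_choice_tsv",
    "read_perception_tsv",
    "write_perception_tsv",
    "read_events_tsv",
    "write_events_tsv",
    "save_nifti",
    "load_nifti",
    "write_json",
    "read_json",
]

EVENTS_COLUMNS = ("onset", "duration", "trial_type")


def write_perception_tsv(ratings: dict[str, PerceptionRatings], path: str | Path) -> None:
    frame = pd.concat(
        [r.to_frame(subject_id) for subject_id, r in sorted(ratings.items())],
        ignore_index=True,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_perception_tsv(path: str | Path) -> dict[str, PerceptionRatings]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return {
        str(subject): PerceptionRatings.from_frame(grp)
        for subject, grp in frame.groupby("subject_id")
    }


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in EVENTS_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"events table is missing columns {missing}")
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENTS_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"events table is missing columns {missing}")
    return events


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_nifti(path: str | Path):
    import nibabel as nib

    img = nib.load(str(path))
    return img.get_fdata(), img.affine


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
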