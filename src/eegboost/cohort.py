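"""Cohort data model: HRSD-21 symptom records, subjects, and the exclusion flow.

The 21-item Hamilton Rating Scale for Depression (HRSD-21) scores ten
symptoms on a 5-point scale (0-4) and eleven on a 3-point scale (0-2).
The outcome modelled throughout this package is the per-item *improvement*,
defined as the week-8 score minus the baseline score, so negative values
indicate that the symptom improved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

N_ITEMS = 21

#: Item names in instrument order (item 1 .. item 21).
ITEM_NAMES: tuple[str, ...] = (
    "depressed mood",
    "self-critical",
    "suicidal thoughts",
    "trouble sleeping",
    "nighttime awakening",
    "waking early",
    "loss of interest",
    "psychomotor retardation",
    "agitation",
    "worrying",
    "physical anxiety",
    "appetite changes",
    "energy loss",
    "libido loss",
    "health preoccupation",
    "weight loss",
    "loss of insight",
    "diurnal variation",
    "unreality and nihilism",
    "paranoia",
    "obsessive thoughts",
)

#: Per-item maximum score: 4 for the ten 5-point items, 2 for the eleven
#: 3-point items (standard HRSD-21 layout).
ITEM_SCALE: tuple[int, ...] = (4, 4, 4, 2, 2, 2, 4, 4, 4, 4, 4, 2, 2, 2, 4, 2, 2, 2, 4, 2, 2)

TREATMENT_ARMS: tuple[str, ...] = ("escitalopram", "sertraline", "venlafaxine_xr")


class CohortError(ValueError):
    """Base class for cohort data errors."""


class DropoutError(CohortError):
    """Raised when an operation requires a week-8 visit that is missing."""


class ScaleViolationError(CohortError):
    """A score falls outside its item's allowed range."""


def _as_items(values: Sequence[int], what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.shape != (N_ITEMS,):
        raise CohortError(f"{what}: expected {N_ITEMS} item scores, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded):
            raise ScaleViolationError(f"{what}: non-integer item scores")
        arr = rounded.astype(int)
    return arr.astype(int)


@dataclass
class SymptomRecord:
    """HRSD-21 item scores for one subject at baseline and (optionally) week 8."""

    subject_id: str
    baseline: np.ndarray
    week8: Optional[np.ndarray] = None
    item_scale: tuple[int, ...] = ITEM_SCALE

    def __post_init__(self) -> None:
        self.baseline = _as_items(self.baseline, f"{self.subject_id} baseline")
        self._check_range(self.baseline, "baseline")
        if self.week8 is not None:
            self.week8 = _as_items(self.week8, f"{self.subject_id} week8")
            self._check_range(self.week8, "week8")

    def _check_range(self, arr: np.ndarray, visit: str) -> None:
        scale = np.asarray(self.item_scale)
        bad = np.nonzero((arr < 0) | (arr > scale))[0]
        if bad.size:
            i = int(bad[0])
            raise ScaleViolationError(
                f"subject {self.subject_id!r}, {visit} item {i + 1}: "
                f"score {arr[i]} outside [0, {scale[i]}]"
            )

    @property
    def has_week8(self) -> bool:
        return self.week8 is not None


def compute_improvement(record: SymptomRecord) -> np.ndarray:
    """Per-item improvement, week8 - baseline (negative = improved).

    Raises :class:`DropoutError` if the week-8 visit is absent.
    """
    if record.week8 is None:
        raise DropoutError(f"subject {record.subject_id!r} has no week-8 visit")
    return record.week8 - record.baseline


@dataclass
class Subject:
    subject_id: str
    symptom_record: SymptomRecord
    eeg_present: bool = True
    features_complete: bool = True
    treatment_arm: Optional[str] = None

    def __post_init__(self) -> None:
        if self.treatment_arm is not None and self.treatment_arm not in TREATMENT_ARMS:
            raise CohortError(
                f"subject {self.subject_id!r}: unknown treatment arm {self.treatment_arm!r}"
            )


@dataclass
class CohortDataset:
    """An ordered collection of subjects plus a provenance log of exclusions."""

    subjects: list[Subject] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate subject_ids: {dup}")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def improvement_matrix(self) -> pd.DataFrame:
        """n_subjects x 21 signed-integer improvements, indexed by subject_id."""
        rows = [compute_improvement(s.symptom_record) for s in self.subjects]
        return pd.DataFrame(
            np.asarray(rows, dtype=int),
            index=self.subject_ids,
            columns=[f"item_{i + 1:02d}" for i in range(N_ITEMS)],
        )

    def baseline_matrix(self) -> pd.DataFrame:
        rows = [s.symptom_record.baseline for s in self.subjects]
        return pd.DataFrame(
            np.asarray(rows, dtype=int),
            index=self.subject_ids,
            columns=[f"item_{i + 1:02d}" for i in range(N_ITEMS)],
        )

    def treatment_dummies(self) -> pd.DataFrame:
        """Three binary indicator columns, one per treatment arm."""
        data = {
            f"treatment {arm}": [int(s.treatment_arm == arm) for s in self.subjects]
            for arm in TREATMENT_ARMS
        }
        return pd.DataFrame(data, index=self.subject_ids)

    def write_provenance(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.provenance, indent=2) + "\n")


def apply_exclusions(roster: Iterable[Subject]) -> CohortDataset:
    """Apply the cohort exclusion flow in order: dropouts, missing EEG,
    missing features.  Each count is measured among the subjects surviving
    the previous step; the counts are recorded in the provenance log.
    """
    current = list(roster)
    total = len(current)
    provenance: list[dict] = [{"step": "enrolled", "excluded": 0, "remaining": total}]

    steps = [
        ("dropped out", lambda s: s.symptom_record.has_week8),
        ("missing EEG", lambda s: s.eeg_present),
        ("missing features", lambda s: s.features_complete),
    ]
    for name, keep in steps:
        kept = [s for s in current if keep(s)]
        provenance.append(
            {"step": name, "excluded": len(current) - len(kept), "remaining": len(kept)}
        )
        current = kept

    return CohortDataset(subjects=current, provenance=provenance)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Wide layout, one row per subject:
#   subject_id, treatment, eeg_present, features_complete,
#   baseline_item_01..baseline_item_21, week8_item_01..week8_item_21
# week8 columns are left blank for dropouts.  UTF-8, comma separated,
# header row.  Round trips losslessly.

_BASE_COLS = [f"baseline_item_{i + 1:02d}" for i in range(N_ITEMS)]
_WK8_COLS = [f"week8_item_{i + 1:02d}" for i in range(N_ITEMS)]


def write_scores(subjects: Iterable[Subject], path: str | Path) -> None:
    rows = []
    for s in subjects:
        row: dict = {
            "subject_id": s.subject_id,
            "treatment": s.treatment_arm if s.treatment_arm is not None else "",
            "eeg_present": int(s.eeg_present),
            "features_complete": int(s.features_complete),
        }
        for i, c in enumerate(_BASE_COLS):
            row[c] = int(s.symptom_record.baseline[i])
        for i, c in enumerate(_WK8_COLS):
            row[c] = int(s.symptom_record.week8[i]) if s.symptom_record.week8 is not None else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scores(path: str | Path) -> list[Subject]:
    """Read a cohort scores CSV, validating scales row by row.

    Raises :class:`CohortError` with the offending row number on malformed
    rows, out-of-range scores, or duplicated subject ids.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "treatment": str}, keep_default_na=False)
    missing = [c for c in ["subject_id"] + _BASE_COLS if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing required columns {missing}")

    seen: set[str] = set()
    subjects: list[Subject] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        rownum = pos + 2  # 1-based, after header
        sid = str(row["subject_id"])
        if sid in seen:
            raise CohortError(f"{path} row {rownum}: duplicate subject_id {sid!r}")
        seen.add(sid)
        try:
            baseline = [int(row[c]) for c in _BASE_COLS]
            wk8_raw = [row.get(c, "") for c in _WK8_COLS]
            has_wk8 = all(str(v).strip() != "" for v in wk8_raw)
            week8 = [int(v) for v in wk8_raw] if has_wk8 else None
            record = SymptomRecord(subject_id=sid, baseline=baseline, week8=week8)
        except (ValueError, CohortError) as exc:
            raise CohortError(f"{path} row {rownum}: {exc}") from exc
        arm = str(row.get("treatment", "")).strip() or None
        eeg = bool(int(row["eeg_present"])) if "eeg_present" in df.columns else True
        feats = bool(int(row["features_complete"])) if "features_complete" in df.columns else True
        try:
            subjects.append(
                Subject(
                    subject_id=sid,
                    symptom_record=record,
                    eeg_present=eeg,
                    features_complete=feats,
                    treatment_arm=arm,
                )
            )
        except CohortError as exc:
            raise CohortError(f"{path} row {rownum}: {exc}") from exc
    return subjects
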