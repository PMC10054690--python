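"""Domain types and file I/O for multi-reader annotation studies.

A reader study consists of annotation records (one bounding box placed by one
observer on one slice, with an ordinal confidence), an observer table with
experience fields, and a slice-level reference standard.  This module holds
those types, their CSV dialects, the slice-level score reduction, the
per-observer binarization rule, and the experience grouping logic.

Conventions: box coordinates are pixel-based, origin top-left, 0-based,
max-exclusive; annotation tables are comma-separated UTF-8 with LF line
endings and a fixed header so that write followed by read is the identity.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationRecord",
    "ObserverProfile",
    "GroupCutoffs",
    "GroupAssignment",
    "ScoreMatrix",
    "LabelMatrix",
    "ReferenceStandard",
    "read_annotations",
    "write_annotations",
    "read_observers",
    "write_observers",
    "read_reference",
    "write_reference",
    "slice_scores",
    "binarize_scores",
    "assign_groups",
    "group_members",
    "cohort_summary",
    "stratified_sample",
    "export_study_json",
]

CONFIDENCE_LEVELS = (1, 2, 3, 4, 5)

ANNOTATION_COLUMNS = [
    "observer_id",
    "patient_id",
    "slice_id",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "confidence",
    "session",
]

OBSERVER_COLUMNS = [
    "observer_id",
    "years_experience",
    "cine_cases",
    "adhesion_cases",
    "clinical_threshold_pct",
    "is_consensus",
]

REFERENCE_COLUMNS = ["slice_id", "patient_id", "label"]

#: canonical group names, in the order reporting tables list them
GROUP_NAMES = (
    "consensus",
    "low-year",
    "high-year",
    "low-cine",
    "high-cine",
    "low-adhesion",
    "high-adhesion",
)


class StudyDataError(ValueError):
    """Raised for malformed or inconsistent study inputs."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One bounding box placed by one observer on one slice.

    ``confidence`` is the observer's certainty that the finding is an
    adhesion, on a 5-point ordinal scale; ``session`` distinguishes repeat
    readings of the same slice set.
    """

    observer_id: str
    patient_id: str
    slice_id: str
    box: tuple[float, float, float, float]  # (x_min, y_min, x_max, y_max)
    confidence: int
    session: int = 1

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCE_LEVELS:
            raise StudyDataError(
                f"confidence must be in 1..5, got {self.confidence!r}"
            )
        x_min, y_min, x_max, y_max = self.box
        if not (x_min < x_max and y_min < y_max):
            raise StudyDataError(f"degenerate box {self.box!r}")
        if self.session not in (1, 2):
            raise StudyDataError(f"session must be 1 or 2, got {self.session!r}")


@dataclass(frozen=True)
class ObserverProfile:
    """Experience fields and clinical threshold for one observer.

    ``clinical_threshold_pct`` is the minimum certainty (as a percent, a
    multiple of 20 matching the 5-point scale) at which the observer would
    call a finding clinically significant; it drives the binarization of
    that observer's confidence scores.  ``adhesion_cases <= cine_cases`` is
    deliberately NOT required.
    """

    observer_id: str
    years_experience: int
    cine_cases: int
    adhesion_cases: int
    clinical_threshold_pct: int
    is_consensus: bool = False

    def __post_init__(self) -> None:
        if self.years_experience < 0 or self.cine_cases < 0 or self.adhesion_cases < 0:
            raise StudyDataError(f"negative experience field in {self}")
        if self.clinical_threshold_pct not in (0, 20, 40, 60, 80, 100):
            raise StudyDataError(
                "clinical_threshold_pct must be a multiple of 20 in 0..100, "
                f"got {self.clinical_threshold_pct!r}"
            )


@dataclass(frozen=True)
class GroupCutoffs:
    """Experience cutoffs separating low from high groups (high iff >= cutoff)."""

    years_cutoff: int = 5
    cine_cutoff: int = 30
    adhesion_cutoff: int = 2

    def __post_init__(self) -> None:
        if min(self.years_cutoff, self.cine_cutoff, self.adhesion_cutoff) <= 0:
            raise StudyDataError("all group cutoffs must be positive")


@dataclass(frozen=True)
class GroupAssignment:
    """Group membership of one observer: consensus, or low/high per dimension."""

    observer_id: str
    consensus: bool
    year: str | None  # "low" | "high" | None for consensus readers
    cine: str | None
    adhesion: str | None

    @property
    def groups(self) -> tuple[str, ...]:
        """Names of the reporting groups this observer belongs to."""
        if self.consensus:
            return ("consensus",)
        return (
            f"{self.year}-year",
            f"{self.cine}-cine",
            f"{self.adhesion}-adhesion",
        )


@dataclass(frozen=True)
class ScoreMatrix:
    """Slice x observer ordinal scores in {0..5} for one reading session.

    0 means the observer placed no box on the slice; 1-5 is the maximum
    confidence over the observer's boxes on the slice.  No missing cells.
    """

    scores: pd.DataFrame  # index = slice ids, columns = observer ids
    session: int = 1

    def __post_init__(self) -> None:
        df = self.scores
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise StudyDataError("slice and observer identifiers must be unique")
        values = df.to_numpy()
        if values.size and not np.isin(values, range(6)).all():
            raise StudyDataError("scores must be integers in 0..5")

    @property
    def slices(self) -> list[str]:
        return list(self.scores.index)

    @property
    def observers(self) -> list[str]:
        return list(self.scores.columns)


@dataclass(frozen=True)
class LabelMatrix:
    """Slice x observer binary diagnoses (True = positive for adhesions)."""

    labels: pd.DataFrame  # boolean, same shape as the source ScoreMatrix

    def __post_init__(self) -> None:
        if not all(dt == bool for dt in self.labels.dtypes):
            raise StudyDataError("label matrix must be boolean")

    @property
    def slices(self) -> list[str]:
        return list(self.labels.index)

    @property
    def observers(self) -> list[str]:
        return list(self.labels.columns)

    def values(self) -> np.ndarray:
        return self.labels.to_numpy()


@dataclass(frozen=True)
class ReferenceStandard:
    """Consensus truth per slice, with the induced patient-level labels.

    A patient is positive iff at least one of its slices is positive; this is
    validated at construction.
    """

    slice_labels: pd.Series  # bool, index = slice ids
    slice_to_patient: pd.Series  # patient id per slice id

    def __post_init__(self) -> None:
        if not self.slice_labels.index.equals(self.slice_to_patient.index):
            raise StudyDataError("slice_labels and slice_to_patient must share an index")
        if self.slice_labels.index.duplicated().any():
            raise StudyDataError("duplicate slice ids in reference standard")

    @property
    def patient_labels(self) -> pd.Series:
        return self.slice_labels.groupby(self.slice_to_patient).any()

    @property
    def n_positive_slices(self) -> int:
        return int(self.slice_labels.sum())

    @property
    def n_negative_slices(self) -> int:
        return int((~self.slice_labels).sum())


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _format_coord(x: float) -> str:
    # repr round-trips floats exactly; integers print without trailing .0
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    """Write annotation records as CSV (fixed column order, LF endings)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.observer_id,
                    r.patient_id,
                    r.slice_id,
                    *(_format_coord(c) for c in r.box),
                    r.confidence,
                    r.session,
                ]
            )


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read and validate an annotation table written by :func:`write_annotations`."""
    path = Path(path)
    records: list[AnnotationRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ANNOTATION_COLUMNS:
            raise StudyDataError(
                f"{path}: expected header {ANNOTATION_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(ANNOTATION_COLUMNS):
                raise StudyDataError(f"{path}:{lineno}: expected "
                                     f"{len(ANNOTATION_COLUMNS)} fields, got {len(row)}")
            try:
                record = AnnotationRecord(
                    observer_id=row[0],
                    patient_id=row[1],
                    slice_id=row[2],
                    box=tuple(float(v) for v in row[3:7]),
                    confidence=int(row[7]),
                    session=int(row[8]),
                )
            except StudyDataError as exc:
                raise StudyDataError(f"{path}:{lineno}: {exc}") from None
            except ValueError as exc:
                raise StudyDataError(f"{path}:{lineno}: malformed row: {exc}") from None
            records.append(record)
    return records


def write_observers(profiles: Iterable[ObserverProfile], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(OBSERVER_COLUMNS)
        for p in profiles:
            writer.writerow(
                [
                    p.observer_id,
                    p.years_experience,
                    p.cine_cases,
                    p.adhesion_cases,
                    p.clinical_threshold_pct,
                    int(p.is_consensus),
                ]
            )


def read_observers(path: str | Path) -> list[ObserverProfile]:
    path = Path(path)
    profiles: list[ObserverProfile] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != OBSERVER_COLUMNS:
            raise StudyDataError(
                f"{path}: expected header {OBSERVER_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                profiles.append(
                    ObserverProfile(
                        observer_id=row[0],
                        years_experience=int(row[1]),
                        cine_cases=int(row[2]),
                        adhesion_cases=int(row[3]),
                        clinical_threshold_pct=int(row[4]),
                        is_consensus=bool(int(row[5])),
                    )
                )
            except (StudyDataError, ValueError, IndexError) as exc:
                raise StudyDataError(f"{path}:{lineno}: {exc}") from None
    return profiles


def write_reference(reference: ReferenceStandard, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(REFERENCE_COLUMNS)
        for slice_id, label in reference.slice_labels.items():
            writer.writerow(
                [
                    slice_id,
                    reference.slice_to_patient[slice_id],
                    "positive" if label else "negative",
                ]
            )


def read_reference(path: str | Path) -> ReferenceStandard:
    path = Path(path)
    slice_ids: list[str] = []
    patients: list[str] = []
    labels: list[bool] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != REFERENCE_COLUMNS:
            raise StudyDataError(
                f"{path}: expected header {REFERENCE_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3 or row[2] not in ("positive", "negative"):
                raise StudyDataError(f"{path}:{lineno}: malformed reference row {row}")
            slice_ids.append(row[0])
            patients.append(row[1])
            labels.append(row[2] == "positive")
    return ReferenceStandard(
        slice_labels=pd.Series(labels, index=slice_ids, dtype=bool),
        slice_to_patient=pd.Series(patients, index=slice_ids),
    )


def export_study_json(
    records: Sequence[AnnotationRecord],
    profiles: Sequence[ObserverProfile],
    reference: ReferenceStandard,
    path: str | Path,
) -> None:
    """Serialize a parsed study as a single JSON document for downstream use."""
    doc = {
        "annotations": [
            {
                "observer_id": r.observer_id,
                "patient_id": r.patient_id,
                "slice_id": r.slice_id,
                "box": list(r.box),
                "confidence": r.confidence,
                "session": r.session,
            }
            for r in records
        ],
        "observers": [
            {
                "observer_id": p.observer_id,
                "years_experience": p.years_experience,
                "cine_cases": p.cine_cases,
                "adhesion_cases": p.adhesion_cases,
                "clinical_threshold_pct": p.clinical_threshold_pct,
                "is_consensus": p.is_consensus,
            }
            for p in profiles
        ],
        "reference": {
            "slice_labels": {
                s: bool(v) for s, v in reference.slice_labels.items()
            },
            "slice_to_patient": dict(reference.slice_to_patient.items()),
        },
    }
    with open(path, "w", encoding="utf-8", newline="") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Scoring, binarization, grouping
# ---------------------------------------------------------------------------


def slice_scores(
    records: Iterable[AnnotationRecord],
    all_slices: Sequence[str],
    all_observers: Sequence[str],
    session: int = 1,
) -> ScoreMatrix:
    """Reduce box annotations to a slice x observer ordinal score matrix.

    Each cell is the maximum confidence over that observer's boxes on that
    slice in the given session; slices the observer left unannotated score 0
    (readers submit every slice, so 0 is an explicit negative, not missing
    data).
    """
    scores = pd.DataFrame(
        0, index=list(all_slices), columns=list(all_observers), dtype=int
    )
    slice_set = set(all_slices)
    observer_set = set(all_observers)
    for r in records:
        if r.session != session:
            continue
        if r.slice_id not in slice_set:
            raise StudyDataError(f"unknown slice id {r.slice_id!r} in records")
        if r.observer_id not in observer_set:
            raise StudyDataError(f"unknown observer id {r.observer_id!r} in records")
        current = scores.at[r.slice_id, r.observer_id]
        if r.confidence > current:
            scores.at[r.slice_id, r.observer_id] = r.confidence
    return ScoreMatrix(scores=scores, session=session)


def binarize_scores(
    matrix: ScoreMatrix, profiles: Mapping[str, ObserverProfile] | Sequence[ObserverProfile]
) -> LabelMatrix:
    """Binarize ordinal scores with each observer's clinical threshold.

    A cell is positive iff the observer annotated the slice (score > 0) AND
    the confidence, mapped to percent as 20 x score, is at least the
    observer's clinical-significance threshold.  A 0% threshold means any
    annotation counts as positive; an unannotated slice is never positive.
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.observer_id: p for p in profiles}
    missing = [o for o in matrix.observers if o not in profiles]
    if missing:
        raise StudyDataError(f"missing observer profile(s): {missing}")
    thresholds = np.array(
        [profiles[o].clinical_threshold_pct for o in matrix.observers]
    )
    values = matrix.scores.to_numpy()
    positive = (values > 0) & (values * 20 >= thresholds[np.newaxis, :])
    return LabelMatrix(
        labels=pd.DataFrame(
            positive, index=matrix.scores.index, columns=matrix.scores.columns
        )
    )


def assign_groups(
    profile: ObserverProfile, cutoffs: GroupCutoffs = GroupCutoffs()
) -> GroupAssignment:
    """Place an observer into the consensus group or low/high experience groups.

    Consensus readers belong to the consensus group only.  Otherwise the
    observer is "high" in a dimension iff the corresponding experience count
    reaches the cutoff (>=).
    """
    if profile.is_consensus:
        return GroupAssignment(
            observer_id=profile.observer_id,
            consensus=True,
            year=None,
            cine=None,
            adhesion=None,
        )

    def side(value: int, cutoff: int) -> str:
        return "high" if value >= cutoff else "low"

    return GroupAssignment(
        observer_id=profile.observer_id,
        consensus=False,
        year=side(profile.years_experience, cutoffs.years_cutoff),
        cine=side(profile.cine_cases, cutoffs.cine_cutoff),
        adhesion=side(profile.adhesion_cases, cutoffs.adhesion_cutoff),
    )


def group_members(
    profiles: Sequence[ObserverProfile], cutoffs: GroupCutoffs = GroupCutoffs()
) -> dict[str, list[str]]:
    """Map each reporting group name to its (ordered) observer ids.

    All seven canonical groups are present as keys; a group nobody belongs to
    maps to an empty list.
    """
    members: dict[str, list[str]] = {name: [] for name in GROUP_NAMES}
    for p in profiles:
        for g in assign_groups(p, cutoffs).groups:
            members[g].append(p.observer_id)
    return members


def cohort_summary(patient_labels: Mapping[str, bool] | pd.Series) -> dict[str, int]:
    """Count patients without adhesions and their share of the cohort.

    ``pct_negative`` is rounded to the nearest integer percent (half away
    from zero).
    """
    labels = pd.Series(patient_labels, dtype=bool)
    n = len(labels)
    if n == 0:
        raise StudyDataError("empty cohort")
    n_negative = int((~labels).sum())
    pct = int(math.floor(100.0 * n_negative / n + 0.5))
    return {"n_patients": n, "n_negative": n_negative, "pct_negative": pct}


def stratified_sample(
    patient_labels: Mapping[str, bool] | pd.Series,
    fraction: float,
    seed: int,
    rounding: str = "ceil",
) -> list[str]:
    """Sample patients without replacement within each label stratum.

    Keeps the relative prevalence of the cohort by sampling the same fraction
    from the positive and negative groups separately.  Per-stratum counts are
    ``fraction * n`` rounded by ``rounding`` ("ceil", "floor" or "round").
    Deterministic given ``seed``; output order follows the input order.
    """
    if not 0 < fraction <= 1:
        raise StudyDataError(f"fraction must be in (0, 1], got {fraction}")
    rounders = {"ceil": math.ceil, "floor": math.floor, "round": round}
    if rounding not in rounders:
        raise StudyDataError(f"rounding must be one of {sorted(rounders)}")
    labels = pd.Series(patient_labels, dtype=bool)
    rng = np.random.default_rng(seed)
    chosen: set[str] = set()
    for value in (False, True):  # fixed stratum order for determinism
        stratum = [p for p, v in labels.items() if v == value]
        if not stratum:
            continue
        k = min(len(stratum), int(rounders[rounding](fraction * len(stratum))))
        chosen.update(rng.choice(stratum, size=k, replace=False))
    return [p for p in labels.index if p in chosen]
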