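"""Per-patient score tables and confusion counts.

Every stage of the follow-up pipeline consumes one universal input: a table
with one row per patient carrying the binary ground-truth label (1 = local
recurrent nasopharyngeal carcinoma, 0 = recurrence-free) and the three
per-sequence model scores — T1WI, T2WI and post-contrast T1WIC — each a
probability-like value in [0, 1].  This module owns that table, its CSV
serialisation (header ``patient_id,label,score_t1wi,score_t2wi,score_t1wic``)
and the 2x2 confusion counts from which every diagnostic metric derives.

All three scores are required for every patient: the layered tactic is
defined over the fused T1WI/T2WI score *and* the T1WIC adjudicator, so a
missing score is a hard validation error rather than an imputable gap.
"""

from __future__ import annotations

import csv
from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "SCORE_COLUMNS",
    "LABEL_NAMES",
    "ScoreTableFormatError",
    "ScoreTableValidationError",
    "ScoreRecord",
    "ScoreTable",
    "ConfusionMatrix",
    "read_score_table",
    "write_score_table",
    "confusion_from_calls",
]

REQUIRED_COLUMNS = ("patient_id", "label", "score_t1wi", "score_t2wi", "score_t1wic")
SCORE_COLUMNS = REQUIRED_COLUMNS[2:]

#: textual label coding accepted by :func:`read_score_table` via ``label_names=True``
LABEL_NAMES = {"recurrent": 1, "free": 0}


class ScoreTableFormatError(ValueError):
    """The file lacks a required column or is otherwise malformed."""


class ScoreTableValidationError(ValueError):
    """A row violates a domain invariant (score range, label coding, duplicate id)."""


@dataclass(frozen=True)
class ScoreRecord:
    """One patient: id, recurrence label and the three sequence-model scores."""

    patient_id: str
    label: int
    score_t1wi: float
    score_t2wi: float
    score_t1wic: float

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ScoreTableValidationError(
                f"patient {self.patient_id!r}: label must be 0 or 1, got {self.label!r}"
            )
        for name in SCORE_COLUMNS:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and 0.0 <= float(value) <= 1.0):
                raise ScoreTableValidationError(
                    f"patient {self.patient_id!r}: {name} must lie in [0, 1], got {value!r}"
                )


@dataclass(frozen=True)
class ScoreTable:
    """Ordered, validated collection of :class:`ScoreRecord`.

    Parameters
    ----------
    records
        Per-patient records; order is preserved through serialisation.
    cohort_tag
        Free-text provenance tag (e.g. ``"internal"``, ``"external"``,
        ``"synthetic"``); carried along, never interpreted.
    """

    records: tuple[ScoreRecord, ...]
    cohort_tag: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ScoreTableValidationError("a score table must contain at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id in seen:
                raise ScoreTableValidationError(f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ScoreRecord]:
        return iter(self.records)

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(rec.patient_id for rec in self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([rec.label for rec in self.records], dtype=int)

    @property
    def t1wi(self) -> np.ndarray:
        return np.array([rec.score_t1wi for rec in self.records], dtype=float)

    @property
    def t2wi(self) -> np.ndarray:
        return np.array([rec.score_t2wi for rec in self.records], dtype=float)

    @property
    def t1wic(self) -> np.ndarray:
        return np.array([rec.score_t1wic for rec in self.records], dtype=float)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return len(self) - self.n_pos

    @classmethod
    def from_arrays(
        cls,
        patient_ids: Sequence[str],
        labels: Sequence[int],
        t1wi: Sequence[float],
        t2wi: Sequence[float],
        t1wic: Sequence[float],
        cohort_tag: str = "",
    ) -> "ScoreTable":
        if not (len(patient_ids) == len(labels) == len(t1wi) == len(t2wi) == len(t1wic)):
            raise ScoreTableValidationError("array lengths differ")
        records = tuple(
            ScoreRecord(str(pid), int(lab), float(a), float(b), float(c))
            for pid, lab, a, b, c in zip(patient_ids, labels, t1wi, t2wi, t1wic)
        )
        return cls(records, cohort_tag)

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a :class:`pandas.DataFrame` (columns as on disk)."""
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "label": self.labels,
                "score_t1wi": self.t1wi,
                "score_t2wi": self.t2wi,
                "score_t1wic": self.t1wic,
            }
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts for binary recurrence calls against ground truth."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


def _parse_label(raw: str, patient_id: str, label_names: bool) -> int:
    text = raw.strip()
    if label_names and text.lower() in LABEL_NAMES:
        return LABEL_NAMES[text.lower()]
    try:
        value = int(text)
    except ValueError:
        raise ScoreTableValidationError(
            f"patient {patient_id!r}: label {raw!r} is not binary"
        ) from None
    if value not in (0, 1):
        raise ScoreTableValidationError(f"patient {patient_id!r}: label must be 0 or 1, got {value}")
    return value


def read_score_table(
    path: str | Path,
    *,
    delimiter: str = ",",
    label_names: bool = False,
    cohort_tag: str | None = None,
) -> ScoreTable:
    """Read and validate a delimited score table.

    Parameters
    ----------
    path
        CSV file whose header names the five required columns (extra columns
        are ignored).
    delimiter
        Field delimiter, comma by default.
    label_names
        Additionally accept the textual coding ``"recurrent"``/``"free"``.
    cohort_tag
        Tag for the returned table; defaults to the file stem.

    Raises
    ------
    ScoreTableFormatError
        Missing file or missing required column (named in the message).
    ScoreTableValidationError
        Score outside [0, 1], non-binary label, missing value or duplicate
        patient id (offending patient named in the message).
    """
    path = Path(path)
    if not path.exists():
        raise ScoreTableFormatError(f"score table not found: {path}")
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ScoreTableFormatError(f"{path}: empty file, expected a header row")
        for column in REQUIRED_COLUMNS:
            if column not in reader.fieldnames:
                raise ScoreTableFormatError(f"{path}: missing required column {column!r}")
        records: list[ScoreRecord] = []
        for row in reader:
            pid = (row["patient_id"] or "").strip()
            if not pid:
                raise ScoreTableValidationError(f"{path}: row {reader.line_num} has empty patient_id")
            label = _parse_label(row["label"] or "", pid, label_names)
            scores: list[float] = []
            for column in SCORE_COLUMNS:
                raw = (row[column] or "").strip()
                if not raw:
                    raise ScoreTableValidationError(f"patient {pid!r}: missing value for {column}")
                try:
                    scores.append(float(raw))
                except ValueError:
                    raise ScoreTableValidationError(
                        f"patient {pid!r}: {column} value {raw!r} is not a number"
                    ) from None
            records.append(ScoreRecord(pid, label, *scores))
    if not records:
        raise ScoreTableFormatError(f"{path}: no data rows")
    tag = path.stem if cohort_tag is None else cohort_tag
    return ScoreTable(tuple(records), tag)


def write_score_table(table: ScoreTable, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a score table as UTF-8 delimited text; floats use shortest repr
    so that a write/read round-trip reproduces every field exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(REQUIRED_COLUMNS)
        for rec in table.records:
            writer.writerow(
                [
                    rec.patient_id,
                    rec.label,
                    repr(rec.score_t1wi),
                    repr(rec.score_t2wi),
                    repr(rec.score_t1wic),
                ]
            )


def confusion_from_calls(labels: Sequence[int], calls: Sequence[int]) -> ConfusionMatrix:
    """Tally TP/FN/FP/TN from paired ground-truth labels and binary calls."""
    labels_arr = np.asarray(labels, dtype=int)
    calls_arr = np.asarray(calls, dtype=int)
    if labels_arr.shape != calls_arr.shape or labels_arr.ndim != 1 or labels_arr.size == 0:
        raise ValueError("labels and calls must be equal-length non-empty 1-d vectors")
    for name, arr in (("labels", labels_arr), ("calls", calls_arr)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    pos = labels_arr == 1
    called = calls_arr == 1
    return ConfusionMatrix(
        tp=int((pos & called).sum()),
        fn=int((pos & ~called).sum()),
        fp=int((~pos & called).sum()),
        tn=int((~pos & ~called).sum()),
    )
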