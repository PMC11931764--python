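"""The layered follow-up rule (DARNDEST) and strategy-level evaluation.

Each patient is triaged on the fused unenhanced score into one of three
groups:

positive
    fused score >= ``c1``; called recurrent outright.  The group receives a
    contrast-enhanced examination (work-up of a positive call), but the call
    itself does not depend on the T1WIC score.
suspicious
    ``c2`` <= fused score < ``c1``; referred for a contrast-enhanced scan
    and adjudicated by the T1WIC model: called recurrent iff
    T1WIC score >= ``c3``.
negative
    fused score < ``c2``; unenhanced examination only, called
    recurrence-free.

Boundary scores equal to a cutoff fall on the positive/suspicious side
(the ">=" rule used module-wide).

Besides the layered rule, :func:`evaluate_strategy` evaluates the two
single-model comparators (fused-score-only, T1WIC-only) and the conventional
strategy (everyone scanned with contrast; its diagnostic calls are out of
scope here — it exists for the cost/time comparison).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cutoffs import CutoffSet, fuse_scores
from .metrics import DiagnosticSummary, diagnostic_summary
from .score_io import ConfusionMatrix, ScoreRecord, ScoreTable, confusion_from_calls

__all__ = [
    "GROUPS",
    "STRATEGIES",
    "TriageOutcome",
    "StrategyEvaluation",
    "DiagnosticsUnavailableError",
    "darndest_assign",
    "assign_table",
    "evaluate_strategy",
]

GROUPS = ("positive", "suspicious", "negative")
STRATEGIES = ("t1_t2_only", "t1wic_only", "darndest", "conventional")


class DiagnosticsUnavailableError(RuntimeError):
    """Diagnostics were requested for a strategy that makes no calls
    (the conventional everyone-enhanced strategy)."""


@dataclass(frozen=True)
class TriageOutcome:
    """One patient's triage result: group, examination mode, final call."""

    patient_id: str
    group: str
    mri_mode: str
    final_call: int


def darndest_assign(record: ScoreRecord, cutoffs: CutoffSet) -> TriageOutcome:
    """Apply the layered rule to a single patient."""
    fused = fuse_scores(record.score_t1wi, record.score_t2wi)
    if fused >= cutoffs.c1:
        return TriageOutcome(record.patient_id, "positive", "enhanced", 1)
    if fused >= cutoffs.c2:
        call = 1 if record.score_t1wic >= cutoffs.c3 else 0
        return TriageOutcome(record.patient_id, "suspicious", "enhanced", call)
    return TriageOutcome(record.patient_id, "negative", "unenhanced", 0)


def assign_table(table: ScoreTable, cutoffs: CutoffSet) -> list[TriageOutcome]:
    """Apply the layered rule to every patient, preserving row order."""
    return [darndest_assign(rec, cutoffs) for rec in table.records]


class StrategyEvaluation:
    """Diagnostics and group composition of one strategy on one cohort.

    ``group_counts``, ``group_true_counts`` and ``group_detected_counts``
    map group name to, respectively, patients triaged there, true
    recurrences among them, and true recurrences the strategy's final calls
    detect there.  ``confusion`` and ``summary`` raise
    :class:`DiagnosticsUnavailableError` for the conventional strategy.
    """

    def __init__(
        self,
        strategy_name: str,
        group_counts: dict[str, int],
        group_true_counts: dict[str, int],
        group_detected_counts: dict[str, int] | None,
        confusion: ConfusionMatrix | None,
        summary: DiagnosticSummary | None,
    ) -> None:
        self.strategy_name = strategy_name
        self.group_counts = dict(group_counts)
        self.group_true_counts = dict(group_true_counts)
        self.group_detected_counts = dict(group_detected_counts or {})
        self._confusion = confusion
        self._summary = summary

    @property
    def confusion(self) -> ConfusionMatrix:
        if self._confusion is None:
            raise DiagnosticsUnavailableError(
                f"strategy {self.strategy_name!r} makes no diagnostic calls"
            )
        return self._confusion

    @property
    def summary(self) -> DiagnosticSummary:
        if self._summary is None:
            raise DiagnosticsUnavailableError(
                f"strategy {self.strategy_name!r} makes no diagnostic calls"
            )
        return self._summary

    @property
    def has_diagnostics(self) -> bool:
        return self._summary is not None

    @property
    def table_n(self) -> int:
        return sum(self.group_counts.values())

    @property
    def n_true(self) -> int:
        return sum(self.group_true_counts.values())

    def to_dict(self) -> dict:
        out: dict = {
            "strategy": self.strategy_name,
            "group_counts": self.group_counts,
            "group_true_counts": self.group_true_counts,
            "group_detected_counts": self.group_detected_counts,
        }
        if self.has_diagnostics:
            cm = self.confusion
            out["confusion"] = {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn}
            out["summary"] = self.summary.to_dict()
        return out


def _group_tallies(
    groups: np.ndarray, labels: np.ndarray, calls: np.ndarray, names: tuple[str, ...]
) -> tuple[dict[str, int], dict[str, int], dict[str, int]]:
    counts, true_counts, detected = {}, {}, {}
    for name in names:
        mask = groups == name
        counts[name] = int(mask.sum())
        true_counts[name] = int((mask & (labels == 1)).sum())
        detected[name] = int((mask & (labels == 1) & (calls == 1)).sum())
    return counts, true_counts, detected


def evaluate_strategy(table: ScoreTable, cutoffs: CutoffSet, strategy: str) -> StrategyEvaluation:
    """Evaluate one follow-up strategy on a score table.

    Strategies
    ----------
    ``t1_t2_only``
        Positive iff fused score >= ``c1``; nobody receives contrast.
    ``t1wic_only``
        Positive iff T1WIC score >= ``c3``; everybody receives contrast
        (mirrors the enhanced-sequence model row of the comparison tables).
    ``darndest``
        The layered rule (see :func:`darndest_assign`).
    ``conventional``
        Everybody receives contrast; no automated calls — diagnostics on the
        returned evaluation raise :class:`DiagnosticsUnavailableError`.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    labels = table.labels
    n = len(table)

    if strategy == "conventional":
        return StrategyEvaluation(
            strategy,
            group_counts={"all": n},
            group_true_counts={"all": int(labels.sum())},
            group_detected_counts=None,
            confusion=None,
            summary=None,
        )

    if labels.min() == labels.max():
        raise ValueError("both classes must be present to evaluate diagnostics")

    fused = fuse_scores(table.t1wi, table.t2wi)
    if strategy == "t1_t2_only":
        calls = (fused >= cutoffs.c1).astype(int)
        groups = np.where(calls == 1, "positive", "negative")
        names: tuple[str, ...] = ("positive", "negative")
    elif strategy == "t1wic_only":
        calls = (table.t1wic >= cutoffs.c3).astype(int)
        groups = np.where(calls == 1, "positive", "negative")
        names = ("positive", "negative")
    else:  # darndest
        outcomes = assign_table(table, cutoffs)
        calls = np.array([o.final_call for o in outcomes], dtype=int)
        groups = np.array([o.group for o in outcomes])
        names = GROUPS

    counts, true_counts, detected = _group_tallies(groups, labels, calls, names)
    cm = confusion_from_calls(labels, calls)
    return StrategyEvaluation(strategy, counts, true_counts, detected, cm, diagnostic_summary(cm))
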