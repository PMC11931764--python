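"""Score fusion and the two-level cutoff selection that parameterises the
layered triage rule.

Three thresholds drive the tactic (see :mod:`darndest.triage`):

* ``c1`` — first-level cutoff on the fused T1WI/T2WI score; at or above it a
  patient is called positive outright.
* ``c2`` — referral (secondary) cutoff on the fused score, ``c2 <= c1``; at
  or above it a non-positive patient is "suspicious" and referred for a
  contrast-enhanced scan, where the T1WIC model adjudicates.
* ``c3`` — adjudication cutoff on the T1WIC score.

``c1`` and ``c3`` are Youden-index cutoffs of their respective scores.
``c2`` is chosen so the *whole* layered rule keeps sensitivity at or above a
floor (default 90%) while referring as few patients as possible — i.e. the
largest fused-score threshold that still meets the floor.  The call rule is
"positive if score >= threshold" everywhere, and Youden ties break toward the
smallest maximising threshold (favouring sensitivity, which is the quantity
the tactic protects).

``c2`` thresholds the *fused* score, not the T1WIC score: a patient's T1WIC
score cannot exist before the contrast scan that the referral decision
grants.  For exploration, :func:`select_secondary_cutoff` accepts
``on="t1wic"`` to study the alternative reading in which the secondary
threshold is applied to the T1WIC score itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .score_io import ScoreTable

__all__ = [
    "CutoffSet",
    "SecondaryCutoffResult",
    "fuse_scores",
    "youden_cutoff",
    "select_secondary_cutoff",
]

DEFAULT_SENS_FLOOR = 0.90
_FLOOR_EPS = 1e-9  # guards float products like 0.9 * 200 = 180.00000000000003


@dataclass(frozen=True)
class CutoffSet:
    """The triage rule's parameters: ``0 <= c2 <= c1 <= 1`` on the fused
    score, ``c3`` on the T1WIC score, plus the sensitivity floor that chose
    ``c2``."""

    c1: float
    c2: float
    c3: float
    sens_floor: float = DEFAULT_SENS_FLOOR

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.c2 > self.c1:
            raise ValueError(f"c2 must not exceed c1 (got c2={self.c2} > c1={self.c1})")
        if not 0.0 < self.sens_floor <= 1.0:
            raise ValueError(f"sens_floor must lie in (0, 1], got {self.sens_floor}")

    def to_dict(self) -> dict:
        return {"c1": self.c1, "c2": self.c2, "c3": self.c3, "sens_floor": self.sens_floor}

    @classmethod
    def from_dict(cls, data: dict) -> "CutoffSet":
        return cls(
            c1=float(data["c1"]),
            c2=float(data["c2"]),
            c3=float(data["c3"]),
            sens_floor=float(data.get("sens_floor", DEFAULT_SENS_FLOOR)),
        )


def fuse_scores(t1, t2):
    """Equal-weight fusion of the T1WI and T2WI scores: ``0.5*t1 + 0.5*t2``.

    Accepts scalars or arrays; inputs must lie in [0, 1], and so does the
    output (it is the midpoint).
    """
    t1_arr = np.asarray(t1, dtype=float)
    t2_arr = np.asarray(t2, dtype=float)
    for name, arr in (("t1", t1_arr), ("t2", t2_arr)):
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValueError(f"{name} scores must lie in [0, 1]")
    fused = 0.5 * t1_arr + 0.5 * t2_arr
    if np.isscalar(t1) and np.isscalar(t2):
        return float(fused)
    return fused


def youden_cutoff(scores, labels) -> float:
    """Cutoff maximising the Youden index J = sensitivity + specificity - 1.

    Candidate thresholds are the unique observed scores, with the call rule
    "positive if score >= t".  Ties in J break toward the smallest such
    threshold (the most sensitive of the equally good cutoffs).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores and labels must be equal-length non-empty 1-d vectors")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to select a Youden cutoff")
    thresholds = np.unique(scores)  # ascending
    pos_sorted = np.sort(scores[labels == 1])
    neg_sorted = np.sort(scores[labels == 0])
    m, n = len(pos_sorted), len(neg_sorted)
    sens = (m - np.searchsorted(pos_sorted, thresholds, side="left")) / m
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / n
    j = sens + spec - 1.0
    return float(thresholds[int(np.argmax(j))])  # argmax -> first max -> smallest t


@dataclass(frozen=True)
class SecondaryCutoffResult:
    """Outcome of the referral-cutoff search.

    ``value``
        The selected ``c2``, or ``None`` when no referral tier is needed
        (the first-level rule alone already meets the floor).
    ``needed``
        Whether a referral tier is required at all.
    ``floor_met``
        Whether the floor is attainable; when ``False``, ``value`` is 0
        (refer everyone below ``c1``) and sensitivity still falls short
        given the adjudication cutoff ``c3``.
    ``sensitivity``
        The layered rule's overall sensitivity at the returned cutoff.
    """

    value: float | None
    needed: bool
    floor_met: bool
    sensitivity: float

    def resolve(self, c1: float) -> float:
        """The concrete ``c2`` to run with: ``c1`` when no tier is needed
        (an empty suspicious group), else the selected value."""
        return c1 if self.value is None else self.value


def select_secondary_cutoff(
    table: ScoreTable,
    c1: float,
    c3: float,
    sens_floor: float = DEFAULT_SENS_FLOOR,
    *,
    on: str = "fused",
) -> SecondaryCutoffResult:
    """Choose the referral cutoff ``c2`` subject to a sensitivity floor.

    Let S(c2) be the overall sensitivity of the layered rule with cutoffs
    (c1, c2, c3): a recurrence is detected if its fused score is >= c1, or
    its fused score is in [c2, c1) *and* its T1WIC score is >= c3.  S is
    non-increasing in c2, so the search returns the **largest** candidate
    (the unique observed referral-score values below c1, plus 0) with
    S(c2) >= sens_floor — the fewest contrast referrals that honour the
    floor.

    With ``on="t1wic"`` the referral threshold is applied to the T1WIC score
    of non-positive patients instead of the fused score (alternative rule
    reading; detection then requires T1WIC >= max(c2, c3)).
    """
    if on not in ("fused", "t1wic"):
        raise ValueError(f"on must be 'fused' or 't1wic', got {on!r}")
    labels = table.labels
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to select the secondary cutoff")
    fused = fuse_scores(table.t1wi, table.t2wi)
    t1wic = table.t1wic
    referral_score = fused if on == "fused" else t1wic

    n_pos = int(labels.sum())
    base_positive = fused >= c1
    base_tp = int((base_positive & (labels == 1)).sum())
    floor_count = sens_floor * n_pos - _FLOOR_EPS

    if base_tp >= floor_count:
        return SecondaryCutoffResult(
            value=None, needed=False, floor_met=True, sensitivity=base_tp / n_pos
        )

    # recoverable recurrences: missed by the first level but adjudicable
    recoverable = (labels == 1) & ~base_positive & (t1wic >= c3)
    rec_sorted = np.sort(referral_score[recoverable])

    candidates = np.unique(referral_score[~base_positive])
    candidates = candidates[candidates < c1]
    candidates = np.concatenate([[0.0], candidates])  # descending search below
    # extra detections at threshold t = #(recoverable with referral score >= t)
    extra = len(rec_sorted) - np.searchsorted(rec_sorted, candidates, side="left")
    total_tp = base_tp + extra
    feasible = total_tp >= floor_count
    if not feasible.any():
        return SecondaryCutoffResult(
            value=0.0,
            needed=True,
            floor_met=False,
            sensitivity=(base_tp + len(rec_sorted)) / n_pos,
        )
    idx = int(np.flatnonzero(feasible).max())  # candidates ascend -> largest feasible
    return SecondaryCutoffResult(
        value=float(candidates[idx]),
        needed=True,
        floor_met=True,
        sensitivity=float(total_tp[idx]) / n_pos,
    )
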