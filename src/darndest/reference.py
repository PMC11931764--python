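"""Reference worked-example tables for the two evaluation cohorts.

The layered tactic was tuned and reported on an internal test cohort
(n = 433, 197 local recurrences) and an external one (n = 202, 93
recurrences).  This module freezes the published per-model confusion
quadruples, diagnostic-table cells, cutoffs, cohort-scale economics and
per-sequence AUCs, and can synthesise a score table whose calls realise the
published quadruples exactly — the worked example behind the regression
suite and the ``fixtures`` CLI subcommand.

Two published specificity cells (internal T1WI 82.57 and internal T2WI
85.32) are inconsistent with their own TP/FN/FP/TN quadruples, both of which
give 196/236 = 83.05 — the value their published confidence intervals
(78.26, 87.84) correspond to.  ``TABLE1`` carries the quadruple-consistent
values.  The radiologist ("doctor") rows are kept as point estimates only:
their published intervals were not computed with the Wald method used for
the model rows.

Test-set group tallies in ``TEST_SET_GROUPS`` are reconstructed: each entry
is the unique integer count whose scaling to the 1,000-patient hypothetical
cohort reproduces the published cohort-scale figure, and together they are
consistent with the published fused-model and layered-rule quadruples.
"""

from __future__ import annotations

from .cutoffs import CutoffSet
from .score_io import ConfusionMatrix, ScoreTable

__all__ = [
    "COHORTS",
    "TABLE1",
    "DOCTOR_ROWS",
    "MODEL_ROWS",
    "DARNDEST_CONFUSION",
    "DARNDEST_PRINTED",
    "PUBLISHED_CUTOFFS",
    "PUBLISHED_AUC",
    "TEST_SET_GROUPS",
    "COHORT_SCALE",
    "COST_PER_TP_CNY",
    "STRATEGY_TOTALS",
    "COST_RATIOS_PCT",
    "reference_score_table",
]

COHORTS = ("internal", "external")
MODEL_ROWS = ("T1WIC", "T1WI", "T2WI", "T1_T2")
DOCTOR_ROWS = ("Doctor-S", "Doctor-J")

# Each row: confusion quadruple plus the five diagnostic cells; model rows
# carry (estimate, ci_low, ci_high) percentages, doctor rows estimates only.
_M = ("sensitivity", "specificity", "accuracy", "ppv", "npv")


def _row(counts, *cells):
    return {
        "counts": ConfusionMatrix(*counts),
        "metrics": dict(zip(_M, cells)),
    }


TABLE1 = {
    "internal": {
        "T1WIC": _row(
            (166, 31, 35, 201),
            (84.26, 79.18, 89.35),
            (85.17, 80.64, 89.70),
            (84.76, 81.37, 88.14),
            (82.59, 77.34, 87.83),
            (86.64, 82.26, 91.02),
        ),
        "T1WI": _row(
            (168, 29, 40, 196),
            (85.28, 80.33, 90.23),
            (83.05, 78.26, 87.84),  # published point cell 82.57 is a transcription slip
            (84.06, 80.62, 87.51),
            (80.77, 75.41, 86.13),
            (87.11, 82.73, 91.49),
        ),
        "T2WI": _row(
            (164, 33, 40, 196),
            (83.25, 78.03, 88.46),
            (83.05, 78.26, 87.84),  # published point cell 85.32 is a transcription slip
            (83.14, 79.61, 86.67),
            (80.39, 74.94, 85.84),
            (85.59, 81.04, 90.14),
        ),
        "T1_T2": _row(
            (166, 31, 34, 202),
            (84.26, 79.18, 89.35),
            (85.59, 81.11, 90.07),
            (84.99, 81.62, 88.35),
            (83.00, 77.79, 88.21),
            (86.70, 82.33, 91.06),
        ),
        "Doctor-S": _row((154, 43, 13, 223), 78.17, 94.49, 87.07, 92.22, 83.83),
        "Doctor-J": _row((166, 31, 41, 195), 84.26, 82.63, 83.37, 80.19, 86.28),
    },
    "external": {
        "T1WIC": _row(
            (78, 15, 19, 90),
            (83.87, 76.40, 91.35),
            (82.57, 75.45, 89.69),
            (83.17, 78.01, 88.33),
            (80.41, 72.51, 88.31),
            (85.71, 79.02, 92.41),
        ),
        "T1WI": _row(
            (75, 18, 19, 90),
            (80.65, 72.62, 88.67),
            (82.57, 75.45, 89.69),
            (81.68, 76.35, 87.02),
            (79.79, 71.67, 87.91),
            (83.33, 76.30, 90.36),
        ),
        "T2WI": _row(
            (76, 17, 16, 93),
            (81.72, 73.87, 89.58),
            (85.32, 78.68, 91.96),
            (83.66, 78.57, 88.76),
            (82.61, 74.86, 90.35),
            (84.55, 77.79, 91.30),
        ),
        "T1_T2": _row(
            (79, 14, 18, 91),
            (84.95, 77.68, 92.21),
            (83.49, 76.52, 90.46),
            (84.16, 79.12, 89.19),
            (81.44, 73.71, 89.18),
            (86.67, 80.16, 93.17),
        ),
        "Doctor-S": _row((77, 16, 3, 106), 82.80, 97.25, 90.59, 96.25, 86.89),
        "Doctor-J": _row((72, 21, 4, 105), 77.42, 96.33, 87.62, 94.74, 83.33),
    },
}

# Layered-rule confusion quadruples and their published headline metrics.
DARNDEST_CONFUSION = {
    "internal": ConfusionMatrix(178, 19, 42, 194),
    "external": ConfusionMatrix(84, 9, 19, 90),
}
DARNDEST_PRINTED = {
    "internal": {"accuracy": 85.91, "sensitivity": 90.36, "specificity": 82.20},
    "external": {"accuracy": 86.14, "sensitivity": 90.32, "specificity": 82.57},
}

# Published two-level cutoffs; the T1WIC adjudication cutoff was not
# published, so the worked example uses 0.5 (its synthetic scores are placed
# around it).
FIXTURE_C3 = 0.5
PUBLISHED_CUTOFFS = {
    "internal": CutoffSet(c1=0.490, c2=0.197, c3=FIXTURE_C3),
    "external": CutoffSet(c1=0.460, c2=0.282, c3=FIXTURE_C3),
}

# Per-sequence AUCs (DenseNet) used to calibrate the synthetic generator.
PUBLISHED_AUC = {
    "internal": {"T1WIC": 0.9124, "T1WI": 0.9098, "T2WI": 0.9145, "T1_T2": 0.9296},
    "external": {"T1WIC": 0.9071, "T1WI": 0.8874, "T2WI": 0.8877, "T1_T2": 0.9065},
}

# Reconstructed test-set group tallies (patients, true cases, detected true)
# and the published 1,000-patient cohort-scale figures they project to.
TEST_SET_GROUPS = {
    "internal": {
        "positive": (200, 166, 166),
        "suspicious": (74, 27, 12),
        "negative": (159, 4, 2),
    },
    "external": {
        "positive": (97, 79, 79),
        "suspicious": (18, 7, 5),
        "negative": (87, 7, 1),
    },
}
COHORT_SCALE = {
    "internal": {
        "patients": {"positive": 462, "suspicious": 171, "negative": 367},
        "true_cases": {"positive": 383, "suspicious": 62, "negative": 9},
        "detected_true": {"positive": 383, "suspicious": 28, "negative": 5},
    },
    "external": {
        "patients": {"positive": 480, "suspicious": 89, "negative": 431},
        "true_cases": {"positive": 391, "suspicious": 35, "negative": 35},
        "detected_true": {"positive": 391, "suspicious": 25, "negative": 5},
    },
}

# Published cost of detecting one true recurrence per group (RMB).
COST_PER_TP_CNY = {
    "internal": {"positive": 6381, "suspicious": 87286, "negative": 488800},
    "external": {"positive": 6251, "suspicious": 97760, "negative": 488800},
}

# Published strategy totals: (cost CNY, cost USD, time hours).
STRATEGY_TOTALS = {
    "conventional": (2_444_000, 340_865, 226.4),
    "t1_t2_only": (2_246_000, 313_250, 129.2),
    "darndest_internal": (2_371_293, 330_724, 190.7),
    "darndest_external": (2_358_723, 328_971, 184.5),
}

# Published layered-vs-conventional cost ratios computed from the published
# totals.  (The published layered-vs-fused external ratio, 100.53%, is
# inconsistent with its own operands and is not carried.)
COST_RATIOS_PCT = {
    "darndest_vs_conventional": {"internal": 97.03, "external": 96.51},
    "darndest_vs_t1_t2": {"internal": 105.58},
}

# Synthetic realisation of the worked example.  Each block is
# (count, label, fused-band, t1wic-band): the fused score is shared by T1WI
# and T2WI; bands place scores relative to the cohort's published cutoffs
# ("hi" >= c1, "mid" in [c2, c1), "lo" < c2; T1WIC "hi" >= 0.5, "lo" < 0.5).
_COMPOSITION = {
    "internal": [
        (154, 1, "hi", "hi"),
        (12, 1, "hi", "lo"),
        (12, 1, "mid", "hi"),
        (15, 1, "mid", "lo"),
        (4, 1, "lo", "lo"),
        (27, 0, "hi", "hi"),
        (7, 0, "hi", "lo"),
        (8, 0, "mid", "hi"),
        (39, 0, "mid", "lo"),
        (155, 0, "lo", "lo"),
    ],
    "external": [
        (73, 1, "hi", "hi"),
        (6, 1, "hi", "lo"),
        (5, 1, "mid", "hi"),
        (2, 1, "mid", "lo"),
        (7, 1, "lo", "lo"),
        (18, 0, "hi", "hi"),
        (1, 0, "mid", "hi"),
        (10, 0, "mid", "lo"),
        (80, 0, "lo", "lo"),
    ],
}
_FUSED_BAND = {"hi": 0.80, "mid": 0.30, "lo": 0.10}
_T1WIC_BAND = {"hi": 0.80, "lo": 0.20}


def reference_score_table(cohort: str) -> ScoreTable:
    """Synthetic score table realising the published worked example.

    Under the cohort's published cutoffs (and T1WIC cutoff 0.5) the table
    reproduces the published fused-model, T1WIC-model and layered-rule
    confusion quadruples and group tallies exactly.  Scores are
    block-constant placeholders, not simulated score distributions — use
    :mod:`darndest.synthetic` for distributionally realistic cohorts.
    """
    if cohort not in COHORTS:
        raise ValueError(f"cohort must be one of {COHORTS}, got {cohort!r}")
    ids, labels, t1, t2, wic = [], [], [], [], []
    i = 0
    for count, label, fused_band, wic_band in _COMPOSITION[cohort]:
        for _ in range(count):
            i += 1
            ids.append(f"{cohort[:3].upper()}{i:04d}")
            labels.append(label)
            t1.append(_FUSED_BAND[fused_band])
            t2.append(_FUSED_BAND[fused_band])
            wic.append(_T1WIC_BAND[wic_band])
    return ScoreTable.from_arrays(ids, labels, t1, t2, wic, cohort_tag=cohort)
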