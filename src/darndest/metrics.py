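"""Diagnostic-performance statistics.

Implements the five standard diagnostic metrics (sensitivity, specificity,
accuracy, PPV, NPV) with Wald 95% confidence intervals, the paired McNemar
Z test for comparing two classifiers on the same patients, ROC analysis, and
the DeLong paired comparison of correlated AUCs.

Conventions
-----------
* Metrics are reported as percentages rounded half-away-from-zero to two
  decimals for display; unrounded proportions are retained on each
  :class:`MetricWithCI` as ``raw``.
* Binomial CIs use the Wald normal approximation,
  :math:`\\hat p \\pm z_{0.975}\\sqrt{\\hat p(1-\\hat p)/n}` with
  :math:`z_{0.975} = 1.959964...`, clipped to [0, 1].  This is the method
  that reproduces the published per-model diagnostic tables cell-for-cell.
* The default significance threshold for pairwise model comparisons is
  Bonferroni-corrected over three comparisons, :math:`\\alpha = 0.05/3`.
* McNemar's test defaults to the plain (uncorrected) Z; a continuity
  correction is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score, roc_curve

from ._rounding import round_half_away
from .score_io import ConfusionMatrix

__all__ = [
    "ALPHA_PAIRWISE",
    "MetricWithCI",
    "DiagnosticSummary",
    "PairedTestResult",
    "RocResult",
    "wald_ci",
    "auc_variance",
    "diagnostic_summary",
    "mcnemar_test",
    "roc_auc",
    "delong_compare",
]

#: Bonferroni threshold over the three pairwise model comparisons (0.05 / 3)
ALPHA_PAIRWISE = 0.05 / 3


def _z(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    return float(ndtri(0.5 + level / 2.0))


def wald_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald binomial confidence interval, returned as percentages.

    Returns ``(low, high)`` in percent, rounded half-away-from-zero to two
    decimals, with the underlying interval clipped to [0, 1] before scaling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must lie in [0, n], got {successes} of {n}")
    p = successes / n
    half = _z(level) * np.sqrt(p * (1.0 - p) / n)
    low = max(0.0, p - half)
    high = min(1.0, p + half)
    return round_half_away(100.0 * low), round_half_away(100.0 * high)


@dataclass(frozen=True)
class MetricWithCI:
    """A percentage point estimate with its confidence bounds.

    ``estimate``, ``ci_low`` and ``ci_high`` are display values in percent
    (two decimals); ``raw`` is the unrounded proportion in [0, 1].  All four
    are ``None`` when the metric is undefined (zero denominator).
    """

    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    raw: float | None = None

    @property
    def defined(self) -> bool:
        return self.estimate is not None

    @classmethod
    def from_counts(cls, successes: int, n: int, level: float = 0.95) -> "MetricWithCI":
        if n == 0:
            return cls(None, None, None, None)
        low, high = wald_ci(successes, n, level)
        p = successes / n
        return cls(round_half_away(100.0 * p), low, high, p)

    def to_dict(self) -> dict:
        return {"estimate": self.estimate, "ci_low": self.ci_low, "ci_high": self.ci_high}


@dataclass(frozen=True)
class DiagnosticSummary:
    """The five diagnostic metrics of one classifier on one cohort."""

    sensitivity: MetricWithCI
    specificity: MetricWithCI
    accuracy: MetricWithCI
    ppv: MetricWithCI
    npv: MetricWithCI
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity.to_dict(),
            "specificity": self.specificity.to_dict(),
            "accuracy": self.accuracy.to_dict(),
            "ppv": self.ppv.to_dict(),
            "npv": self.npv.to_dict(),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def diagnostic_summary(cm: ConfusionMatrix, level: float = 0.95) -> DiagnosticSummary:
    """Compute sensitivity, specificity, accuracy, PPV and NPV with Wald CIs.

    Any metric whose denominator is zero (e.g. PPV with no positive calls)
    is returned as an undefined :class:`MetricWithCI` rather than fabricated.
    """
    if cm.n == 0:
        raise ValueError("confusion matrix is empty")
    return DiagnosticSummary(
        sensitivity=MetricWithCI.from_counts(cm.tp, cm.tp + cm.fn, level),
        specificity=MetricWithCI.from_counts(cm.tn, cm.fp + cm.tn, level),
        accuracy=MetricWithCI.from_counts(cm.tp + cm.tn, cm.n, level),
        ppv=MetricWithCI.from_counts(cm.tp, cm.tp + cm.fp, level),
        npv=MetricWithCI.from_counts(cm.tn, cm.fn + cm.tn, level),
        n_pos=cm.n_pos,
        n_neg=cm.n_neg,
    )


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of a paired two-classifier comparison (McNemar or DeLong).

    ``statistic`` is the signed Z value; ``effect`` carries the estimated
    difference where one exists (AUC difference for DeLong, ``None`` for
    McNemar).  ``significant`` is ``p_value < alpha``.
    """

    statistic: float
    p_value: float
    alpha: float = ALPHA_PAIRWISE
    significant: bool = field(default=False)
    effect: float | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
            "effect": self.effect,
        }


def _paired_result(statistic: float, p: float, alpha: float, effect: float | None = None) -> PairedTestResult:
    p = float(min(1.0, max(0.0, p)))
    return PairedTestResult(float(statistic), p, alpha, bool(p < alpha), effect)


def mcnemar_test(
    labels,
    calls_a,
    calls_b,
    *,
    correction: bool = False,
    alpha: float = ALPHA_PAIRWISE,
) -> PairedTestResult:
    """McNemar's Z test on the paired correctness of two classifiers.

    Per patient, each classifier is scored correct (call equals label) or
    wrong; with ``b`` = cases A correct and B wrong, ``c`` = cases A wrong
    and B correct, the statistic is

    .. math:: Z = \\frac{|b - c| - k}{\\sqrt{b + c}},

    signed by ``b - c``, with :math:`k = 1` when ``correction`` is on and 0
    otherwise, and a two-sided normal p-value.  ``b + c = 0`` yields
    statistic 0 and p = 1 (no discordant pairs, nothing to test).
    """
    labels = np.asarray(labels, dtype=int)
    calls_a = np.asarray(calls_a, dtype=int)
    calls_b = np.asarray(calls_b, dtype=int)
    if not (labels.shape == calls_a.shape == calls_b.shape) or labels.ndim != 1:
        raise ValueError("labels, calls_a and calls_b must be equal-length 1-d vectors")
    correct_a = calls_a == labels
    correct_b = calls_b == labels
    b = int((correct_a & ~correct_b).sum())
    c = int((~correct_a & correct_b).sum())
    if b + c == 0:
        return _paired_result(0.0, 1.0, alpha)
    k = 1.0 if correction else 0.0
    z_abs = max(0.0, (abs(b - c) - k)) / np.sqrt(b + c)
    statistic = float(np.sign(b - c) * z_abs)
    p = 2.0 * float(ndtr(-z_abs))
    return _paired_result(statistic, p, alpha)


@dataclass(frozen=True)
class RocResult:
    """An empirical ROC curve with its AUC and DeLong confidence interval."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_low": self.auc_ci_low,
            "auc_ci_high": self.auc_ci_high,
            "thresholds": [float(t) for t in self.thresholds],
            "tpr": [float(t) for t in self.tpr],
            "fpr": [float(f) for f in self.fpr],
        }


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """DeLong placement components via midranks.

    Returns ``(auc, v10, v01)`` where ``v10[i]`` is the fraction of
    controls the *i*-th case outranks (ties half) and ``v01`` the mirrored
    per-control components; ``mean(v10) = mean(v01) = auc`` (tie-corrected
    Mann-Whitney probability).
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    ranks_all = rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - rankdata(neg)) / m
    return float(v10.mean()), v10, v01


def _component_var(v: np.ndarray) -> float:
    return float(v.var(ddof=1)) if len(v) > 1 else 0.0


def auc_variance(scores, labels) -> float:
    """DeLong variance of a single empirical AUC (placement-component form
    ``S10/m + S01/n``)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    _, v10, v01 = _placements(scores, labels)
    return _component_var(v10) / len(v10) + _component_var(v01) / len(v01)


def roc_auc(scores, labels, *, level: float = 0.95) -> RocResult:
    """Empirical ROC curve and tie-corrected AUC with a DeLong CI.

    The curve thresholds every unique score with the rule "positive if
    score >= t"; the AUC equals the Mann-Whitney probability with ties
    counted one half.  The CI is the Wald interval on the DeLong variance of
    the single curve, clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d vectors")
    _check_two_classes(labels)
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc, v10, v01 = _placements(scores, labels)
    var = _component_var(v10) / len(v10) + _component_var(v01) / len(v01)
    half = _z(level) * np.sqrt(var)
    # cross-check the placement AUC against the trapezoidal curve area
    assert abs(auc - roc_auc_score(labels, scores)) < 1e-10
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        auc_ci_low=float(max(0.0, auc - half)),
        auc_ci_high=float(min(1.0, auc + half)),
    )


def delong_compare(
    scores_a,
    scores_b,
    labels,
    *,
    alpha: float = ALPHA_PAIRWISE,
) -> PairedTestResult:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must be measured on the same patients.  The variance
    of the AUC difference combines the per-class empirical covariance of the
    placement components of the two curves:

    .. math::

        \\operatorname{Var}(\\hat A_a - \\hat A_b) =
        \\frac{s^{10}_{aa} + s^{10}_{bb} - 2 s^{10}_{ab}}{m} +
        \\frac{s^{01}_{aa} + s^{01}_{bb} - 2 s^{01}_{ab}}{n}.

    Returns a signed Z with a two-sided normal p-value; ``effect`` carries
    the AUC difference (a minus b).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (scores_a.shape == scores_b.shape == labels.shape) or labels.ndim != 1:
        raise ValueError("scores_a, scores_b and labels must be equal-length 1-d vectors")
    _check_two_classes(labels)
    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    diff = auc_a - auc_b
    if m > 1 and n > 1:
        s10 = np.cov(v10_a, v10_b, ddof=1)
        s01 = np.cov(v01_a, v01_b, ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        var = 0.0
    if var <= 0.0:
        if diff == 0.0:
            return _paired_result(0.0, 1.0, alpha, effect=0.0)
        statistic = float(np.sign(diff) * np.inf)
        return _paired_result(statistic, 0.0, alpha, effect=diff)
    z = diff / np.sqrt(var)
    p = 2.0 * float(ndtr(-abs(z)))
    return _paired_result(float(z), p, alpha, effect=float(diff))


def plot_roc(results: dict[str, RocResult], path) -> None:
    """Write a simple ROC figure for one or more named curves (requires
    matplotlib, an optional dependency)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, res in results.items():
        ax.plot(res.fpr, res.tpr, label=f"{name} (AUC {res.auc:.4f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
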