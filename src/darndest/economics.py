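"""Hypothetical-cohort cost and time model.

Test-set group composition is projected onto a hypothetical follow-up cohort
(default 1,000 patients), and each strategy is costed by how many of those
patients receive a contrast-enhanced versus unenhanced MR examination:

* layered triage — positive + suspicious groups enhanced, negative group
  unenhanced;
* fused-model-only — nobody enhanced;
* T1WIC-only and conventional — everybody enhanced.

Unit prices and scan times default to the whole-cohort figures of the
published comparison divided by 1,000 — enhanced ￥2,444 / 0.2264 h and
unenhanced ￥2,246 / 0.1292 h per examination (2024 Guangzhou medical-pricing
basis) — and are fully configurable.  The cost of detecting one true
positive in a group is the conventional whole-cohort cost divided by the
true positives the strategy detects in that group, i.e. what buying the
detections of that group at everyone-enhanced prices costs.  Currency
converts at ￥7.17 per US dollar (2024).

Display conventions: yuan and dollars round to the nearest unit, hours to
one decimal, percentages to two decimals, ties away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._rounding import round_half_away, round_to_int
from .triage import StrategyEvaluation

__all__ = [
    "EconParams",
    "GroupProjection",
    "CohortProjection",
    "EconReport",
    "project_cohort",
    "cost_per_true_positive",
    "strategy_totals",
    "convert_currency",
    "cost_ratio",
    "build_econ_report",
]

#: groups whose patients receive a contrast-enhanced examination under triage
ENHANCED_GROUPS = ("positive", "suspicious", "all")


@dataclass(frozen=True)
class EconParams:
    """Unit prices (RMB), per-examination times (hours) and FX rate."""

    cohort_n: int = 1000
    unit_cost_enhanced: float = 2444.0
    unit_cost_unenhanced: float = 2246.0
    unit_time_enhanced: float = 0.2264
    unit_time_unenhanced: float = 0.1292
    fx_rate: float = 7.17

    def __post_init__(self) -> None:
        if self.cohort_n < 1:
            raise ValueError("cohort_n must be >= 1")
        if not self.unit_cost_enhanced >= self.unit_cost_unenhanced > 0:
            raise ValueError("require unit_cost_enhanced >= unit_cost_unenhanced > 0")
        if self.unit_time_enhanced <= 0 or self.unit_time_unenhanced <= 0:
            raise ValueError("unit times must be positive")
        if self.fx_rate <= 0:
            raise ValueError("fx_rate must be positive")

    def to_dict(self) -> dict:
        return {
            "cohort_n": self.cohort_n,
            "unit_cost_enhanced": self.unit_cost_enhanced,
            "unit_cost_unenhanced": self.unit_cost_unenhanced,
            "unit_time_enhanced": self.unit_time_enhanced,
            "unit_time_unenhanced": self.unit_time_unenhanced,
            "fx_rate": self.fx_rate,
        }


@dataclass(frozen=True)
class GroupProjection:
    """One group's composition at cohort scale."""

    patients: int
    true_cases: int
    detected_true: int


@dataclass(frozen=True)
class CohortProjection:
    """Strategy group composition scaled to the hypothetical cohort."""

    groups: dict[str, GroupProjection]
    prevalence: float
    cohort_n: int

    @property
    def enhanced_patients(self) -> int:
        return sum(g.patients for name, g in self.groups.items() if name in ENHANCED_GROUPS)

    def to_dict(self) -> dict:
        return {
            "cohort_n": self.cohort_n,
            "prevalence": self.prevalence,
            "groups": {
                name: {
                    "patients": g.patients,
                    "true_cases": g.true_cases,
                    "detected_true": g.detected_true,
                }
                for name, g in self.groups.items()
            },
        }


def _largest_remainder(quotas: list[float], total: int) -> list[int]:
    """Integer apportionment: floors plus units by largest fractional part."""
    floors = [math.floor(q) for q in quotas]
    remainder = total - sum(floors)
    order = sorted(range(len(quotas)), key=lambda i: quotas[i] - floors[i], reverse=True)
    for i in order[:remainder]:
        floors[i] += 1
    return floors


def project_cohort(evaluation: StrategyEvaluation, cohort_n: int = 1000) -> CohortProjection:
    """Scale a strategy's test-set group composition to ``cohort_n`` patients.

    Group patient counts are scaled by ``cohort_n / table_n`` and
    reconciled by largest remainder so they sum exactly to ``cohort_n``;
    true and detected cases are scaled and rounded to the nearest integer,
    then clipped so ``detected <= true <= patients`` within each group.
    """
    if cohort_n < 1:
        raise ValueError("cohort_n must be >= 1")
    table_n = evaluation.table_n
    scale = cohort_n / table_n
    names = list(evaluation.group_counts)
    patients = _largest_remainder([evaluation.group_counts[g] * scale for g in names], cohort_n)
    groups: dict[str, GroupProjection] = {}
    for name, n_patients in zip(names, patients):
        true_cases = min(n_patients, round_to_int(evaluation.group_true_counts[name] * scale))
        detected = round_to_int(evaluation.group_detected_counts.get(name, 0) * scale)
        groups[name] = GroupProjection(n_patients, true_cases, min(detected, true_cases))
    return CohortProjection(
        groups=groups, prevalence=evaluation.n_true / table_n, cohort_n=cohort_n
    )


def cost_per_true_positive(detected_true: int, params: EconParams) -> float:
    """Cost (RMB, nearest yuan) of detecting one true positive in a group:
    the conventional whole-cohort cost divided by the group's detected
    count.  Zero detections yield ``math.inf`` (rendered ``"infinity"`` in
    reports)."""
    if detected_true < 0:
        raise ValueError("detected_true must be >= 0")
    if detected_true == 0:
        return math.inf
    return float(round_to_int(params.cohort_n * params.unit_cost_enhanced / detected_true))


def strategy_totals(
    projection: CohortProjection, params: EconParams, strategy: str
) -> tuple[float, float]:
    """Total examination cost (RMB) and time (hours, one decimal) of running
    one strategy over the hypothetical cohort."""
    cohort_n = projection.cohort_n
    if strategy == "conventional" or strategy == "t1wic_only":
        enhanced = cohort_n
    elif strategy == "t1_t2_only":
        enhanced = 0
    elif strategy == "darndest":
        enhanced = projection.enhanced_patients
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    unenhanced = cohort_n - enhanced
    cost = enhanced * params.unit_cost_enhanced + unenhanced * params.unit_cost_unenhanced
    time = enhanced * params.unit_time_enhanced + unenhanced * params.unit_time_unenhanced
    return float(round_to_int(cost)), round_half_away(time, 1)


def convert_currency(amount_rmb: float, fx_rate: float = 7.17) -> float:
    """Convert RMB to US dollars at ``fx_rate`` yuan per dollar, rounded to
    the nearest dollar."""
    if fx_rate <= 0:
        raise ValueError("fx_rate must be positive")
    return float(round_to_int(amount_rmb / fx_rate))


def cost_ratio(numerator: float, denominator: float) -> float:
    """Cost ratio as a percentage with two decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(100.0 * numerator / denominator, 2)


@dataclass(frozen=True)
class EconReport:
    """Cohort-scale economics of the layered strategy and its comparators."""

    projection: CohortProjection
    cost_per_tp: dict[str, float]
    totals: dict[str, dict[str, float]]
    ratios: dict[str, float]
    params: EconParams = field(default_factory=EconParams)

    def to_dict(self) -> dict:
        def _cost(v: float):
            return "infinity" if math.isinf(v) else v

        return {
            "projection": self.projection.to_dict(),
            "cost_per_true_positive_cny": {k: _cost(v) for k, v in self.cost_per_tp.items()},
            "strategy_totals": self.totals,
            "cost_ratios_pct": self.ratios,
            "params": self.params.to_dict(),
        }


def build_econ_report(
    triage_evaluation: StrategyEvaluation,
    params: EconParams | None = None,
) -> EconReport:
    """Assemble the full economics report from a layered-triage evaluation.

    Includes the cohort projection, per-group cost of one detected
    recurrence, total cost (RMB and USD) and time per strategy, and the
    layered strategy's cost relative to the fused-model-only and
    conventional strategies.
    """
    params = params or EconParams()
    projection = project_cohort(triage_evaluation, params.cohort_n)
    cost_per_tp = {
        name: cost_per_true_positive(group.detected_true, params)
        for name, group in projection.groups.items()
    }
    totals: dict[str, dict[str, float]] = {}
    for strategy in ("darndest", "t1_t2_only", "conventional"):
        cost, time = strategy_totals(projection, params, strategy)
        totals[strategy] = {
            "cost_cny": cost,
            "cost_usd": convert_currency(cost, params.fx_rate),
            "time_hr": time,
        }
    ratios = {
        "darndest_vs_t1_t2": cost_ratio(totals["darndest"]["cost_cny"], totals["t1_t2_only"]["cost_cny"]),
        "darndest_vs_conventional": cost_ratio(
            totals["darndest"]["cost_cny"], totals["conventional"]["cost_cny"]
        ),
    }
    return EconReport(projection, cost_per_tp, totals, ratios, params)
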