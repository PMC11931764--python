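import math

import pytest

from darndest.economics import (
    EconParams,
    build_econ_report,
    convert_currency,
    cost_per_true_positive,
    cost_ratio,
    project_cohort,
    strategy_totals,
)
from darndest.reference import COHORT_SCALE, TEST_SET_GROUPS
from darndest.triage import evaluate_strategy

PARAMS = EconParams()


class TestEconParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cohort_n": 0},
            {"unit_cost_enhanced": 1000.0, "unit_cost_unenhanced": 2000.0},
            {"unit_time_enhanced": 0.0},
            {"fx_rate": 0.0},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            EconParams(**kwargs)


class TestProjectCohort:
    def test_reproduces_published_internal_projection(self, internal_table, internal_cutoffs):
        ev = evaluate_strategy(internal_table, internal_cutoffs, "darndest")
        projection = project_cohort(ev, 1000)
        expected = COHORT_SCALE["internal"]
        assert {g: p.patients for g, p in projection.groups.items()} == expected["patients"]
        assert {g: p.true_cases for g, p in projection.groups.items()} == expected["true_cases"]
        assert projection.groups["positive"].detected_true == 383
        assert projection.groups["suspicious"].detected_true == 28
        assert projection.prevalence == pytest.approx(197 / 433)

    def test_group_patients_sum_to_cohort(self, external_table):
        from darndest.reference import PUBLISHED_CUTOFFS

        ev = evaluate_strategy(external_table, PUBLISHED_CUTOFFS["external"], "darndest")
        projection = project_cohort(ev, 1000)
        assert sum(p.patients for p in projection.groups.values()) == 1000
        expected = COHORT_SCALE["external"]
        assert {g: p.patients for g, p in projection.groups.items()} == expected["patients"]
        assert {g: p.true_cases for g, p in projection.groups.items()} == expected["true_cases"]

    def test_scaled_counts_within_rounding_of_quota(self, internal_table, internal_cutoffs):
        ev = evaluate_strategy(internal_table, internal_cutoffs, "darndest")
        projection = project_cohort(ev, 1000)
        for group, proj in projection.groups.items():
            quota = ev.group_counts[group] * 1000 / len(internal_table)
            assert abs(proj.patients - quota) < 1.0  # largest-remainder never drifts a full seat
            true_quota = ev.group_true_counts[group] * 1000 / len(internal_table)
            assert abs(proj.true_cases - true_quota) <= 0.5

    def test_empty_group_scales_to_zero(self, internal_table):
        from darndest.cutoffs import CutoffSet

        collapsed = CutoffSet(c1=0.490, c2=0.490, c3=0.5)
        ev = evaluate_strategy(internal_table, collapsed, "darndest")
        projection = project_cohort(ev, 1000)
        assert projection.groups["suspicious"].patients == 0

    def test_invalid_cohort_n(self, internal_table, internal_cutoffs):
        ev = evaluate_strategy(internal_table, internal_cutoffs, "darndest")
        with pytest.raises(ValueError):
            project_cohort(ev, 0)


class TestCostPerTruePositive:
    @pytest.mark.parametrize(
        "detected, expected",
        [(383, 6381), (28, 87286), (5, 488800), (391, 6251), (25, 97760)],
    )
    def test_published_values(self, detected, expected):
        assert cost_per_true_positive(detected, PARAMS) == expected

    def test_zero_detections_is_infinite(self):
        assert math.isinf(cost_per_true_positive(0, PARAMS))

    def test_strictly_decreasing(self):
        costs = [cost_per_true_positive(d, PARAMS) for d in range(1, 50)]
        assert all(a > b for a, b in zip(costs, costs[1:]))


class TestStrategyTotals:
    def test_published_totals(self, internal_table, internal_cutoffs):
        ev = evaluate_strategy(internal_table, internal_cutoffs, "darndest")
        projection = project_cohort(ev, 1000)
        conventional = strategy_totals(projection, PARAMS, "conventional")
        fused_only = strategy_totals(projection, PARAMS, "t1_t2_only")
        layered = strategy_totals(projection, PARAMS, "darndest")
        assert conventional == (2_444_000, 226.4)
        assert fused_only == (2_246_000, 129.2)
        assert layered[1] == 190.7  # 633 enhanced / 367 unenhanced
        # layered total sits between the all-unenhanced and all-enhanced poles
        assert fused_only[0] <= layered[0] <= conventional[0]

    def test_monotone_in_enhanced_referrals(self, internal_table, internal_cutoffs):
        ev = evaluate_strategy(internal_table, internal_cutoffs, "darndest")
        projection = project_cohort(ev, 1000)
        assert (
            strategy_totals(projection, PARAMS, "t1_t2_only")[0]
            <= strategy_totals(projection, PARAMS, "darndest")[0]
            <= strategy_totals(projection, PARAMS, "conventional")[0]
        )


class TestCurrencyAndRatios:
    @pytest.mark.parametrize(
        "cny, usd", [(2_444_000, 340_865), (2_246_000, 313_250), (0, 0)]
    )
    def test_conversion(self, cny, usd):
        assert convert_currency(cny, 7.17) == usd

    @pytest.mark.parametrize(
        "num, den, expected",
        [(2_371_293, 2_444_000, 97.03), (2_358_723, 2_444_000, 96.51), (5, 5, 100.00)],
    )
    def test_ratios(self, num, den, expected):
        assert cost_ratio(num, den) == expected

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            cost_ratio(1.0, 0.0)


class TestEconReport:
    def test_internal_report_end_to_end(self, internal_table, internal_cutoffs):
        ev = evaluate_strategy(internal_table, internal_cutoffs, "darndest")
        report = build_econ_report(ev, PARAMS)
        assert report.cost_per_tp["positive"] == 6381
        assert report.cost_per_tp["suspicious"] == 87286
        assert report.totals["conventional"]["cost_usd"] == 340_865
        assert report.totals["t1_t2_only"]["cost_usd"] == 313_250
        assert report.totals["darndest"]["time_hr"] == 190.7
        assert report.ratios["darndest_vs_conventional"] == 97.03
        assert report.ratios["darndest_vs_t1_t2"] == 105.58
        # cost-per-TP times detections recovers the conventional total
        for group, proj in report.projection.groups.items():
            if proj.detected_true:
                recovered = report.cost_per_tp[group] * proj.detected_true
                assert abs(recovered - 2_444_000) <= proj.detected_true / 2

    def test_report_serialises_infinity(self, internal_table, internal_cutoffs):
        ev = evaluate_strategy(internal_table, internal_cutoffs, "darndest")
        report = build_econ_report(ev, PARAMS)
        payload = report.to_dict()
        assert payload["cost_per_true_positive_cny"]["negative"] == "infinity"

    def test_fig4_negative_group_from_published_detected_count(self):
        """The published negative-group detection count (index exam plus later
        follow-up) prices one detection at the published figure."""
        detected = COHORT_SCALE["internal"]["detected_true"]["negative"]
        assert cost_per_true_positive(detected, PARAMS) == 488_800
        assert TEST_SET_GROUPS["internal"]["negative"][2] == 2  # reconstructed test-set count
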