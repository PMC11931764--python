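import numpy as np
import pytest
from scipy.special import ndtri
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from darndest.metrics import (
    ALPHA_PAIRWISE,
    auc_variance,
    delong_compare,
    diagnostic_summary,
    mcnemar_test,
    roc_auc,
    wald_ci,
)
from darndest.score_io import ConfusionMatrix

Z95 = ndtri(0.975)


def brute_force_auc(scores, labels):
    """O(n^2) pair-count oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1][:, None]
    neg = scores[np.asarray(labels) == 0][None, :]
    return float(((pos > neg) + 0.5 * (pos == neg)).mean())


def discordant_vectors(b, c):
    """Labels/calls where A is correct and B wrong on b patients, vice versa
    on c, and both correct on 5 more."""
    n = b + c + 5
    labels = np.zeros(n, dtype=int)
    calls_a = np.zeros(n, dtype=int)
    calls_b = np.zeros(n, dtype=int)
    calls_b[:b] = 1  # A correct, B wrong
    calls_a[b : b + c] = 1  # A wrong, B correct
    return labels, calls_a, calls_b


class TestWaldCI:
    def test_published_interval(self):
        assert wald_ci(166, 197) == (79.18, 89.35)

    def test_closed_form_half(self):
        # 0.5 +/- 1.959964 * 0.05
        assert wald_ci(50, 100) == (40.20, 59.80)

    def test_degenerate_proportion_clips(self):
        assert wald_ci(197, 197) == (100.0, 100.0)
        low, high = wald_ci(0, 50)
        assert low == 0.0 and high == 0.0  # zero-width Wald interval at p-hat = 0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            wald_ci(5, 0)
        with pytest.raises(ValueError):
            wald_ci(6, 5)


class TestDiagnosticSummary:
    @pytest.mark.parametrize(
        "cm, sens, spec, acc, ppv, npv",
        [
            ((166, 31, 34, 202), 84.26, 85.59, 84.99, 83.00, 86.70),
            ((79, 14, 18, 91), 84.95, 83.49, 84.16, 81.44, 86.67),
            ((1, 0, 0, 1), 100.0, 100.0, 100.0, 100.0, 100.0),
        ],
    )
    def test_point_estimates(self, cm, sens, spec, acc, ppv, npv):
        s = diagnostic_summary(ConfusionMatrix(*cm))
        assert (
            s.sensitivity.estimate,
            s.specificity.estimate,
            s.accuracy.estimate,
            s.ppv.estimate,
            s.npv.estimate,
        ) == (sens, spec, acc, ppv, npv)

    def test_zero_denominator_marks_undefined(self):
        s = diagnostic_summary(ConfusionMatrix(0, 0, 2, 3))  # no true positives at all
        assert not s.sensitivity.defined
        assert s.specificity.defined

    def test_accuracy_integer_identity(self):
        cm = ConfusionMatrix(17, 5, 9, 30)
        s = diagnostic_summary(cm)
        assert s.accuracy.raw * cm.n == pytest.approx(cm.tp + cm.tn, abs=1e-9)

    def test_ppv_recoverable_by_bayes(self):
        cm = ConfusionMatrix(166, 31, 34, 202)
        s = diagnostic_summary(cm)
        prev = cm.n_pos / cm.n
        sens, spec = s.sensitivity.raw, s.specificity.raw
        bayes = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
        assert bayes == pytest.approx(s.ppv.raw, abs=1e-12)


class TestMcNemar:
    def test_symmetric_discordance_is_null(self):
        res = mcnemar_test(*discordant_vectors(5, 5))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_closed_form_uncorrected(self):
        res = mcnemar_test(*discordant_vectors(10, 0))
        assert res.statistic == pytest.approx(10 / np.sqrt(10), abs=1e-4)

    def test_closed_form_corrected(self):
        res = mcnemar_test(*discordant_vectors(10, 0), correction=True)
        assert res.statistic == pytest.approx(9 / np.sqrt(10), abs=1e-4)

    def test_no_discordance(self):
        labels = np.array([1, 0, 1])
        res = mcnemar_test(labels, labels, labels)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_antisymmetric_in_methods(self):
        labels, a, b = discordant_vectors(9, 3)
        fwd = mcnemar_test(labels, a, b)
        rev = mcnemar_test(labels, b, a)
        assert fwd.statistic == -rev.statistic
        assert fwd.p_value == rev.p_value

    @pytest.mark.parametrize("correction", [False, True])
    def test_matches_statsmodels_chi2(self, correction):
        rng = np.random.default_rng(21)
        labels = rng.integers(0, 2, 300)
        calls_a = np.where(rng.random(300) < 0.7, labels, 1 - labels)
        calls_b = np.where(rng.random(300) < 0.75, labels, 1 - labels)
        mine = mcnemar_test(labels, calls_a, calls_b, correction=correction)
        correct_a, correct_b = calls_a == labels, calls_b == labels
        table = [
            [int((correct_a & correct_b).sum()), int((correct_a & ~correct_b).sum())],
            [int((~correct_a & correct_b).sum()), int((~correct_a & ~correct_b).sum())],
        ]
        ref = sm_mcnemar(table, exact=False, correction=correction)
        assert mine.statistic**2 == pytest.approx(ref.statistic, rel=1e-10)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mcnemar_test([1, 0], [1], [1, 0])

    def test_significance_uses_bonferroni_alpha(self):
        res = mcnemar_test(*discordant_vectors(30, 2))
        assert res.alpha == pytest.approx(0.05 / 3)
        assert res.significant


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert res.auc == 1.0

    def test_all_ties_give_half(self):
        res = roc_auc([0.4] * 6, [1, 1, 1, 0, 0, 0])
        assert res.auc == 0.5

    def test_matches_pair_count_oracle(self):
        rng = np.random.default_rng(33)
        scores = rng.choice(np.linspace(0, 1, 25), size=60)  # force ties
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_negation_flips_auc(self):
        rng = np.random.default_rng(4)
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels).auc == pytest.approx(
            1.0 - roc_auc(-scores, labels).auc, abs=1e-12
        )

    def test_curve_monotone_and_ci_ordered(self):
        rng = np.random.default_rng(5)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        res = roc_auc(scores, labels)
        assert (np.diff(res.tpr) >= 0).all() and (np.diff(res.fpr) >= 0).all()
        assert res.auc_ci_low <= res.auc <= res.auc_ci_high

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


def jackknife_variance(stat, scores_list, labels):
    """Leave-one-out jackknife variance of a statistic of (scores..., labels)."""
    n = len(labels)
    thetas = []
    for i in range(n):
        mask = np.arange(n) != i
        thetas.append(stat(*[s[mask] for s in scores_list], labels[mask]))
    thetas = np.array(thetas)
    return (n - 1) / n * ((thetas - thetas.mean()) ** 2).sum()


class TestDeLong:
    def test_identical_scores_null(self):
        rng = np.random.default_rng(7)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        res = delong_compare(scores, scores, labels)
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.effect == 0.0

    def test_single_curve_variance_matches_jackknife(self):
        rng = np.random.default_rng(17)
        labels = np.array([1] * 10 + [0] * 10)
        scores = rng.random(20) + 0.3 * labels
        var_jack = jackknife_variance(lambda s, l: roc_auc(s, l).auc, [scores], labels)
        assert auc_variance(scores, labels) == pytest.approx(var_jack, rel=0.15)

    def test_difference_variance_matches_jackknife(self):
        rng = np.random.default_rng(19)
        labels = np.array([1] * 10 + [0] * 10)
        a = rng.random(20) + 0.4 * labels
        b = 0.6 * a + 0.4 * rng.random(20)
        res = delong_compare(a, b, labels)
        var_delong = (res.effect / res.statistic) ** 2
        var_jack = jackknife_variance(
            lambda sa, sb, l: delong_compare(sa, sb, l).effect, [a, b], labels
        )
        assert var_delong == pytest.approx(var_jack, rel=0.15)

    def test_null_rejection_rate(self):
        """Two uninformative score vectors: the test should reject at about
        its nominal level (0.05 +/- 0.02 over 1,000 replicates, n=200)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(1000):
            labels = rng.integers(0, 2, 200)
            labels[:2] = [0, 1]
            a, b = rng.random(200), rng.random(200)
            if delong_compare(a, b, labels, alpha=0.05).p_value < 0.05:
                rejections += 1
        assert rejections / 1000 == pytest.approx(0.05, abs=0.02)

    def test_detects_real_difference(self):
        rng = np.random.default_rng(23)
        labels = rng.integers(0, 2, 400)
        labels[:2] = [0, 1]
        good = rng.random(400) + 1.5 * labels
        noise = rng.random(400)
        res = delong_compare(good, noise, labels, alpha=ALPHA_PAIRWISE)
        assert res.significant and res.effect > 0.3
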