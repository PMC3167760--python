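"""ROC/AROC, DeLong, McNemar, cutoff selection, odds ratios, comparators."""

import math

import numpy as np
import pytest

import glaufuse as gf
from glaufuse.evaluation import QUADRANTS, delong_auc_variance

from conftest import make_healthy_record


def _brute_force_concordance(outputs, labels):
    outputs = np.asarray(outputs, float)
    labels = np.asarray(labels, int)
    pos = outputs[labels == 1]
    neg = outputs[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_worked_example_three_quarters(self):
        r = gf.roc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auroc == pytest.approx(0.75)
        assert _brute_force_concordance([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation_and_all_ties(self):
        assert gf.roc([1, 2, 3, 9, 10], [0, 0, 0, 1, 1]).auroc == 1.0
        assert gf.roc([0.5] * 8, [0, 1] * 4).auroc == 0.5

    def test_auroc_equals_concordance_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            labels = np.r_[0, 1, rng.integers(0, 2, n - 2)]
            scores = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
            assert gf.roc(scores, labels).auroc == pytest.approx(
                _brute_force_concordance(scores, labels), abs=1e-12
            )

    def test_sensitivity_monotone_in_threshold(self, rng):
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        r = gf.roc(rng.normal(size=60), labels)
        order = np.argsort(r.thresholds)
        sens = r.sensitivity[order]
        assert np.all(np.diff(sens) <= 1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            gf.roc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_identical_outputs_give_p_one(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        s = rng.normal(size=40)
        res = gf.delong_test(s, s, labels)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_antisymmetric_in_classifier_order(self, rng):
        labels = np.repeat([0, 1], 30)
        a = rng.normal(size=60) + labels
        b = rng.normal(size=60) + 0.5 * labels
        ab = gf.delong_test(a, b, labels)
        ba = gf.delong_test(b, a, labels)
        assert ab.statistic == pytest.approx(-ba.statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_variance_matches_bootstrap_oracle(self, rng):
        """DeLong's single-AROC variance vs a 2000-rep bootstrap on n=60."""
        labels = np.repeat([0, 1], 30)
        scores = rng.normal(size=60) + 1.2 * labels
        _, var_delong = delong_auc_variance(scores, labels)
        reps = []
        for _ in range(2000):
            idx0 = rng.integers(0, 30, 30)
            idx1 = 30 + rng.integers(0, 30, 30)
            idx = np.r_[idx0, idx1]
            reps.append(gf.roc(scores[idx], labels[idx]).auroc)
        var_boot = float(np.var(reps, ddof=1))
        assert abs(var_delong - var_boot) / var_boot < 0.25

    def test_constant_comparator_reduces_to_single_auc_variance(self, rng):
        labels = np.repeat([0, 1], 30)
        scores = rng.normal(size=60) + labels
        const = np.zeros(60)
        res = gf.delong_test(scores, const, labels)
        _, var_single = delong_auc_variance(scores, labels)
        # the constant classifier contributes no placement variance
        assert res.aux["var_diff"] == pytest.approx(var_single)

    def test_degenerate_zero_variance_unequal_aucs_errors(self):
        labels = np.array([0, 0, 1, 1])
        with pytest.raises(ZeroDivisionError):
            gf.delong_test([1, 2, 3, 4], [4, 3, 2, 1], labels)


class TestMcNemar:
    def test_balanced_discordance_capped_at_one(self):
        assert gf.mcnemar_test(5, 5).p_value == 1.0

    def test_worked_example_nine_vs_one(self):
        res = gf.mcnemar_test(9, 1)
        assert res.p_value == pytest.approx(22 / 1024)

    def test_no_discordance_convention(self):
        assert gf.mcnemar_test(0, 0).p_value == 1.0

    @pytest.mark.parametrize("b,c", [(3, 8), (0, 7), (12, 12), (1, 1), (20, 5)])
    def test_exact_p_matches_term_by_term_binomial_summation(self, b, c):
        n, k = b + c, min(b, c)
        expected = min(1.0, 2.0 * sum(math.comb(n, i) for i in range(k + 1)) / 2 ** n)
        assert gf.mcnemar_test(b, c).p_value == pytest.approx(expected, abs=1e-12)

    def test_chi2_variant(self):
        res = gf.mcnemar_test(30, 10, method="chi2")
        assert res.statistic == pytest.approx(10.0)
        assert 0.001 < res.p_value < 0.002

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            gf.mcnemar_test(-1, 2)


class TestCutoffAndAgreement:
    def test_cutoff_maximizes_product_vs_enumeration(self, rng):
        for _ in range(20):
            labels = np.r_[0, 1, rng.integers(0, 2, 10)]
            scores = np.round(rng.uniform(0, 1, 12), 1)
            r = gf.roc(scores, labels)
            cut = gf.select_cutoff(r)
            prods = r.sensitivity * r.specificity
            at_cut = prods[np.flatnonzero(r.thresholds == cut)[0]]
            assert at_cut == pytest.approx(prods.max())

    def test_perfect_classifier_product_one(self):
        r = gf.roc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        cut = gf.select_cutoff(r)
        i = np.flatnonzero(r.thresholds == cut)[0]
        assert r.sensitivity[i] * r.specificity[i] == 1.0

    def test_tie_broken_toward_higher_specificity(self):
        # two thresholds reach product 0.5: prefer the more specific one
        r = gf.roc([0.1, 0.6, 0.4, 0.9], [0, 0, 1, 1])
        cut = gf.select_cutoff(r)
        i = np.flatnonzero(r.thresholds == cut)[0]
        best = (r.sensitivity * r.specificity).max()
        ties = np.flatnonzero(r.sensitivity * r.specificity == best)
        assert r.specificity[i] == r.specificity[ties].max()

    def test_odds_ratio_direct_formula(self):
        a = np.r_[np.ones(12), np.zeros(18)].astype(int)
        b = np.r_[np.ones(10), np.zeros(2), np.ones(3), np.zeros(15)].astype(int)
        odds, table = gf.agreement_odds_ratio(a, b)
        assert table.tolist() == [[10, 2], [3, 15]]
        assert odds == pytest.approx(25.0)

    def test_identical_raters_use_haldane_correction(self):
        a = np.r_[np.ones(6), np.zeros(4)].astype(int)
        odds, table = gf.agreement_odds_ratio(a, a)
        assert odds == pytest.approx((6.5 * 4.5) / 0.25)

    def test_symmetric_in_rater_order(self, rng):
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        assert gf.agreement_odds_ratio(a, b)[0] == pytest.approx(
            gf.agreement_odds_ratio(b, a)[0]
        )


class TestComparators:
    def test_ght_label_mapping(self):
        for label, expect in [("WNL", "NORMAL"), ("BORDERLINE", "ABNORMAL"), ("ONL", "ABNORMAL")]:
            sap = gf.SAPTest.from_categories(["GE5"] * 52, 0.0, label)
            assert gf.classify_ght(sap) == expect

    def test_quadrants_tile_the_circle(self):
        seen = np.concatenate(list(QUADRANTS.values()))
        assert sorted(seen) == list(range(256))
        assert all(len(v) == 64 for v in QUADRANTS.values())

    def test_center_of_normative_distribution_is_normal(self, norm_db):
        rec = make_healthy_record(seed=31)
        rec.oct = gf.OCTTest(
            ascan_um=tuple(norm_db.intercept_um),
            signal_strength=10,
            age_years=norm_db.reference_age_years,
            se_diopters=norm_db.reference_se_diopters,
        )
        assert gf.classify_oct_quadrant(rec.oct, norm_db) == "NORMAL"

    def test_deeply_thinned_quadrant_is_abnormal(self, norm_db):
        vals = np.array(norm_db.intercept_um)
        vals[QUADRANTS["superior"]] *= 0.6  # 40% below normative mean
        rec = gf.OCTTest(
            ascan_um=tuple(np.clip(vals, 5, 395)),
            signal_strength=10,
            age_years=norm_db.reference_age_years,
            se_diopters=norm_db.reference_se_diopters,
        )
        assert gf.classify_oct_quadrant(rec, norm_db) == "ABNORMAL"

    def test_exact_fifth_percentile_boundary_is_normal(self, norm_db):
        vals = np.array(norm_db.intercept_um, dtype=float)
        boundary = {
            q: float(np.percentile(norm_db.residuals[:, idx].mean(axis=1), 5.0))
            for q, idx in QUADRANTS.items()
        }
        for q, idx in QUADRANTS.items():
            # land the quadrant mean on the cut (a hair above, so float
            # round-off cannot push it below the strict-inequality boundary)
            vals[idx] += boundary[q] + 1e-9
        rec = gf.OCTTest(
            ascan_um=tuple(np.clip(vals, 5, 395)),
            signal_strength=10,
            age_years=norm_db.reference_age_years,
            se_diopters=norm_db.reference_se_diopters,
        )
        assert gf.classify_oct_quadrant(rec, norm_db) == "NORMAL"
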