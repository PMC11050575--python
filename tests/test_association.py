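"""Association statistics: odds ratios, exact tests, trend, logistic fit."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from screendca import (
    Cohort,
    CohortError,
    ContingencyTable,
    PatientRecord,
    TrendTable,
    TwoByTwoTable,
    binary_logistic,
    cochran_armitage,
    eca_scan,
    fisher_exact,
    kruskal_wallis,
    odds_ratio,
    pearson_chi2,
)
from screendca.simulate import fixture_table

pos_tables = st.builds(
    TwoByTwoTable,
    tp=st.integers(1, 300),
    fp=st.integers(1, 300),
    fn=st.integers(1, 300),
    tn=st.integers(1, 300),
)


class TestOddsRatio:
    def test_screening_table(self, table5):
        ore = odds_ratio(table5)
        assert ore.or_value == pytest.approx(4.0, abs=0.05)
        assert ore.ci95[0] == pytest.approx(2.9, abs=0.05)
        assert ore.ci95[1] == pytest.approx(5.4, abs=0.05)
        assert math.exp(ore.log_or) == pytest.approx(ore.or_value)

    def test_eye_anomaly_row(self):
        ore = odds_ratio(fixture_table("table4_eye"))
        assert round(ore.or_value, 1) == 6.4
        assert round(ore.ci95[0], 1) == 2.9
        assert round(ore.ci95[1], 1) == 14.0

    def test_unit_table_symmetric_on_log_scale(self):
        ore = odds_ratio(TwoByTwoTable(1, 1, 1, 1))
        assert ore.or_value == 1.0
        assert ore.ci95[0] * ore.ci95[1] == pytest.approx(1.0)

    def test_skin_row_against_hand_woolf(self):
        # independent recomputation of the Woolf formulas for (3,1,241,768)
        or_exp = (3 * 768) / (1 * 241)
        se_exp = math.sqrt(1 / 3 + 1 / 1 + 1 / 241 + 1 / 768)
        lo = math.exp(math.log(or_exp) - 1.959964 * se_exp)
        hi = math.exp(math.log(or_exp) + 1.959964 * se_exp)
        ore = odds_ratio(fixture_table("table4_skin"))
        assert ore.or_value == pytest.approx(or_exp)
        assert ore.or_value == pytest.approx(9.56, abs=0.01)
        assert ore.ci95 == pytest.approx((lo, hi))
        assert ore.ci95 == pytest.approx((0.99, 92.3), abs=0.05)

    def test_zero_cell_requires_correction(self):
        with pytest.raises(CohortError, match="correction"):
            odds_ratio(TwoByTwoTable(0, 5, 5, 5))
        ore = odds_ratio(TwoByTwoTable(0, 5, 5, 5), correction=True)
        assert ore.method == "haldane_corrected"
        assert ore.or_value == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))

    @given(pos_tables, st.integers(2, 7))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariant_to_row_or_column_scaling(self, t, k):
        base = odds_ratio(t).or_value
        row = odds_ratio(TwoByTwoTable(k * t.tp, k * t.fp, t.fn, t.tn)).or_value
        col = odds_ratio(TwoByTwoTable(k * t.tp, t.fp, k * t.fn, t.tn)).or_value
        assert row == pytest.approx(base, rel=1e-12)
        assert col == pytest.approx(base, rel=1e-12)


class TestPearsonChi2:
    def test_screening_table_highly_significant(self, table5):
        res = pearson_chi2(table5)
        assert res.p_value < 1e-4
        assert res.df == 1

    def test_identical_row_distributions(self):
        t = ContingencyTable(np.array([[10, 20, 30], [20, 40, 60]]),
                             ("a", "b"), ("x", "y", "z"))
        res = pearson_chi2(t)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_independence_2x2(self):
        assert pearson_chi2(TwoByTwoTable(10, 10, 10, 10)).statistic == 0.0

    def test_zero_margin_errors(self):
        t = ContingencyTable(np.array([[0, 0], [5, 5]]), ("a", "b"), ("x", "y"))
        with pytest.raises(CohortError, match="margin"):
            pearson_chi2(t)

    def test_reports_min_expected_cell(self, table5):
        assert pearson_chi2(table5).min_expected == pytest.approx(433 * 244 / 1013)


def _fisher_two_sided_bruteforce(t: TwoByTwoTable) -> float:
    """Enumerate the full hypergeometric support with the observed margins."""
    n = t.n
    r1 = t.tp + t.fp
    c1 = t.tp + t.fn
    ks = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    probs = hypergeom.pmf(ks, n, c1, r1)
    p_obs = hypergeom.pmf(t.tp, n, c1, r1)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestFisherExact:
    def test_skin_row(self):
        res = fisher_exact(fixture_table("table4_skin"))
        assert res.p_value == pytest.approx(0.0455, abs=5e-5)

    def test_degenerate_margin(self):
        assert fisher_exact(TwoByTwoTable(0, 6, 0, 9)).p_value == 1.0

    @given(st.tuples(st.integers(0, 25), st.integers(0, 25),
                     st.integers(0, 25), st.integers(0, 25))
           .filter(lambda c: sum(c) > 0).map(lambda c: TwoByTwoTable(*c)))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_matches_bruteforce_enumeration(self, t):
        assert fisher_exact(t).p_value == pytest.approx(
            _fisher_two_sided_bruteforce(t), rel=1e-9, abs=1e-12
        )

    @given(pos_tables)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_one_sided_le_two_sided(self, t):
        one = min(
            fisher_exact(t, "one", "increasing").p_value,
            fisher_exact(t, "one", "decreasing").p_value,
        )
        assert one <= fisher_exact(t, "two").p_value + 1e-12


class TestCochranArmitage:
    def test_screen_negative_strata(self):
        res = cochran_armitage(fixture_table("fig3_trend_eca_neg"))
        assert res.p_value == pytest.approx(0.0015, abs=1e-4)

    def test_screen_positive_strata(self):
        res = cochran_armitage(fixture_table("fig3_trend_eca_pos"))
        assert res.p_value == pytest.approx(0.2994, abs=1e-4)

    def test_equal_rates_two_groups(self):
        res = cochran_armitage(TrendTable((50, 80), (10, 16), (0.0, 1.0)))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.5)

    def test_all_successes_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = cochran_armitage(TrendTable((5, 5), (5, 5), (0.0, 1.0)))
        assert res.p_value == 1.0

    @given(st.integers(5, 60), st.integers(5, 60),
           st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_two_groups_reproduce_two_proportion_z(self, n1, n2, x1, x2):
        x1, x2 = min(x1, n1), min(x2, n2)
        tot = x1 + x2
        if tot == 0 or tot == n1 + n2:
            return
        trend = TrendTable((n1, n2), (x1, x2), (0.0, 1.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = cochran_armitage(trend, sidedness="two").statistic
        chi2 = pearson_chi2(
            ContingencyTable(np.array([[x1, n1 - x1], [x2, n2 - x2]]),
                             ("g1", "g2"), ("yes", "no"))
        ).statistic
        assert z**2 == pytest.approx(chi2, rel=1e-9)


def _auc_pairwise_oracle(t: TwoByTwoTable) -> float:
    """All positive/negative subject pairs; ties in score count one half."""
    wins = t.tp * t.tn
    ties = t.tp * t.fp + t.fn * t.tn
    return (wins + 0.5 * ties) / (t.n_outcome_pos * t.n_outcome_neg)


class TestBinaryLogistic:
    def test_screening_table(self, table5):
        fit = binary_logistic(table5)
        assert fit.wald_chi2 == pytest.approx(78.2, abs=0.05)
        assert fit.auc == pytest.approx(0.667, abs=5e-4)
        assert fit.brier == pytest.approx(0.168, abs=5e-4)
        assert fit.wald_p < 1e-4

    def test_uninformative(self):
        fit = binary_logistic(TwoByTwoTable(5, 5, 5, 5))
        assert fit.slope == 0.0
        assert fit.auc == 0.5
        assert fit.brier == 0.25

    def test_zero_cell_is_separation(self):
        with pytest.raises(CohortError, match="separat"):
            binary_logistic(TwoByTwoTable(0, 5, 5, 5))

    def test_slope_equals_log_odds_ratio(self, table5):
        assert binary_logistic(table5).slope == odds_ratio(table5).log_or

    @given(pos_tables)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_auc_matches_pairwise_rank_oracle(self, t):
        assert binary_logistic(t).auc == pytest.approx(
            _auc_pairwise_oracle(t), abs=1e-12
        )

    @pytest.mark.parametrize("cells", [(166, 267, 78, 502), (12, 40, 7, 91), (3, 2, 5, 9)])
    def test_closed_form_agrees_with_iterative_mle(self, cells):
        import statsmodels.api as sm

        t = TwoByTwoTable(*cells)
        x = np.repeat([1.0, 1.0, 0.0, 0.0], cells)
        y = np.repeat([1.0, 0.0, 1.0, 0.0], cells)
        ml = sm.Logit(y, sm.add_constant(x)).fit(disp=False, tol=1e-12)
        fit = binary_logistic(t)
        assert fit.intercept == pytest.approx(ml.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ml.params[1], abs=1e-6)
        assert fit.se_slope == pytest.approx(ml.bse[1], abs=1e-6)


class TestKruskalWallis:
    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 80), rng.normal(1.2, 1, 80)
        assert kruskal_wallis([a, b]).p_value < 1e-4

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


def _scan_cohort(label, a, b, c, d):
    """Cohort in which `label` is the only anomaly type present."""
    recs, i = [], 0
    for count, exposed, diag in ((a, True, True), (b, True, False),
                                 (c, False, True), (d, False, False)):
        for _ in range(count):
            i += 1
            recs.append(PatientRecord(
                patient_id=f"p{i}",
                eca_status=exposed,
                eca_types=(label,) if exposed else (),
                diagnosis_identified=diag,
            ))
    return Cohort(tuple(recs))


class TestEcaScan:
    def test_endocrine_pattern_significant(self):
        cohort = _scan_cohort("Endocrine", 10, 7, 234, 762)
        row = next(r for r in eca_scan(cohort, labels=("Endocrine",)))
        assert row.significant
        assert round(row.or_estimate.or_value, 1) == 4.7
        assert round(row.or_estimate.ci95[0], 1) == 1.8
        assert round(row.or_estimate.ci95[1], 1) == 12.4

    def test_skull_pattern_not_significant(self):
        cohort = _scan_cohort("Skull", 0, 1, 244, 768)
        row = next(r for r in eca_scan(cohort, labels=("Skull",)))
        assert row.exact_p == pytest.approx(1.0)
        assert not row.significant
        assert row.or_estimate is None

    def test_no_exposure_anywhere(self):
        cohort = _scan_cohort("Eye", 0, 0, 30, 70)
        rows = eca_scan(cohort, labels=("Eye", "Renal"))
        assert all(r.prevalence == 0 and r.or_estimate is None for r in rows)
        assert all(r.exact_p == 1.0 for r in rows)

    def test_or_present_iff_significant(self):
        cohort = _scan_cohort("Endocrine", 10, 7, 234, 762)
        for row in eca_scan(cohort, labels=("Endocrine", "Skull")):
            assert (row.or_estimate is not None) == row.significant
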