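"""Repeated-measures CV, confidence intervals, t-tests, correlations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dwirep import (
    CentileTable,
    PairedCohort,
    compare_medians,
    cv_by_centile,
    cv_confidence_interval,
    cv_from_sigma2,
    cv_repeated,
    parameter_correlations,
)


def brute_force_cv(visit1, visit2):
    """Textbook reference: explicit loop, mean-subtracted n-1 variance."""
    d = [math.log(v2) - math.log(v1) for v1, v2 in zip(visit1, visit2)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    return 100.0 * math.sqrt(math.expm1(var / 2.0))


def make_cohort(values, parameter="ADC"):
    """values: dict (subject, visit) -> constant centile value."""
    tables = []
    for (sub, visit), v in values.items():
        tables.append(
            CentileTable(parameter, np.full(101, float(v)), subject_id=sub, visit=visit)
        )
    return PairedCohort.from_tables(tables)


class TestCvRepeated:
    def test_identical_pairs_give_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        res = cv_repeated(v, v)
        assert res.sigma2 == 0.0
        assert res.cv_percent == 0.0
        assert res.ci_low == res.ci_high == 0.0

    def test_closed_form_sigma2_2ln2_gives_100pct(self):
        a = math.sqrt(math.log(2.0))
        res = cv_repeated([1.0, 1.0], [math.exp(a), math.exp(-a)])
        assert res.sigma2 == pytest.approx(2.0 * math.log(2.0), rel=1e-12)
        assert res.cv_percent == pytest.approx(100.0, rel=1e-12)

    def test_small_sigma2_maps_to_2_0002pct(self):
        # pairs engineered so the log-difference variance is exactly 8e-4
        s = math.sqrt(8e-4 / 2.0)
        res = cv_repeated([1.0, 1.0], [math.exp(s), math.exp(-s)])
        assert res.sigma2 == pytest.approx(8e-4, rel=1e-12)
        assert res.cv_percent == pytest.approx(2.000175, abs=1e-4)

    def test_matches_brute_force_on_random_cohorts(self, rng):
        for _ in range(200):
            n = rng.integers(2, 30)
            v1 = rng.lognormal(0.0, 1.0, n)
            v2 = v1 * rng.lognormal(0.0, 0.2, n)
            res = cv_repeated(v1, v2)
            assert res.cv_percent == pytest.approx(brute_force_cv(v1, v2), rel=1e-12)

    def test_zero_mean_convention(self):
        v1 = np.array([1.0, 1.0])
        v2 = np.array([2.0, 2.0])  # pure multiplicative shift
        default = cv_repeated(v1, v2)
        zero_mean = cv_repeated(v1, v2, convention="zero_mean")
        assert default.cv_percent == 0.0  # shift absorbed by the mean
        assert zero_mean.cv_percent == pytest.approx(
            cv_from_sigma2(math.log(2.0) ** 2), rel=1e-12
        )

    def test_nonpositive_value_raises_with_index(self):
        with pytest.raises(ValueError, match="visit 2"):
            cv_repeated([1.0, 2.0], [1.0, -2.0], parameter="f")

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cv_repeated([1.0], [1.0])

    @settings(max_examples=50, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, scale):
        v1 = np.array([0.9, 1.1, 1.3, 0.8])
        v2 = np.array([1.0, 1.0, 1.2, 0.9])
        a = cv_repeated(v1, v2)
        b = cv_repeated(scale * v1, scale * v2)
        assert b.sigma2 == pytest.approx(a.sigma2, rel=1e-9)
        assert b.cv_percent == pytest.approx(a.cv_percent, rel=1e-9)
        assert (b.ci_low, b.ci_high) == pytest.approx((a.ci_low, a.ci_high), rel=1e-9)

    def test_visit_symmetry(self):
        v1 = np.array([0.9, 1.1, 1.3, 0.8])
        v2 = np.array([1.0, 1.0, 1.2, 0.9])
        a = cv_repeated(v1, v2)
        b = cv_repeated(v2, v1)
        assert a.cv_percent == pytest.approx(b.cv_percent, rel=1e-12)
        assert (a.ci_low, a.ci_high) == pytest.approx((b.ci_low, b.ci_high), rel=1e-12)


class TestConfidenceInterval:
    def test_chi_square_endpoints_at_n15(self):
        sigma2, n = 8e-4, 15
        lo, hi = cv_confidence_interval(sigma2, n)
        df = n - 1
        expected_lo = cv_from_sigma2(df * sigma2 / stats.chi2.ppf(0.975, df))
        expected_hi = cv_from_sigma2(df * sigma2 / stats.chi2.ppf(0.025, df))
        assert lo == pytest.approx(expected_lo, rel=1e-12)
        assert hi == pytest.approx(expected_hi, rel=1e-12)
        assert lo <= cv_from_sigma2(sigma2) <= hi

    def test_width_shrinks_with_n(self, rng):
        s = 0.02
        n = 10**5
        v1 = np.exp(rng.normal(0, s, n))
        v2 = np.exp(rng.normal(0, s, n))
        res = cv_repeated(v1, v2)
        assert (res.ci_high - res.ci_low) < 0.01 * res.cv_percent

    def test_level_validation(self):
        with pytest.raises(ValueError, match="level"):
            cv_confidence_interval(1e-3, 10, level=1.5)

    def test_bootstrap_ci_contains_point_estimate(self, rng):
        v1 = rng.lognormal(0, 0.5, 15)
        v2 = v1 * rng.lognormal(0, 0.05, 15)
        res = cv_repeated(v1, v2, ci_method="bootstrap", n_boot=500, seed=1)
        assert res.ci_low <= res.cv_percent <= res.ci_high


class TestCvByCentile:
    def test_identical_visits_zero_everywhere(self):
        tables = []
        rng = np.random.default_rng(0)
        for sub in ("a", "b", "c"):
            centiles = np.sort(rng.lognormal(0, 0.3, 101))
            for visit in (1, 2):
                tables.append(CentileTable("ADC", centiles, subject_id=sub, visit=visit))
        cohort = PairedCohort.from_tables(tables)
        results = cv_by_centile(cohort, "ADC")
        assert len(results) == 101
        assert all(r.cv_percent == 0.0 for r in results)

    def test_flat_profile_matches_injected_cv(self, rng):
        # visits scaled by independent lognormal factors at every centile
        s = math.sqrt(math.log(1.0 + 0.10**2))  # inject 10% CV
        n_sub, n_rep = 15, 40
        cvs = []
        for rep in range(n_rep):
            tables = []
            for i in range(n_sub):
                base = np.sort(rng.lognormal(0, 0.3, 101))
                for visit in (1, 2):
                    factor = math.exp(rng.normal(0, s))
                    tables.append(
                        CentileTable("ADC", base * factor, subject_id=f"s{i}", visit=visit)
                    )
            cohort = PairedCohort.from_tables(tables)
            results = cv_by_centile(cohort, "ADC")
            cvs.append([r.cv_percent for r in results])
        mean_profile = np.mean(cvs, axis=0)
        # flat across centiles and centred on the injected 10%
        assert np.ptp(mean_profile) < 0.02 * 10.0
        mc_se = np.std(np.mean(cvs, axis=1), ddof=1) / math.sqrt(n_rep)
        assert abs(np.mean(mean_profile) - 10.0) < max(3 * mc_se, 0.35)

    def test_nonpositive_centile_skipped_with_warning(self, caplog):
        tables = []
        for sub in ("a", "b"):
            centiles = np.linspace(0.0, 1.0, 101)  # 0th centile is exactly 0
            for visit in (1, 2):
                tables.append(CentileTable("f", centiles, subject_id=sub, visit=visit))
        cohort = PairedCohort.from_tables(tables)
        with caplog.at_level("WARNING"):
            results = cv_by_centile(cohort, "f")
        assert len(results) == 100
        assert results[0].centile == 1
        assert "skipping centile 0" in caplog.text


class TestCompareMedians:
    def test_identical_visits_degenerate(self):
        cohort = make_cohort({("a", 1): 1.0, ("a", 2): 1.0, ("b", 1): 2.0, ("b", 2): 2.0})
        res = compare_medians(cohort, "ADC")
        assert res.t == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_symmetric_differences_give_t0(self):
        values = {}
        for i, d in enumerate([1.0, -1.0, 1.0, -1.0]):
            values[(f"s{i}", 1)] = 10.0
            values[(f"s{i}", 2)] = 10.0 + d
        res = compare_medians(make_cohort(values), "ADC")
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, rel=1e-12)
        assert not res.degenerate

    def test_hand_computed_t_statistic(self):
        diffs = [1.0, 2.0, 3.0, 4.0, 5.0]
        values = {}
        for i, d in enumerate(diffs):
            values[(f"s{i}", 1)] = 10.0
            values[(f"s{i}", 2)] = 10.0 + d
        res = compare_medians(make_cohort(values), "ADC")
        expected_t = 3.0 / (np.std(diffs, ddof=1) / math.sqrt(5))
        assert res.t == pytest.approx(expected_t, rel=1e-9)
        assert res.t == pytest.approx(4.242640687, rel=1e-6)
        assert res.df == 4

    def test_null_p_values_are_uniform(self, rng):
        # 2000 null cohorts of 10 pairs; KS against U(0,1) at alpha=0.01
        pvals = []
        for _ in range(2000):
            values = {}
            for i in range(10):
                values[(f"s{i}", 1)] = rng.lognormal(0, 0.2)
                values[(f"s{i}", 2)] = rng.lognormal(0, 0.2)
            pvals.append(compare_medians(make_cohort(values), "ADC").p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestParameterCorrelations:
    def _two_param_cohort(self, x, y):
        tables = []
        for i, (a, b) in enumerate(zip(x, y)):
            for visit in (1, 2):
                tables.append(CentileTable("p1", np.full(101, a), f"s{i}", visit))
                tables.append(CentileTable("p2", np.full(101, b), f"s{i}", visit))
        return PairedCohort.from_tables(tables)

    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        corr = parameter_correlations(self._two_param_cohort(x, x * 2))
        assert corr.get("p1", "p1") == 1.0
        assert corr.get("p1", "p2") == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        corr = parameter_correlations(self._two_param_cohort(x, 10.0 - x))
        assert corr.get("p1", "p2") == pytest.approx(-1.0)

    def test_constant_parameter_reported_missing(self):
        x = np.array([1.0, 2.0, 3.0])
        corr = parameter_correlations(self._two_param_cohort(x, np.ones(3)))
        assert np.isnan(corr.get("p1", "p2"))
        assert corr.get("p2", "p2") == 1.0

    def test_averages_the_two_visit_medians(self):
        # visit medians differ; correlation must use their average
        tables = []
        x_avg = [1.0, 2.0, 3.0]
        for i, v in enumerate(x_avg):
            tables.append(CentileTable("p1", np.full(101, v - 0.5), f"s{i}", 1))
            tables.append(CentileTable("p1", np.full(101, v + 0.5), f"s{i}", 2))
            tables.append(CentileTable("p2", np.full(101, 2 * v), f"s{i}", 1))
            tables.append(CentileTable("p2", np.full(101, 2 * v), f"s{i}", 2))
        corr = parameter_correlations(PairedCohort.from_tables(tables))
        assert corr.get("p1", "p2") == pytest.approx(1.0)

    def test_needs_three_subjects(self):
        x = np.array([1.0, 2.0])
        with pytest.raises(ValueError, match="3 subjects"):
            parameter_correlations(self._two_param_cohort(x, x))


class TestPairedCohort:
    def test_missing_visit_rejected(self):
        tables = [
            CentileTable("ADC", np.full(101, 1.0), "a", 1),
            CentileTable("ADC", np.full(101, 1.0), "a", 2),
            CentileTable("ADC", np.full(101, 1.0), "b", 1),
        ]
        with pytest.raises(ValueError, match="missing centile table"):
            PairedCohort.from_tables(tables)

    def test_subgroup_filter(self):
        values = {(f"s{i}", v): float(i + 1) for i in range(4) for v in (1, 2)}
        cohort = make_cohort(values)
        cohort.subgroups.update({"s0": "cranial", "s1": "cranial", "s2": "body", "s3": "body"})
        sub = cohort.filter("cranial")
        assert sub.subjects == ("s0", "s1")
        with pytest.raises(ValueError, match="fewer than 2"):
            cohort.filter("unknown")
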