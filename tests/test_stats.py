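"""Descriptive statistics and the univariate success-vs-failure tests.

Exact expected p values for the small-sample tests are derived from
exhaustive enumeration oracles implemented in this file (rank assignments
for Mann-Whitney, hypergeometric tables for Fisher).
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom, rankdata

from mpa_tdm.errors import DomainError
from mpa_tdm.nca import pk_params_frame, pk_summary
from mpa_tdm.stats import (compare_groups, correlations, cv_percent,
                           cv_percent_of, fisher_exact, mann_whitney,
                           median_iqr, spearman)


def mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating rank assignments."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    mean_u = na * (len(b)) / 2
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


def fisher_oracle(table):
    """Point-probability two-sided Fisher p by full enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    p = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            p += pk
    return p


class TestMedianIqr:
    def test_dose_distribution(self):
        # 21 patients on 2 g/day, two on 1, two on 3, one on 1.5
        doses = [2.0] * 21 + [1.0, 1.0, 3.0, 3.0, 1.5]
        assert median_iqr(doses) == (2.0, 2.0, 2.0)

    def test_interpolated_quartiles(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_single_value(self):
        assert median_iqr([7.0]) == (7.0, 7.0, 7.0)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            median_iqr([])


class TestCv:
    def test_printed_mean_sd(self):
        assert cv_percent(64, 28) == pytest.approx(43.75)
        assert round(cv_percent(64, 28)) == 44

    def test_zero_sd(self):
        assert cv_percent(5.0, 0.0) == 0.0

    def test_sample_cv_uses_n_minus_1(self):
        assert cv_percent_of([10, 20]) == pytest.approx(
            100 * math.sqrt(50) / 15)

    def test_zero_mean_rejected(self):
        with pytest.raises(DomainError):
            cv_percent(0.0, 1.0)


class TestMannWhitney:
    def test_no_overlap_small(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(mw_exact_oracle([1, 2], [3, 4]))
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_symmetric(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # n_a * n_b / 2
        assert p == pytest.approx(1.0)

    def test_extreme_separation(self):
        _, p = mann_whitney(np.arange(10) + 100.0, np.arange(10.0))
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney([], [1.0])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=4)
        b = rng.normal(size=5)
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(mw_exact_oracle(a, b), abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), shift=st.floats(-5, 5))
    def test_invariant_under_monotone_transform(self, seed, shift):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=8)
        b = rng.normal(loc=shift, size=9)
        f = lambda x: np.exp(np.asarray(x) / 3.0)  # strictly increasing
        assert mann_whitney(a, b)[1] == pytest.approx(
            mann_whitney(f(a), f(b))[1], abs=1e-12)

    def test_exact_and_normal_agree_at_10v10(self):
        """Exact and tie-free normal-approximation p within 0.02."""
        rng = np.random.default_rng(42)
        from scipy.stats import mannwhitneyu
        for _ in range(40):
            a = rng.normal(size=10)
            b = rng.normal(loc=rng.uniform(-1, 1), size=10)
            p_exact = mannwhitneyu(a, b, method="exact").pvalue
            p_norm = mannwhitneyu(a, b, method="asymptotic",
                                  use_continuity=True).pvalue
            assert abs(p_exact - p_norm) < 0.02


class TestFisherExact:
    def test_identical_rows(self):
        assert fisher_exact([[3, 3], [3, 3]]) == pytest.approx(1.0)

    def test_perfect_association(self):
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252)
        assert fisher_oracle([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_cohort_sex_table(self):
        # 12F/5M successes vs 4F/4M failures
        p = fisher_exact([[12, 5], [4, 4]])
        assert p == pytest.approx(fisher_oracle([[12, 5], [4, 4]]), abs=1e-10)
        assert p == pytest.approx(0.394, abs=0.001)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(a=st.integers(1, 10), b=st.integers(1, 10),
           c=st.integers(1, 10), d=st.integers(1, 10))
    def test_matches_enumeration_and_is_swap_invariant(self, a, b, c, d):
        p = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_oracle([[a, b], [c, d]]), abs=1e-9)
        assert p == pytest.approx(fisher_exact([[c, d], [a, b]]), abs=1e-12)
        assert p == pytest.approx(fisher_exact([[b, a], [d, c]]), abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(DomainError):
            fisher_exact([[0, 0], [3, 4]])

    def test_doubling_rule_option(self):
        p = fisher_exact([[12, 5], [4, 4]], rule="double_one_sided")
        assert 0 < p <= 1


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [2, 4, 6]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_hand_worked_rho(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (0,1,-1,0): 1 - 12/60 = 0.8
        res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8)
        # exact permutation p: count |rho| >= 0.8 over all 24 orderings
        count = sum(
            1 for perm in itertools.permutations([1, 3, 2, 4])
            if abs(np.corrcoef(rankdata([1, 2, 3, 4]),
                               rankdata(perm))[0, 1]) >= 0.8 - 1e-12)
        assert res.p_value == pytest.approx(count / 24)

    def test_rank_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert spearman(x, y).rho == pytest.approx(
            spearman(rankdata(x), rankdata(y)).rho, abs=1e-12)

    def test_constant_vector_flagged(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.rho is None and "undefined" in res.note

    def test_too_few_pairs(self):
        with pytest.raises(DomainError):
            spearman([1, 2], [3, 4])


class TestCompareGroups:
    def test_all_rows_present_on_fixture(self, small_cohort):
        pk = pk_params_frame(pk_summary(small_cohort))
        rows = compare_groups(small_cohort, pk, small_cohort.outcomes)
        names = [g.characteristic for g in rows]
        assert names[0] == "females_males"
        for expected in ("age_years", "mpa_auc_0_12", "mpa_c12h",
                         "mpag_auc_0_12", "ratio_auc", "ratio_c12h"):
            assert expected in names
        assert len(names) == 22
        by = {g.characteristic: g for g in rows}
        assert by["females_males"].test == "fisher_exact"
        assert by["mpa_c12h"].test == "mann_whitney"
        # two successes vs one failure: medians populated, p computable
        assert by["mpa_c12h"].failure_median == pytest.approx(0.6 * 1.2)

    def test_empty_failure_group_reports_absent(self, small_cohort):
        outcomes = [o for o in small_cohort.outcomes]
        for o in outcomes:
            o.label = "success"
            o.flare_month = None
        pk = pk_params_frame(pk_summary(small_cohort))
        rows = compare_groups(small_cohort, pk, outcomes)
        by = {g.characteristic: g for g in rows}
        assert by["mpa_c12h"].failure_median is None
        assert by["mpa_c12h"].p_value is None

    def test_correlation_pairs_emitted(self, small_cohort):
        pk = pk_params_frame(pk_summary(small_cohort))
        res = correlations(small_cohort, pk, small_cohort.outcomes)
        names = [r.pair for r in res]
        assert "mpa_auc_vs_albumin" in names
        assert "mpa_auc_vs_mpa_c12h" in names
        assert len(names) == 10
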