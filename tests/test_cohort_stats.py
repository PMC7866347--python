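"""Statistical engine versus independent from-scratch oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from luscohort.cohort_stats import (
    chisq_contingency,
    fleiss_kappa,
    kruskal_wallis,
    logistic_or,
    mann_whitney,
    proportion_ci,
)

# ---------------------------------------------------------------------------
# Oracles (kept deliberately naive and independent of the implementation path)
# ---------------------------------------------------------------------------

def clopper_pearson_bisection(x: int, n: int, alpha: float = 0.05):
    """Exact binomial bounds by bisection on the binomial tail probabilities."""

    def upper_tail(p):  # P(X >= x | p)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(x, n + 1))

    def lower_tail(p):  # P(X <= x | p)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(0, x + 1))

    def bisect(fn, target, increasing):
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if (fn(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    # lower bound solves P(X >= x | p) = alpha/2 (tail increasing in p);
    # upper bound solves P(X <= x | p) = alpha/2 (tail decreasing in p)
    lower = 0.0 if x == 0 else bisect(upper_tail, alpha / 2, increasing=True)
    upper = 1.0 if x == n else bisect(lower_tail, alpha / 2, increasing=False)
    return lower, upper


def mann_whitney_enumeration(a, b):
    """Exhaustively enumerate rank assignments for the exact two-sided p."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # assumes no ties

    def u_of(sample):
        r = sum(ranks[v] for v in sample)
        return r - len(sample) * (len(sample) + 1) / 2

    u_obs = u_of(a)
    n1 = len(a)
    mean_u = n1 * len(b) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(pooled, n1):
        u = u_of(combo)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


def kruskal_oracle(groups):
    """H from first principles: midranks, between-group sum, tie correction."""
    pooled = sorted(v for g in groups for v in g)
    n = len(pooled)
    midrank = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        for k in range(i, j):
            midrank.setdefault(pooled[i], (i + j + 1) / 2)
        i = j
    h = 12.0 / (n * (n + 1)) * sum(
        len(g) * (np.mean([midrank[v] for v in g]) - (n + 1) / 2) ** 2 for g in groups
    )
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction


def fleiss_oracle(table, raters):
    """Fleiss' kappa by direct arithmetic on the count matrix."""
    table = [[float(c) for c in row] for row in table]
    n_items = len(table)
    p_i = [
        (sum(c * c for c in row) - raters) / (raters * (raters - 1)) for row in table
    ]
    p_bar = sum(p_i) / n_items
    p_j = [sum(row[j] for row in table) / (n_items * raters) for j in range(len(table[0]))]
    p_e = sum(p * p for p in p_j)
    return (p_bar - p_e) / (1 - p_e)


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def test_complication_proportion_matches_printed_interval():
    est = proportion_ci(35, 166)
    assert round(est.point) == 21
    assert round(est.ci_low) == 15
    assert round(est.ci_high) == 28


def test_clopper_pearson_matches_bisection_oracle():
    for x, n in [(35, 166), (1, 10), (9, 9), (0, 20), (57, 166)]:
        est = proportion_ci(x, n)
        lo, hi = clopper_pearson_bisection(x, n)
        assert est.ci_low / 100 == pytest.approx(lo, abs=1e-8)
        assert est.ci_high / 100 == pytest.approx(hi, abs=1e-8)


def test_zero_numerator_interval_starts_at_zero():
    est = proportion_ci(0, 30)
    assert est.ci_low == 0.0
    assert est.point == 0.0


def test_interval_contains_point_and_widens_with_smaller_n():
    wide = proportion_ci(7, 33)
    narrow = proportion_ci(70, 330)
    for est in (wide, narrow):
        assert est.ci_low <= est.point <= est.ci_high
    assert (wide.ci_high - wide.ci_low) > (narrow.ci_high - narrow.ci_low)


def test_wilson_alternative_available():
    est = proportion_ci(35, 166, method="wilson")
    assert est.method == "wilson"
    assert round(est.ci_low) == 16  # differs from the exact interval's 15


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------

def test_stratum_contrast_p_rounds_to_printed_value():
    _, p = chisq_contingency([[21, 36], [14, 95]], yates=True)
    assert round(p, 3) == 0.001


def test_uncorrected_statistic_matches_hand_computed_expecteds():
    table = np.array([[21, 36], [14, 95]], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    oracle = ((table - expected) ** 2 / expected).sum()
    stat, _ = chisq_contingency(table, yates=False)
    assert stat == pytest.approx(oracle, rel=1e-12)


def test_flat_table_has_no_association():
    stat, p = chisq_contingency([[10, 10], [10, 10]], yates=False)
    assert stat == 0.0
    assert p == 1.0


def test_chisq_invariant_under_permutation():
    table = [[5, 9, 2], [7, 3, 11]]
    stat, p = chisq_contingency(table, yates=False)
    permuted = [list(reversed(row)) for row in reversed(table)]
    stat2, p2 = chisq_contingency(permuted, yates=False)
    assert stat2 == pytest.approx(stat, rel=1e-12)
    assert p2 == pytest.approx(p, rel=1e-12)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def test_mann_whitney_complete_ties():
    u, p = mann_whitney([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
    assert u == 4.5  # n1*n2/2
    assert p == 1.0


def test_mann_whitney_matches_exhaustive_enumeration():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    u, p = mann_whitney(a, b)
    u_oracle, p_oracle = mann_whitney_enumeration(a, b)
    assert u == u_oracle
    assert p == pytest.approx(p_oracle, abs=1e-12)
    # a second, non-extreme configuration
    a2, b2 = [1.0, 4.0, 5.0], [2.0, 3.0, 6.0]
    u2, p2 = mann_whitney(a2, b2)
    u2_oracle, p2_oracle = mann_whitney_enumeration(a2, b2)
    assert u2 == u2_oracle
    assert p2 == pytest.approx(p2_oracle, abs=1e-12)


def test_mann_whitney_swap_symmetry():
    a, b = [1.0, 2.0, 7.0, 9.0], [3.0, 4.0, 5.0]
    u_ab, p_ab = mann_whitney(a, b)
    u_ba, p_ba = mann_whitney(b, a)
    assert u_ba == len(a) * len(b) - u_ab
    assert p_ab == pytest.approx(p_ba)


def test_kruskal_identical_groups():
    h, p = kruskal_wallis([[3.0, 3.0], [3.0, 3.0, 3.0], [3.0]])
    assert h == 0.0
    assert p == 1.0


def test_kruskal_matches_brute_force_ranks():
    groups = [[1.0, 5.0, 8.0], [2.0, 2.0, 6.0], [3.0, 9.0]]
    h, _ = kruskal_wallis(groups)
    assert h == pytest.approx(kruskal_oracle(groups), rel=1e-12)


def test_two_group_kruskal_approaches_mann_whitney():
    """For two tie-free groups, H equals z^2 of the uncorrected normal approx."""
    rng = np.random.default_rng(5)
    a = rng.normal(0.0, 1.0, 60)
    b = rng.normal(0.5, 1.0, 60)
    h, p_kw = kruskal_wallis([a, b])
    u = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
    n1, n2 = len(a), len(b)
    z = (u - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    assert h == pytest.approx(z * z, rel=1e-9)
    assert p_kw == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-9)


# ---------------------------------------------------------------------------
# Fleiss' kappa
# ---------------------------------------------------------------------------

def test_perfect_agreement_gives_kappa_one():
    table = [[3, 0, 0], [0, 3, 0], [0, 0, 3], [3, 0, 0]]
    assert fleiss_kappa(table, raters=3) == 1.0
    # degenerate: everyone always picks the same single category
    assert fleiss_kappa([[3, 0], [3, 0]], raters=3) == 1.0


def test_hand_built_matrix_matches_arithmetic_oracle():
    table = [[1, 2, 0, 0], [0, 0, 3, 0], [1, 1, 1, 0], [0, 2, 0, 1], [2, 0, 1, 0]]
    kappa = fleiss_kappa(table, raters=3)
    assert kappa == pytest.approx(fleiss_oracle(table, 3), abs=1e-12)
    assert kappa <= 1.0


def test_uniform_random_ratings_drift_to_zero():
    rng = np.random.default_rng(12)
    raters, categories, items = 4, 4, 4000
    table = np.zeros((items, categories), dtype=int)
    choices = rng.integers(0, categories, size=(items, raters))
    for i in range(items):
        for r in choices[i]:
            table[i, r] += 1
    assert abs(fleiss_kappa(table, raters=raters)) < 0.02


def test_row_sum_mismatch_rejected():
    with pytest.raises(ValueError, match="rater count"):
        fleiss_kappa([[2, 0], [3, 0]], raters=3)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def _binary_design(n11, n10, n01, n00):
    """outcome/exposure vectors for a 2x2 table (exposed poor, exposed ok, ...)."""
    y = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
    x = [1] * (n11 + n10) + [0] * (n01 + n00)
    return y, x


def test_unadjusted_or_equals_closed_form_cross_product():
    """Outcome rows of the four-stratum table: 9/26 exposed, 9/122 unexposed."""
    y, x = _binary_design(9, 26, 9, 122)
    est = logistic_or(y, x)
    oracle_or = (9 * 122) / (26 * 9)
    se = math.sqrt(1 / 9 + 1 / 26 + 1 / 9 + 1 / 122)
    z = sps.norm.ppf(0.975)
    assert est.converged
    assert est.odds_ratio == pytest.approx(oracle_or, rel=1e-6)
    assert est.ci_low == pytest.approx(oracle_or * math.exp(-z * se), rel=1e-6)
    assert est.ci_high == pytest.approx(oracle_or * math.exp(z * se), rel=1e-6)


def test_equal_rates_give_unit_odds_ratio():
    y, x = _binary_design(5, 15, 10, 30)
    est = logistic_or(y, x)
    assert est.odds_ratio == pytest.approx(1.0, abs=1e-8)


def test_separation_reported_not_estimated():
    y = [1] * 10 + [0] * 10
    x = [1] * 10 + [0] * 10  # exposure perfectly predicts outcome
    est = logistic_or(y, x)
    assert not est.converged
    assert est.message
    assert math.isnan(est.odds_ratio)
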