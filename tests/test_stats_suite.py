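"""Exact Fisher test, Kruskal–Wallis, OLS fit and summary rows."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import fisher_exact as scipy_fisher, mannwhitneyu

from cxcl13index import (
    TwoByTwo,
    fisher_exact_two_sided,
    kruskal_wallis,
    linear_fit_r2,
    summarize_variable,
)
from cxcl13index.stats import (
    format_p,
    hypergeom_support_probabilities,
    significance_marks,
)


def enumeration_oracle(a, b, c, d):
    """Brute-force two-sided Fisher p: enumerate every table with the observed
    margins, compute each probability as an exact Fraction of factorials, and
    sum those no larger than the observed table's probability."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    f = math.factorial
    constant = Fraction(f(r1) * f(r2) * f(a + c) * f(b + d), f(n))

    def prob(aa):
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        return constant / (f(aa) * f(bb) * f(cc) * f(dd))

    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    p_obs = prob(a)
    return float(sum(p for p in map(prob, support) if p <= p_obs))


@pytest.mark.parametrize(
    "table, expected_3dp",
    [
        ((9, 8, 1, 19), 0.002),   # one or more clinical attacks
        ((16, 1, 13, 7), 0.048),  # OCB positivity
        ((1, 0, 0, 1), 1.0),
    ],
)
def test_fisher_reproduces_published_pvalues(table, expected_3dp):
    result = fisher_exact_two_sided(TwoByTwo(*table))
    assert round(result.p_value, 3) == expected_3dp


def test_fisher_cdms_below_one_in_a_thousand():
    result = fisher_exact_two_sided(TwoByTwo(14, 3, 2, 18))
    assert result.p_value < 0.001
    assert format_p(result.p_value) == "<0.001"


def test_fisher_zero_margin_degenerate():
    result = fisher_exact_two_sided(TwoByTwo(0, 0, 3, 5))
    assert result.p_value == 1.0
    assert result.degenerate


@given(a=st.integers(0, 15), b=st.integers(0, 15), c=st.integers(0, 15), d=st.integers(0, 15))
def test_fisher_invariant_under_row_and_column_swaps(a, b, c, d):
    if a + b + c + d == 0:
        return
    p = fisher_exact_two_sided(TwoByTwo(a, b, c, d)).p_value
    assert fisher_exact_two_sided(TwoByTwo(c, d, a, b)).p_value == p   # row swap
    assert fisher_exact_two_sided(TwoByTwo(b, a, d, c)).p_value == p   # column swap
    assert fisher_exact_two_sided(TwoByTwo(d, c, b, a)).p_value == p   # both


@pytest.mark.parametrize("table", [(9, 8, 1, 19), (16, 1, 13, 7), (14, 3, 2, 18), (5, 0, 0, 7), (3, 3, 3, 3)])
def test_fisher_agrees_with_independent_implementations(table):
    p = fisher_exact_two_sided(TwoByTwo(*table)).p_value
    assert p == pytest.approx(enumeration_oracle(*table), rel=1e-12)
    a, b, c, d = table
    assert p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], rel=1e-7)


@given(r1=st.integers(1, 25), r2=st.integers(1, 25), c1=st.integers(0, 50))
def test_hypergeometric_support_normalizes(r1, r2, c1):
    c1 = min(c1, r1 + r2)
    probs = hypergeom_support_probabilities(r1, r2, c1)
    assert abs(probs.sum() - 1.0) < 1e-12


def test_kruskal_wallis_hand_computed_example():
    """Ranks 1..6 split as {1,2,3} vs {4,5,6}: H = (12/42)(12+75) - 21 = 27/7."""
    result = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
    assert result.statistic == pytest.approx(27 / 7, abs=5e-4)


def test_kruskal_wallis_constant_data_degenerate():
    result = kruskal_wallis([[3.0, 3.0, 3.0], [3.0, 3.0]])
    assert result.statistic == 0.0
    assert result.p_value == 1.0


def test_kruskal_wallis_rejects_empty_group():
    with pytest.raises(ValueError, match="non-empty"):
        kruskal_wallis([[1.0, 2.0], []])


def test_kruskal_wallis_two_groups_matches_ranksum_oracle():
    """With two groups and no ties, the KW chi-square p equals the two-sided
    normal-approximation Mann–Whitney p."""
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    y = rng.normal(loc=0.7, size=15)
    kw = kruskal_wallis([x, y]).p_value
    mw = mannwhitneyu(x, y, method="asymptotic", use_continuity=False).pvalue
    assert kw == pytest.approx(mw, rel=1e-9)


def test_linear_fit_exact_line():
    x = [0.0, 1.0, 2.0, 3.0]
    fit = linear_fit_r2(x, [2 * v + 1 for v in x])
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_linear_fit_five_point_arithmetic_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.1, 2.9, 4.2, 3.8, 5.1])
    fit = linear_fit_r2(x, y)
    # independent normal-equation computation
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    intercept = y.mean() - slope * x.mean()
    ss_res = np.sum((y - (intercept + slope * x)) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    assert fit.slope == pytest.approx(slope, rel=1e-12)
    assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)


def test_linear_fit_independent_data_has_small_r2():
    rng = np.random.default_rng(11)
    x, y = rng.normal(size=1000), rng.normal(size=1000)
    fit = linear_fit_r2(x, y)
    assert fit.r_squared < 0.01
    assert 0 <= fit.p_value_slope <= 1


def test_linear_fit_constant_x_rejected():
    with pytest.raises(ValueError, match="constant"):
        linear_fit_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_summary_binary_row_matches_published_ocb_cells():
    row = summarize_variable(
        "OCB Positive (%)",
        {"low": [True] * 13 + [False] * 7, "high": [True] * 16 + [False] * 1},
        "binary",
    )
    assert row.cells == {"low": "13 (65.0)", "high": "16 (94.1)"}
    assert round(row.test.p_value, 3) == 0.048
    assert row.significance == "*"


def test_summary_mean_sd_format():
    rng = np.random.default_rng(5)
    row = summarize_variable(
        "Age (mean (SD))",
        {"low": rng.normal(41.89, 12.27, 200), "high": rng.normal(35.51, 10.51, 200)},
        "continuous_mean_sd",
    )
    import re

    assert re.fullmatch(r"\d+\.\d{2} \(\d+\.\d{2}\)", row.cells["low"])


def test_summary_constant_continuous_is_degenerate():
    row = summarize_variable("x", {"low": [4.0, 4.0], "high": [4.0, 4.0, 4.0]}, "continuous_median_iqr")
    assert row.test.p_value == 1.0
    assert row.cells["low"] == row.cells["high"] == "4.00 [4.00, 4.00]"


def test_summary_categorical_has_no_pvalue():
    row = summarize_variable(
        "Diagnosis (%)", {"low": ["CIS"] * 16 + ["RIS"] * 4, "high": ["CIS"] * 17}, "categorical"
    )
    assert row.test is None
    assert row.levels["RIS"] == {"low": "4 (20.0)", "high": "0 (0.0)"}


def test_summary_kind_mismatch_rejected():
    with pytest.raises(ValueError, match="unknown kind"):
        summarize_variable("x", {"low": [1], "high": [2]}, "exotic")
    with pytest.raises(ValueError, match="non-boolean"):
        summarize_variable("x", {"low": [1.5], "high": [True]}, "binary")


def test_significance_marks_follow_legend():
    assert significance_marks(0.0005) == "***"
    assert significance_marks(0.002) == "**"
    assert significance_marks(0.048) == "*"
    assert significance_marks(0.1) == ""
    assert format_p(0.0480) == "0.048"
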