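"""Hypothesis tests and summary statistics for the group-comparison table.

The two-sided Fisher exact test is implemented here by full enumeration of
the hypergeometric support with exact integer arithmetic: conditioning on
the table margins, each table's weight C(r1,k)·C(r2,c1-k) is an integer, and
the p-value is the exact rational sum of weights no larger than the observed
one, divided by C(n,c1).  Ties are compared exactly, so no floating-point
tie slack is needed.  This two-sided "probability at most that observed"
rule is the classic definition and reproduces the printed cohort p-values.

Kruskal–Wallis (tie-corrected H, chi-square p) and the least-squares fit are
delegated to scipy behind this module's interface.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclasses.dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table: rows outcome yes/no, columns group high/low."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclasses.dataclass(frozen=True)
class TestResult:
    statistic: Optional[float]
    p_value: float
    method: str
    n: int
    degenerate: bool = False


@dataclasses.dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    p_value_slope: float
    n: int


def hypergeom_support_weights(r1: int, r2: int, c1: int) -> tuple[int, list[int]]:
    """Integer hypergeometric weights over the support of a in the 2x2 table.

    Returns ``(k_min, weights)`` where ``weights[i]`` is
    ``C(r1, k_min+i) * C(r2, c1-k_min-i)``; dividing by ``C(r1+r2, c1)``
    gives the conditional probability of each table.
    """
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    return k_min, [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(k_min, k_max + 1)]


def hypergeom_support_probabilities(r1: int, r2: int, c1: int) -> np.ndarray:
    """Floating-point conditional probabilities over the support (sums to 1)."""
    k_min, weights = hypergeom_support_weights(r1, r2, c1)
    total = math.comb(r1 + r2, c1)
    return np.array([w / total for w in weights])


def fisher_exact_two_sided(table: TwoByTwo) -> TestResult:
    """Two-sided Fisher exact test by exhaustive enumeration of the support.

    p = sum of conditional probabilities of every table sharing the observed
    margins whose probability does not exceed that of the observed table.
    A zero margin makes the table degenerate: the observed table is the only
    one possible, p = 1, flagged via ``degenerate``.
    """
    n = table.total
    if n < 1:
        raise ValueError("table total must be at least 1")
    r1, r2 = table.a + table.b, table.c + table.d
    c1, c2 = table.a + table.c, table.b + table.d
    if min(r1, r2, c1, c2) == 0:
        return TestResult(None, 1.0, "fisher_exact_two_sided", n, degenerate=True)
    k_min, weights = hypergeom_support_weights(r1, r2, c1)
    w_obs = weights[table.a - k_min]
    numerator = sum(w for w in weights if w <= w_obs)
    p = numerator / math.comb(n, c1)  # correctly-rounded big-int division
    return TestResult(None, min(p, 1.0), "fisher_exact_two_sided", n)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test (tie-corrected, chi-square approximation).

    Every group must be non-empty and the pooled sample size at least 3.
    Pooled constant data has no rank variation: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    n = sum(len(g) for g in groups)
    if n < 3:
        raise ValueError("pooled sample size must be at least 3")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis", n, degenerate=True)
    stat, p = sps.kruskal(*groups)
    return TestResult(float(stat), float(p), "kruskal_wallis", n)


def linear_fit_r2(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Ordinary least squares of y on x with R² and the slope t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("x is constant; slope undefined")
    fit = sps.linregress(x, y)
    return FitResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value_slope=float(fit.pvalue),
        n=int(x.size),
    )


# --- summary-table machinery -------------------------------------------------

KINDS = ("continuous_median_iqr", "continuous_mean_sd", "binary", "categorical")


@dataclasses.dataclass(frozen=True)
class SummaryRow:
    """One formatted row of the group-comparison table.

    ``cells`` maps group label -> formatted cell.  ``levels`` is populated
    instead of ``cells`` for categorical variables (level -> per-group
    cells), which carry no p-value, mirroring standard cohort tables.
    """

    variable: str
    kind: str
    cells: dict[str, str] = dataclasses.field(default_factory=dict)
    levels: dict[str, dict[str, str]] = dataclasses.field(default_factory=dict)
    test: Optional[TestResult] = None

    @property
    def p_formatted(self) -> str:
        return "" if self.test is None else format_p(self.test.p_value)

    @property
    def significance(self) -> str:
        return "" if self.test is None else significance_marks(self.test.p_value)


def format_p(p: float) -> str:
    """Render a p-value to 3 decimal places with a '<0.001' floor."""
    if p < 0.001:
        return "<0.001"
    if p > 0.999:
        return ">0.999"
    return f"{p:.3f}"


def significance_marks(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _median_iqr(values: np.ndarray) -> str:
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    return f"{med:.2f} [{q1:.2f}, {q3:.2f}]"


def summarize_variable(
    variable: str,
    groups: dict[str, Sequence],
    kind: str,
) -> SummaryRow:
    """Build one group-comparison row with the appropriate test.

    continuous kinds -> Kruskal–Wallis p; binary (boolean collections, two
    groups) -> two-sided Fisher exact p; categorical -> per-level count rows,
    no p-value.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {KINDS}")
    labels = list(groups)
    if kind in ("continuous_median_iqr", "continuous_mean_sd"):
        arrays = {}
        for label in labels:
            arr = np.asarray(list(groups[label]), dtype=float)
            arrays[label] = arr[~np.isnan(arr)]
        nonempty = [arr for arr in arrays.values() if arr.size]
        test = kruskal_wallis(nonempty) if len(nonempty) >= 2 else None
        cells = {}
        for label, arr in arrays.items():
            if arr.size == 0:
                cells[label] = "NA"
            elif kind == "continuous_median_iqr":
                cells[label] = _median_iqr(arr)
            else:
                cells[label] = f"{arr.mean():.2f} ({arr.std(ddof=1) if arr.size > 1 else 0.0:.2f})"
        return SummaryRow(variable, kind, cells=cells, test=test)
    if kind == "binary":
        flags = {label: [bool(v) for v in groups[label]] for label in labels}
        for label in labels:
            if any(not isinstance(v, (bool, np.bool_)) for v in groups[label]):
                raise ValueError(f"binary variable {variable!r}: group {label!r} has non-boolean values")
        cells = {}
        for label in labels:
            k, m = sum(flags[label]), len(flags[label])
            cells[label] = f"{k} ({100 * k / m:.1f})" if m else "NA"
        test = None
        if len(labels) == 2 and all(len(flags[label]) for label in labels):
            (k1, m1), (k2, m2) = ((sum(flags[l]), len(flags[l])) for l in labels)
            test = fisher_exact_two_sided(TwoByTwo(a=k1, b=k2, c=m1 - k1, d=m2 - k2))
        return SummaryRow(variable, kind, cells=cells, test=test)
    # categorical: one sub-row per level, no test (as in standard cohort tables)
    level_names: list[str] = []
    for label in labels:
        for v in groups[label]:
            if str(v) not in level_names:
                level_names.append(str(v))
    levels = {}
    for level in level_names:
        row = {}
        for label in labels:
            vals = [str(v) for v in groups[label]]
            k, m = vals.count(level), len(vals)
            row[label] = f"{k} ({100 * k / m:.1f})" if m else "NA"
        levels[level] = row
    return SummaryRow(variable, kind, levels=levels, test=None)
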