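"""Association statistics used by the analysis.

Rank-based tests (Mann-Whitney U, Kruskal-Wallis, Spearman) and
ordinary least squares are delegated to scipy; Dunn's post-hoc z tests
(not available there) are implemented directly from the pooled
mean-rank formula with tie correction.  Everything returns a uniform
``TestResult`` so the pipeline can serialize a tidy results table.

Stage and grade are ordinal; for correlation and regression they are
coded as consecutive integers (I..V -> 1..5, ISUP 1..5 as printed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .exceptions import (
    DegenerateDesignError,
    UndefinedCorrelationError,
)

__all__ = [
    "GroupedValues",
    "TestResult",
    "RegressionFit",
    "PairwiseComparison",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "spearman",
    "linear_fit",
    "concordance_r2",
]


@dataclass
class GroupedValues:
    """Ordered categorical groups with one value vector per group."""

    labels: list[str]
    values: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values must align")
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if any(len(v) == 0 for v in self.values):
            raise ValueError("every group must be non-empty")


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    statistic: float  # z
    p_value: float
    p_adjusted: float


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: int
    df: Optional[int] = None
    comparisons: Optional[list[PairwiseComparison]] = None


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    ci95_slope: tuple[float, float]
    n: int

    @property
    def r_squared(self) -> float:
        return self.r * self.r


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U.

    U is the count of (a, b) pairs with a > b plus half the ties (rank
    sum convention).  The p-value uses exact enumeration for small
    untied samples and the tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = _sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    # scipy reports U for the first sample under the "greater" pair
    # count; the smaller-of-the-two convention is symmetric in p.
    u = min(float(res.statistic), len(a) * len(b) - float(res.statistic))
    return TestResult(
        test="mann-whitney-u",
        statistic=u,
        p_value=float(res.pvalue),
        n=len(a) + len(b),
    )


def kruskal_wallis(g: GroupedValues) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    if len(g.values) < 2:
        raise ValueError("omnibus test requires >= 2 groups")
    total = sum(len(v) for v in g.values)
    if total < 5:
        raise ValueError("omnibus test requires total n >= 5")
    pooled = np.concatenate(g.values)
    if np.all(pooled == pooled[0]):
        # degenerate: no rank variation at all
        return TestResult(
            test="kruskal-wallis",
            statistic=0.0,
            p_value=1.0,
            n=total,
            df=len(g.values) - 1,
        )
    h, p = _sps.kruskal(*g.values)
    return TestResult(
        test="kruskal-wallis",
        statistic=float(h),
        p_value=float(p),
        n=total,
        df=len(g.values) - 1,
    )


def dunn_posthoc(g: GroupedValues, adjust: str = "bonferroni") -> TestResult:
    """Dunn's multiple-comparison z tests after a Kruskal-Wallis omnibus.

    Pairwise z = (mean rank_i - mean rank_j) / sqrt(V (1/n_i + 1/n_j))
    with V = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1)) pooling all tied
    groups.  ``bonferroni`` multiplies each two-sided normal p by the
    number of pairs (the labeled default of common ANOVA software);
    ``none`` reports raw p-values.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    omnibus = kruskal_wallis(g)
    pooled = np.concatenate(g.values)
    n_total = len(pooled)
    ranks = _sps.rankdata(pooled)
    # tie correction over pooled rank groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    variance = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = []
    start = 0
    sizes = [len(v) for v in g.values]
    for sz in sizes:
        mean_ranks.append(float(np.mean(ranks[start : start + sz])))
        start += sz
    k = len(g.values)
    n_pairs = k * (k - 1) // 2
    comparisons = []
    for i in range(k):
        for j in range(i + 1, k):
            if sizes[i] == 1 or sizes[j] == 1:
                import warnings

                warnings.warn(
                    f"singleton group in Dunn comparison ({g.labels[i]}, {g.labels[j]})",
                    stacklevel=2,
                )
            denom = np.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
            p_raw = float(2.0 * _sps.norm.sf(abs(z)))
            p_adj = min(1.0, p_raw * n_pairs) if adjust == "bonferroni" else p_raw
            comparisons.append(
                PairwiseComparison(
                    pair=(g.labels[i], g.labels[j]),
                    statistic=float(z),
                    p_value=p_raw,
                    p_adjusted=p_adj,
                )
            )
    return TestResult(
        test="dunn",
        statistic=omnibus.statistic,
        p_value=omnibus.p_value,
        n=n_total,
        df=k - 1,
        comparisons=comparisons,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman requires equal lengths >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("zero variance in an input vector")
    rho, p = _sps.spearmanr(x, y)
    return TestResult(test="spearman", statistic=float(rho), p_value=float(p), n=len(x))


def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Simple OLS with the signed correlation and a t-based slope CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("linear_fit requires equal lengths >= 3")
    if np.all(x == x[0]):
        raise DegenerateDesignError("constant predictor: slope is unidentified")
    fit = _sps.linregress(x, y)
    n = len(x)
    tcrit = float(_sps.t.ppf(0.975, n - 2))
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        ci95_slope=(float(ci[0]), float(ci[1])),
        n=n,
    )


def concordance_r2(a: Sequence[float], b: Sequence[float]) -> float:
    """Squared Pearson correlation between two methods' paired estimates."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("concordance requires paired inputs of length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise UndefinedCorrelationError("zero variance in an input vector")
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r
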