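"""Effect sizes and nonparametric tests for reading-experiment data.

Implements the pooled-SD standardized mean difference

    d = (X1 - X2) / Sw,
    Sw = sqrt(((n1-1) S1^2 + (n2-1) S2^2) / (n1 + n2 - 2)),

a large-sample confidence interval for d, Wilcoxon signed-rank and
rank-sum tests with exact small-sample null distributions (mid-ranks
for ties, zeros dropped), Holm step-down multiplicity adjustment, and
error-percentage bookkeeping against text word totals.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "EffectSize",
    "TestResult",
    "pooled_sd",
    "cohens_d",
    "cohens_d_ci",
    "d_contrast",
    "wilcoxon_signed_rank",
    "rank_sum",
    "holm_bonferroni",
    "percent_of_total",
]


@dataclass(frozen=True)
class GroupSummary:
    """A mean/SD/n triple summarizing one group or condition."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")

    @classmethod
    def from_sample(cls, x: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(x, dtype=float)
        return cls(n=arr.size, mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


@dataclass(frozen=True)
class EffectSize:
    d: float
    sw: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    level: float = 0.95


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "signed-rank" | "rank-sum"
    exact: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def pooled_sd(g1: GroupSummary, g2: GroupSummary) -> float:
    """Pooled standard deviation Sw of two summarized groups."""
    if g1.n + g2.n <= 2:
        raise ValueError("pooled SD needs n1 + n2 > 2")
    num = (g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2
    return math.sqrt(num / (g1.n + g2.n - 2))


def cohens_d(
    g1: GroupSummary, g2: GroupSummary, level: float | None = 0.95
) -> EffectSize:
    """Pooled-SD Cohen d = (mean1 - mean2) / Sw, with optional CI."""
    sw = pooled_sd(g1, g2)
    if sw == 0:
        raise ZeroDivisionError("effect size undefined: pooled SD is zero")
    d = (g1.mean - g2.mean) / sw
    if level is None:
        return EffectSize(d=d, sw=sw)
    lo, hi = cohens_d_ci(d, g1.n, g2.n, level)
    return EffectSize(d=d, sw=sw, ci_low=lo, ci_high=hi, level=level)


def cohens_d_ci(d: float, n1: int, n2: int, level: float = 0.95) -> tuple[float, float]:
    """Large-sample normal interval for d.

    Uses se(d) = sqrt((n1+n2)/(n1 n2) + d^2 / (2 (n1+n2))).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = sps.norm.ppf(0.5 + level / 2.0)
    se = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    return d - z * se, d + z * se


def d_contrast(d_a: float, d_b: float) -> float:
    """Difference of two effect sizes (each signed so that an error
    decrease is positive)."""
    if not (math.isfinite(d_a) and math.isfinite(d_b)):
        raise ValueError("effect sizes must be finite")
    return d_a - d_b


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _exact_tail_p(w: float, dist_vals: np.ndarray, dist_counts: np.ndarray) -> float:
    total = dist_counts.sum()
    le = dist_counts[dist_vals <= w + 1e-9].sum()
    ge = dist_counts[dist_vals >= w - 1e-9].sum()
    return float(min(1.0, 2.0 * min(le, ge) / total))


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of the doubled positive-rank sum via DP."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    vals = np.arange(total + 1, dtype=float)
    return vals, counts


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float] | None = None, *, exact_max_n: int = 25
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied absolute differences get
    mid-ranks.  Up to ``exact_max_n`` informative pairs the null
    distribution is enumerated exactly (conditional on the observed
    ranks); beyond that a normal approximation with continuity
    correction (via scipy) is used.
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    d = d[d != 0]
    if d.size == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="signed-rank", exact=True)
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if d.size <= exact_max_n:
        doubled = np.round(2 * ranks).astype(int)
        vals, counts = _signed_rank_distribution(doubled)
        p = _exact_tail_p(2 * w_pos, vals, counts)
        return TestResult(statistic=w_pos, p_value=p, method="signed-rank", exact=True)
    res = sps.wilcoxon(d, correction=True, method="approx")
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="signed-rank", exact=False,
    )


def _rank_sum_distribution(doubled_ranks: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of group-1's doubled rank sum over all
    C(N, n1) labelings, via DP on (chosen count, sum)."""
    total = int(doubled_ranks.sum())
    counts = np.zeros((n1 + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        for k in range(n1, 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    vals = np.arange(total + 1, dtype=float)
    return vals, counts[n1]


def rank_sum(
    a: Sequence[float], b: Sequence[float], *, exact_max_n: int = 10
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation null (conditional on mid-ranks) when both groups
    have at most ``exact_max_n`` observations; otherwise scipy's normal
    approximation with continuity and tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = _midranks(np.concatenate([a, b]))
    w = float(ranks[: a.size].sum())
    if a.size <= exact_max_n and b.size <= exact_max_n:
        doubled = np.round(2 * ranks).astype(int)
        vals, counts = _rank_sum_distribution(doubled, a.size)
        p = _exact_tail_p(2 * w, vals, counts)
        return TestResult(statistic=w, p_value=p, method="rank-sum", exact=True)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="rank-sum", exact=False,
    )


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def percent_of_total(mean_count: float, text_word_counts: Sequence[int]) -> float:
    """Express a mean misread-word count as a percentage of the total
    word count of the reading material (all parts summed)."""
    total = int(np.sum(text_word_counts))
    if total <= 0:
        raise ValueError("total word count must be positive")
    return 100.0 * mean_count / total
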