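"""Rank-based cohort statistics.

The unpaired rank-sum and one-sample signed-rank statistics are computed
with the normal approximation, midrank tie handling and no continuity
correction — the convention used throughout the cluster statistics, the
latency-balance control and the per-group median tests.  Spearman
correlations go through scipy.  Bonferroni control uses the fixed family
of eight tests (2 groups x 2 signals x 2 levels).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import norm, rankdata, spearmanr

__all__ = [
    "TestKind",
    "StatResult",
    "rank_sum_z",
    "signed_rank_z",
    "median_vs_zero_test",
    "rank_sum_test",
    "spearman_assoc",
    "bonferroni",
]


class TestKind(str, Enum):
    SIGNED_RANK = "SIGNED_RANK"
    RANK_SUM = "RANK_SUM"
    SPEARMAN = "SPEARMAN"


@dataclass
class StatResult:
    test: TestKind
    statistic: float  # Z for rank tests, R for Spearman
    p: float
    n: int
    alpha_corrected: float | None = None
    significant: bool | None = None
    label: str = ""


def rank_sum_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Unpaired Wilcoxon rank-sum Z and two-sided p, oriented A minus B.

    Z = (W - nA(n+1)/2) / sd with W the rank sum of group A over the
    pooled sample, midranks for ties, tie-corrected variance, no
    continuity correction.  Positive Z means A tends larger.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = ranks[:n_a].sum()
    e_w = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    var = n_a * n_b * (n + 1) / 12.0 - n_a * n_b * tie_term / (12.0 * n * (n - 1))
    if var <= 0:
        return 0.0, 1.0
    z = (w - e_w) / np.sqrt(var)
    return float(z), float(2 * norm.sf(abs(z)))


def signed_rank_z(values: np.ndarray) -> tuple[float, float, int]:
    """One-sample Wilcoxon signed-rank Z against zero median.

    Zeros are dropped; |values| are midranked; W+ is the rank sum of the
    positive values; Z = (W+ - n(n+1)/4) / sd with tie-corrected variance.
    Returns (Z, two-sided p, effective n).
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    n = len(v)
    if n == 0:
        raise ValueError("all values are zero; signed-rank test undefined")
    ranks = rankdata(np.abs(v))
    w_plus = ranks[v > 0].sum()
    e_w = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(v), return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        return 0.0, 1.0, n
    z = (w_plus - e_w) / np.sqrt(var)
    return float(z), float(2 * norm.sf(abs(z))), n


def median_vs_zero_test(values: np.ndarray, label: str = "") -> StatResult:
    """Does the per-subject combined effect have a non-zero median?

    Wilcoxon signed-rank with normal approximation; the Z sign follows
    the rank statistic (positive when the distribution leans positive).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise ValueError("need at least 5 subjects")
    if np.all(v == 0):
        raise ValueError("all combined effects are exactly zero")
    z, p, n = signed_rank_z(v)
    return StatResult(TestKind.SIGNED_RANK, z, p, n, label=label)


def rank_sum_test(a: np.ndarray, b: np.ndarray, label: str = "") -> StatResult:
    z, p = rank_sum_z(a, b)
    return StatResult(TestKind.RANK_SUM, z, p, len(a) + len(b), label=label)


def spearman_assoc(x: np.ndarray, y: np.ndarray, label: str = "") -> StatResult:
    """Spearman rank correlation with midranks; two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 subjects")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; correlation undefined")
    r, p = spearmanr(x, y)
    return StatResult(TestKind.SPEARMAN, float(r), float(p), len(x), label=label)


def bonferroni(family: list[StatResult], m: int = 8, alpha: float = 0.05) -> list[StatResult]:
    """Annotate a family of tests with the corrected significance flag.

    Each result is significant iff p < alpha/m; the family size defaults
    to the eight-test family (2 groups x 2 signals x 2 levels).
    """
    if m < 1:
        raise ValueError("family size must be >= 1")
    thr = alpha / m
    for res in family:
        res.alpha_corrected = thr
        res.significant = bool(res.p < thr)
    return family
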