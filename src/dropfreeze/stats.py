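"""Nonparametric and proportion tests used by the freezing-assay pipeline.

Implements the three tests the analysis relies on — the two-sample test of
equal proportions with Yates continuity correction, the Kruskal–Wallis
rank-sum test with tie correction, and Dunn's pairwise post-hoc z test —
directly from their rank/contingency formulas.  Mid-ranks are used for ties
throughout.  Only chi-squared / normal tail approximations are provided (no
permutation variants), matching the conventional tooling for these tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "PairwiseResult",
    "prop_test_2x2",
    "kruskal_wallis",
    "dunn_posthoc",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in [0, 1], got {self.p_value}")


@dataclass(frozen=True)
class PairwiseResult:
    """One Dunn pairwise comparison between two groups.

    ``statistic`` is the z score computed as (rank mean of group_a) minus
    (rank mean of group_b), scaled by the tie-corrected pooled variance, so
    its sign says which group ranks higher.
    """

    group_a: int
    group_b: int
    statistic: float
    p_value: float
    p_adjusted: float
    method: str = "Dunn's z test"


def prop_test_2x2(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    continuity: bool = True,
) -> TestResult:
    """Two-sample test for equality of proportions on a 2x2 table.

    Chi-squared statistic with 1 degree of freedom; with ``continuity`` the
    Yates correction ``n * (|ad - bc| - n/2)^2 / (row and column products)``
    is applied, with the correction term capped so the corrected deviation
    is never negative (equal proportions give statistic exactly 0).

    Parameters
    ----------
    k1, n1 : successes and trials in the first sample.
    k2, n2 : successes and trials in the second sample.
    continuity : apply the Yates continuity correction (default True).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("each sample needs at least one trial")
        if not 0 <= k <= n:
            raise ValueError(f"successes {k} outside [0, {n}]")
    a, b = float(k1), float(n1 - k1)
    c, d = float(k2), float(n2 - k2)
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0.0:
        warnings.warn(
            "degenerate 2x2 margins (pooled all-success or all-failure); "
            "returning statistic 0, p 1",
            stacklevel=2,
        )
        return TestResult(0.0, 1, 1.0, _prop_method(continuity))
    dev = abs(a * d - b * c)
    if continuity:
        dev = max(dev - n / 2.0, 0.0)
    stat = n * dev**2 / margins
    return TestResult(stat, 1, float(chi2.sf(stat, 1)), _prop_method(continuity))


def _prop_method(continuity: bool) -> str:
    base = "2-sample test for equality of proportions"
    return base + (" with continuity correction" if continuity else "")


def _ranked_groups(groups: Sequence[Sequence[float]]):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("need at least three observations in total")
    ranks = rankdata(pooled)  # mid-ranks for ties
    sizes = np.array([a.size for a in arrays])
    splits = np.split(ranks, np.cumsum(sizes)[:-1])
    # tie correction term: sum over tied groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    return splits, sizes, pooled.size, tie_sum


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test across two or more groups.

    H is computed from mid-rank group means and divided by the tie
    correction ``1 - sum(t^3 - t) / (N^3 - N)``; the p-value uses the
    chi-squared approximation with ``k - 1`` degrees of freedom.  When all
    pooled values are identical H is 0 and p is 1 by convention.
    """
    splits, sizes, n_total, tie_sum = _ranked_groups(groups)
    df = len(sizes) - 1
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    if correction <= 0.0:  # all values identical
        return TestResult(0.0, df, 1.0, "Kruskal-Wallis rank sum test")
    rank_means = np.array([s.mean() for s in splits])
    h = (
        12.0
        / (n_total * (n_total + 1))
        * float(np.sum(sizes * (rank_means - (n_total + 1) / 2.0) ** 2))
    )
    h /= correction
    return TestResult(h, df, float(chi2.sf(h, df)), "Kruskal-Wallis rank sum test")


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjustment: str = "none",
) -> list[PairwiseResult]:
    """Dunn's pairwise post-hoc comparisons after a Kruskal–Wallis test.

    For each pair (i, j) the z statistic is the difference of mid-rank means
    over ``sqrt((N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j))``;
    p-values are two-sided.  ``adjustment`` is one of ``none``, ``holm`` or
    ``bh`` applied across all k(k-1)/2 pairs.
    """
    if adjustment not in ("none", "holm", "bh"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    splits, sizes, n_total, tie_sum = _ranked_groups(groups)
    var_term = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    rank_means = [s.mean() for s in splits]
    pairs = list(itertools.combinations(range(len(sizes)), 2))
    z_values, p_values = [], []
    for i, j in pairs:
        se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0.0 else (rank_means[i] - rank_means[j]) / se
        z_values.append(float(z))
        p_values.append(float(2.0 * norm.sf(abs(z))))
    if adjustment == "none":
        adjusted = p_values
    else:
        method = {"holm": "holm", "bh": "fdr_bh"}[adjustment]
        adjusted = list(multipletests(p_values, method=method)[1])
    return [
        PairwiseResult(i, j, z, p, float(padj))
        for (i, j), z, p, padj in zip(pairs, z_values, p_values, adjusted)
    ]
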