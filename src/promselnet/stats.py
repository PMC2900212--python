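"""Shared nonparametric statistics: rank-sum comparison and Kendall correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau, mannwhitneyu, norm, rankdata

__all__ = ["RankSumResult", "rank_sum_test", "kendall_corr"]

_EXACT_N = 12


@dataclass(frozen=True)
class RankSumResult:
    p: float
    study_median: float
    reference_median: float
    n_study: int
    n_reference: int
    method: str  # "exact" or "normal"
    alternative: str


def rank_sum_test(
    study, reference, alternative: str = "two-sided"
) -> RankSumResult:
    """Wilcoxon-Mann-Whitney rank-sum test of study vs reference values.

    Exact null enumeration when both samples have <= 12 observations and no
    ties span the groups; otherwise the tie-corrected normal approximation
    (no continuity correction, so identical samples give a one-tailed p of
    exactly 0.5).  ``alternative`` refers to the study sample: "greater"
    means study values tend to exceed reference values.
    """
    x = np.asarray(study, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if x.size <= _EXACT_N and y.size <= _EXACT_N and not has_ties:
        res = mannwhitneyu(x, y, alternative=alternative, method="exact")
        p, method = float(res.pvalue), "exact"
    else:
        p, method = _normal_rank_sum(x, y, alternative), "normal"
    return RankSumResult(
        p=p,
        study_median=float(np.median(x)),
        reference_median=float(np.median(y)),
        n_study=int(x.size),
        n_reference=int(y.size),
        method=method,
        alternative=alternative,
    )


def _normal_rank_sum(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    n1, n2 = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # MWU statistic of the study sample
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:  # all observations identical
        return 0.5 if alternative != "two-sided" else 1.0
    z = (u1 - mu) / np.sqrt(var)
    if alternative == "greater":
        return float(norm.sf(z))
    if alternative == "less":
        return float(norm.cdf(z))
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * norm.sf(abs(z))))
    raise ValueError(f"unknown alternative {alternative!r}")


def kendall_corr(x, y, exact_n: int = 8) -> tuple[float, float]:
    """Kendall tau-b with its p-value.

    Exact p by permutation enumeration for n <= ``exact_n`` without ties,
    normal approximation otherwise (the tie-adjusted tau-b convention).
    Constant input vectors make the correlation undefined and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector: correlation undefined")
    no_ties = np.unique(x).size == x.size and np.unique(y).size == y.size
    method = "exact" if (x.size <= exact_n and no_ties) else "asymptotic"
    res = kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)
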