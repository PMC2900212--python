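"""Hypergeometric over/under-representation of a study set in functional categories.

For each category present in the reference annotation, the number k of study
genes in the category is compared with a Hypergeometric(N, K, n) draw (N
reference genes, K of them in the category, n study genes):

    p_over  = P(X >= k)    p_under = P(X <= k)

Genes may belong to several categories (each category is tested on its own
urn); genes without any annotation still count in N.  No multiple-testing
correction is applied by default; Benjamini-Hochberg is optional.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "hypergeom_enrichment", "enrichment_table"]


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    N: int  # reference size
    K: int  # reference genes in category
    n: int  # study size
    k: int  # study genes in category
    p_over: float
    p_under: float

    def flags(self, alpha: float = 0.05) -> tuple[bool, bool]:
        return self.p_over < alpha, self.p_under < alpha


def hypergeom_enrichment(
    annotation: dict,
    reference: set,
    study: set,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One hypergeometric test per category occurring in the reference set.

    ``annotation`` maps gene -> set of category identifiers (genes may be
    missing or map to an empty set).  ``study`` must be a subset of
    ``reference``.  Results are sorted by ascending p_over.
    """
    reference = set(reference)
    study = set(study)
    extra = study - reference
    if extra:
        raise ValueError(
            f"study set is not contained in the reference set ({len(extra)} strays)"
        )
    N, n = len(reference), len(study)
    if N == 0 or n == 0:
        raise ValueError("reference and study sets must be nonempty")
    cat_ref: dict[str, int] = {}
    cat_study: dict[str, int] = {}
    for gene in reference:
        for cat in annotation.get(gene, ()):
            cat_ref[cat] = cat_ref.get(cat, 0) + 1
            if gene in study:
                cat_study[cat] = cat_study.get(cat, 0) + 1
    out = []
    for cat, K in sorted(cat_ref.items()):
        k = cat_study.get(cat, 0)
        out.append(
            EnrichmentResult(
                category=cat,
                N=N,
                K=K,
                n=n,
                k=k,
                p_over=float(hypergeom.sf(k - 1, N, K, n)),
                p_under=float(hypergeom.cdf(k, N, K, n)),
            )
        )
    out.sort(key=lambda r: (r.p_over, r.category))
    return out


def enrichment_table(
    results: list[EnrichmentResult], alpha: float = 0.05, correct: bool = False
) -> pd.DataFrame:
    """Tabulate results with enriched/impoverished flags (optionally BH-adjusted)."""
    df = pd.DataFrame([r.__dict__ for r in results])
    if df.empty:
        return df
    if correct:
        df["q_over"] = multipletests(df["p_over"], method="fdr_bh")[1]
        df["q_under"] = multipletests(df["p_under"], method="fdr_bh")[1]
        df["enriched"] = df["q_over"] < alpha
        df["impoverished"] = df["q_under"] < alpha
    else:
        df["enriched"] = df["p_over"] < alpha
        df["impoverished"] = df["p_under"] < alpha
    return df
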