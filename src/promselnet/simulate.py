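"""Synthetic-data generators with the statistical structure the pipeline assumes.

Every generator is deterministic given its seed.  The defaults describe the
study conditions of the scan: 1-kb promoters paired with ~4-kb intronic
references evolving under HKY (kappa 4, GC-poor base composition typical of
noncoding human DNA) on a human/chimp/macaque star tree with human and chimp
branches near 0.005 substitutions/site and a macaque branch near 0.03;
heavy-tailed protein networks grown by preferential attachment; selection
labels planted by a logistic model in (log-)eigenvector centrality;
expression values log-normal with a rank-of-centrality shift; category
annotations multinomial with an optional planted enrichment.

No indels are simulated: gap handling is exercised by deterministic fixture
alignments, and the likelihood drops gapped columns anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import rankdata

from .alignment import TripletAlignment
from .hky import BranchLengths, HKYParams, HKYTransition, PromoterScales

__all__ = [
    "SimulationConfig",
    "simulate_triplet",
    "simulate_gene_case",
    "simulate_network",
    "plant_labels",
    "intercept_for_prevalence",
    "simulate_expression",
    "simulate_annotations",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a full synthetic fixture."""

    seed: int = 0
    n_genes: int = 20
    promoter_len: int = 1000
    intron_len: int = 4000
    hky: HKYParams = field(default_factory=lambda: HKYParams(kappa=4.0, pi=(0.3, 0.2, 0.2, 0.3)))
    branch_lengths: BranchLengths = field(
        default_factory=lambda: BranchLengths(0.0053, 0.0055, 0.030)
    )
    zeta_positive: float = 5.0  # human-branch scaler of the accelerated genes
    n_positive: int = 2
    network_size: int = 2000
    attachment_edges: int = 3
    logistic_beta1: float = 2.0  # planted slope on log-EVC
    baseline_prevalence: float = 0.10
    n_tissues: int = 12
    expression_coupling: float = 1.0
    n_categories: int = 10
    enrichment_effect: float = 5.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "promoter_len", "intron_len", "network_size", "n_tissues", "n_categories"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _branch_child(rng: np.random.Generator, parent: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Evolve parent states one branch: child_i ~ Categorical(P[parent_i])."""
    u = rng.random(parent.size)
    cdf = P.cumsum(axis=1)
    return (u[:, None] > cdf[parent]).sum(axis=1).astype(np.int8)


def simulate_triplet(
    hky: HKYParams,
    bl: BranchLengths,
    scales: PromoterScales,
    n_sites: int,
    seed,
    role: str = "promoter",
) -> TripletAlignment:
    """Gapless triplet alignment evolved from a stationary root on the star tree."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = np.random.default_rng(seed)
    trans = HKYTransition(hky)
    root = rng.choice(4, size=n_sites, p=hky.pi_array)
    rows = []
    for t, z in zip(bl.as_array(), scales.as_array()):
        rows.append(_branch_child(rng, root, trans.probability(z * t)))
    seqs = tuple("".join(_BASES[r]) for r in rows)
    return TripletAlignment(ids=("human", "chimp", "macaque"), seqs=seqs, role=role)


def simulate_gene_case(
    config: SimulationConfig, zeta_h: float, seed
) -> tuple[TripletAlignment, TripletAlignment]:
    """(promoter, intron) alignment pair for one gene.

    Both regions share the neutral parameters; the intron evolves with unit
    scalers and the promoter with (zeta_h, 1, 1).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_prom, s_intr = ss.spawn(2)
    prom = simulate_triplet(
        config.hky,
        config.branch_lengths,
        PromoterScales(zeta_h, 1.0, 1.0),
        config.promoter_len,
        s_prom,
        role="promoter",
    )
    intron = simulate_triplet(
        config.hky,
        config.branch_lengths,
        PromoterScales(1.0, 1.0, 1.0),
        config.intron_len,
        s_intr,
        role="intron",
    )
    return prom, intron


def simulate_network(n: int, m: int, seed) -> list[tuple[str, str]]:
    """Preferential-attachment (heavy-tailed degree) edge list on gene ids G0000..

    m edges per arriving node; the graph is connected by construction and
    m = 1 yields a tree with exactly n - 1 edges.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 and m >= 1")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31 - 1)))
    width = len(str(n - 1))
    name = {v: f"G{v:0{width}d}" for v in g.nodes()}
    return [(name[a], name[b]) for a, b in g.edges()]


def intercept_for_prevalence(values, beta1: float, transform: str, prevalence: float) -> float:
    """Intercept placing the planted logistic model at a target mean label rate.

    Solves mean(expit(beta0 + beta1*x)) = prevalence exactly (the mean-field
    shortcut logit(p) - beta1*mean(x) is biased when the slope is steep).
    """
    from scipy.optimize import brentq

    x = np.asarray(values, dtype=float)
    if transform == "log":
        x = np.log(x)
    center = logit(prevalence) - beta1 * x.mean()

    def gap(b0: float) -> float:
        return expit(b0 + beta1 * x).mean() - prevalence

    return float(brentq(gap, center - 50.0, center + 50.0))


def plant_labels(
    centrality_values, beta0: float, beta1: float, transform: str, seed
) -> np.ndarray:
    """Binary labels ~ Bernoulli(logit^-1(beta0 + beta1 * transform(value)))."""
    x = np.asarray(centrality_values, dtype=float)
    if transform == "log":
        if (x <= 0).any():
            raise ValueError("log transform requires positive values")
        x = np.log(x)
    elif transform != "identity":
        raise ValueError("transform must be 'identity' or 'log'")
    rng = np.random.default_rng(seed)
    p = expit(beta0 + beta1 * x)
    return (rng.random(x.size) < p).astype(int)


def simulate_expression(
    genes,
    n_tissues: int,
    centrality,
    coupling: float,
    seed,
    sigma: float = 0.8,
    absent_rate: float = 0.10,
) -> pd.DataFrame:
    """Long-format (gene_id, tissue, value, call) table coupled to centrality.

    Values are log-normal; each gene's log-mean is shifted by
    ``coupling * (rank of its centrality, scaled to [0, 1])``, and roughly
    ``absent_rate`` of the calls are marked absent at random.
    """
    genes = list(genes)
    cent = np.asarray(centrality, dtype=float)
    if len(genes) != cent.size:
        raise ValueError("genes and centrality must align")
    rng = np.random.default_rng(seed)
    shift = coupling * (rankdata(cent) - 1) / max(1, cent.size - 1)
    rows = []
    for g, s in zip(genes, shift):
        logv = rng.normal(loc=2.0 + s, scale=sigma, size=n_tissues)
        calls = np.where(rng.random(n_tissues) < absent_rate, "A", "P")
        for t in range(n_tissues):
            rows.append((g, f"tissue{t:02d}", float(np.exp(logv[t])), calls[t]))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "value", "call"])


def simulate_annotations(
    genes,
    n_categories: int,
    enriched_category: str | None,
    effect: float,
    seed,
    study_genes=None,
    second_category_prob: float = 0.25,
) -> pd.DataFrame:
    """Gene -> category table with an optional planted enrichment.

    Baseline genes draw their primary category uniformly (and a second
    distinct one with probability ``second_category_prob``).  Genes in
    ``study_genes`` draw the primary category with the enriched category's
    probability multiplied by ``effect`` (then renormalized), planting an
    over-representation at that odds multiplier.
    """
    if n_categories < 2:
        raise ValueError("need at least two categories")
    genes = list(genes)
    study = set(study_genes or ())
    cats = [f"CAT{i:02d}" for i in range(n_categories)]
    names = [f"category {i}" for i in range(n_categories)]
    if enriched_category is not None and enriched_category not in cats:
        raise ValueError(f"enriched_category must be one of {cats}")
    rng = np.random.default_rng(seed)
    base = np.ones(n_categories) / n_categories
    boosted = base.copy()
    if enriched_category is not None:
        boosted[cats.index(enriched_category)] *= effect
        boosted /= boosted.sum()
    rows = []
    for g in genes:
        p = boosted if g in study else base
        first = int(rng.choice(n_categories, p=p))
        chosen = [first]
        if rng.random() < second_category_prob:
            second = int(rng.choice(n_categories))
            if second != first:
                chosen.append(second)
        for c in chosen:
            rows.append((g, cats[c], names[c]))
    return pd.DataFrame(rows, columns=["gene_id", "category_id", "category_name"])
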