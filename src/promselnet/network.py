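"""Protein-interaction network centrality and its association with selection status.

The graph is undirected and unweighted; all centrality measures are computed
on the largest connected component:

* degree — number of interaction partners;
* betweenness — Brandes pair-dependency sum (unnormalized, endpoints
  excluded): for each unordered pair (s, t), the fraction of shortest s-t
  paths passing through the node;
* ASPL — average shortest-path length from the node to every other node in
  the component (smaller = more central);
* EVC — the node's entry in the principal eigenvector of the adjacency
  matrix, scaled so the maximum over nodes is 1.

Association analyses: one-tailed rank-sum comparisons of a study set against
a reference set, logistic regression of selection status on (optionally
log-transformed) centrality, quantile binning for display, and the
top-central / central-reference set constructions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import RankSumResult, rank_sum_test

__all__ = [
    "build_network",
    "largest_component",
    "centralities",
    "eigenvector_centrality",
    "AssociationFit",
    "compare_centrality",
    "centrality_logistic",
    "quantile_bins",
    "top_central",
    "central_reference",
    "plot_quantile_bins",
]

METRICS = ("degree", "betweenness", "aspl", "evc")


def build_network(edge_list, extra_nodes=None) -> nx.Graph:
    """Undirected simple graph from an iterable of identifier pairs.

    Self-loops are dropped and duplicate edges (in either orientation)
    collapse.  Isolated nodes appear only if passed via ``extra_nodes``.
    """
    g = nx.Graph()
    for row in edge_list:
        try:
            a, b = row[0], row[1]
        except (TypeError, IndexError) as exc:
            raise ValueError(f"malformed edge row: {row!r}") from exc
        if a == b:
            continue
        g.add_edge(a, b)
    if extra_nodes is not None:
        g.add_nodes_from(extra_nodes)
    return g


def largest_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected vertex set.

    Size ties break deterministically toward the component containing the
    lexicographically smallest member.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = sorted(
        nx.connected_components(net),
        key=lambda c: (-len(c), min(str(v) for v in c)),
    )
    return net.subgraph(comps[0]).copy()


def eigenvector_centrality(
    net: nx.Graph, tol: float = 1e-10, max_iter: int = 100000
) -> dict:
    """Principal-eigenvector scores scaled to max = 1.

    Power iteration on A + I from the uniform vector; the identity shift
    leaves the eigenvectors unchanged while making the dominant eigenvalue
    unique even on bipartite graphs.  All entries are positive on a
    connected graph (Perron-Frobenius).
    """
    nodes = list(net.nodes())
    A = nx.to_scipy_sparse_array(net, nodelist=nodes, dtype=float, format="csr")
    x = np.ones(len(nodes)) / len(nodes)
    for _ in range(max_iter):
        x_new = A @ x + x
        x_new /= x_new.max()
        if np.abs(x_new - x).max() < tol:
            x = x_new
            break
        x = x_new
    else:
        raise RuntimeError("eigenvector centrality power iteration did not converge")
    return dict(zip(nodes, x))


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness, ASPL and EVC on a connected graph.

    Returns a DataFrame indexed by node with columns degree, betweenness,
    aspl, evc.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net):
        raise ValueError("centralities require a connected graph; pass the largest component")
    nodes = list(net.nodes())
    deg = dict(net.degree())
    btw = nx.betweenness_centrality(net, normalized=False)
    n = len(nodes)
    if n == 1:
        aspl = {nodes[0]: 0.0}
    else:
        aspl = {
            s: sum(lengths.values()) / (n - 1)
            for s, lengths in nx.all_pairs_shortest_path_length(net)
        }
    evc = eigenvector_centrality(net) if n > 1 else {nodes[0]: 1.0}
    df = pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "aspl": [aspl[v] for v in nodes],
            "evc": [evc[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return df


def compare_centrality(
    records: pd.DataFrame,
    study_set,
    reference_set,
    metric: str,
    alternative: str,
) -> RankSumResult:
    """Rank-sum comparison of one centrality metric between two gene sets.

    ``alternative`` is stated for the *study* values ("greater"/"less"/
    "two-sided"); note that for ASPL "more central" means smaller values, so
    the caller inverts the direction there.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    study = [g for g in study_set if g in records.index]
    ref = [g for g in reference_set if g in records.index]
    if not study or not ref:
        raise ValueError("study and reference sets must both intersect the records")
    return rank_sum_test(
        records.loc[study, metric].to_numpy(),
        records.loc[ref, metric].to_numpy(),
        alternative=alternative,
    )


@dataclass(frozen=True)
class AssociationFit:
    coefficient: float
    stderr: float
    p: float
    intercept: float
    transform: str
    n: int
    converged: bool
    separated: bool = False


def centrality_logistic(
    records: pd.DataFrame,
    labels: pd.Series | dict,
    transform: str = "log",
    metric: str = "evc",
) -> AssociationFit:
    """Logistic regression of selection status (0/1) on a centrality metric.

    The metric is transformed (natural log or identity) before the
    binomial-logit ML fit; the reported p is the Wald test of the slope.
    Perfect separation is flagged and the coefficient reported non-finite.
    """
    if transform not in ("identity", "log"):
        raise ValueError("transform must be 'identity' or 'log'")
    lab = pd.Series(labels)
    common = records.index.intersection(lab.index)
    if len(common) == 0:
        raise ValueError("no overlap between records and labels")
    y = lab.loc[common].astype(float).to_numpy()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one observation of each class")
    x = records.loc[common, metric].astype(float).to_numpy()
    if transform == "log":
        if (x <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        x = np.log(x)
    X = sm.add_constant(x)
    separated = False
    try:
        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        separated = any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        ) or not np.isfinite(fit.bse[1])
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:  # statsmodels PerfectSeparationError and kin
        separated = True
    if separated:
        return AssociationFit(
            coefficient=float("inf"),
            stderr=float("nan"),
            p=float("nan"),
            intercept=float("nan"),
            transform=transform,
            n=int(len(y)),
            converged=False,
            separated=True,
        )
    return AssociationFit(
        coefficient=float(fit.params[1]),
        stderr=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        transform=transform,
        n=int(len(y)),
        converged=converged,
        separated=separated,
    )


def quantile_bins(values, labels, k: int = 20) -> pd.DataFrame:
    """Positive-label frequency within k empirical-quantile bins.

    Bin i (1..k) has upper boundary the i/k empirical quantile; each value
    goes to the lowest bin whose upper quantile is >= the value.  Returns a
    DataFrame with columns upper_quantile, frequency, n.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if v.size != y.size:
        raise ValueError("values and labels must have equal length")
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(v).size < k:
        raise ValueError("k exceeds the number of distinct values")
    uppers = np.quantile(v, np.arange(1, k + 1) / k)
    bin_of = np.searchsorted(uppers, v, side="left")
    bin_of = np.minimum(bin_of, k - 1)  # numerical guard at the maximum
    n = np.bincount(bin_of, minlength=k)
    pos = np.bincount(bin_of, weights=y, minlength=k)
    with np.errstate(invalid="ignore"):
        freq = np.where(n > 0, pos / np.maximum(n, 1), 0.0)
    return pd.DataFrame(
        {"upper_quantile": uppers, "frequency": freq, "n": n},
        index=pd.RangeIndex(1, k + 1, name="bin"),
    )


def top_central(records: pd.DataFrame, gene_set, k: int = 10) -> list:
    """The k most central genes of a set by EVC (ties: degree, then identifier)."""
    genes = [g for g in gene_set if g in records.index]
    missing = set(gene_set) - set(genes)
    if missing:
        raise ValueError(f"genes absent from the centrality table: {sorted(missing)[:5]}")
    ordered = sorted(
        genes,
        key=lambda g: (-records.at[g, "evc"], -records.at[g, "degree"], str(g)),
    )
    return ordered[:k]


def central_reference(records: pd.DataFrame, threshold_evc: float) -> set:
    """All nodes with EVC strictly above a threshold."""
    if not 0.0 <= threshold_evc <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return set(records.index[records["evc"] > threshold_evc])


def plot_quantile_bins(bins: pd.DataFrame, fit: AssociationFit | None = None, ax=None):
    """Scatter of positive frequency vs log upper-quantile EVC, with the fitted curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.log(bins["upper_quantile"].to_numpy())
    ax.plot(x, bins["frequency"].to_numpy(), "o", label="observed")
    if fit is not None and np.isfinite(fit.coefficient):
        grid = np.linspace(x.min(), x.max(), 200)
        eta = fit.intercept + fit.coefficient * (
            grid if fit.transform == "log" else np.exp(grid)
        )
        ax.plot(grid, 1.0 / (1.0 + np.exp(-eta)), "-", label="logistic fit")
    ax.set_xlabel("log upper-quantile EVC")
    ax.set_ylabel("positive frequency")
    ax.legend()
    return ax
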