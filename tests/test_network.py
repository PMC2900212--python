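"""Graph construction, the four centralities (with independent oracles),
and the centrality-selection association statistics."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from promselnet.network import (
    build_network,
    centralities,
    central_reference,
    centrality_logistic,
    compare_centrality,
    largest_component,
    quantile_bins,
    top_central,
)
from promselnet.simulate import (
    intercept_for_prevalence,
    plant_labels,
    simulate_network,
)

# --- hand-rolled oracles (independent of networkx's algorithms) -------------


def floyd_warshall(nodes, edges):
    dist = {(a, b): (0 if a == b else np.inf) for a in nodes for b in nodes}
    for a, b in edges:
        dist[(a, b)] = dist[(b, a)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                d = dist[(i, k)] + dist[(k, j)]
                if d < dist[(i, j)]:
                    dist[(i, j)] = d
    return dist


def brute_betweenness(nodes, edges):
    """Enumerate all shortest paths by DFS and sum pair dependencies."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    dist = floyd_warshall(nodes, edges)

    def all_shortest(s, t):
        target = dist[(s, t)]
        paths = []

        def dfs(v, path):
            if len(path) - 1 > target:
                return
            if v == t and len(path) - 1 == target:
                paths.append(list(path))
                return
            for w in adj[v]:
                if w not in path and dist[(s, v)] + 1 + dist[(w, t)] <= target:
                    path.append(w)
                    dfs(w, path)
                    path.pop()

        dfs(s, [s])
        return paths

    btw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if not np.isfinite(dist[(s, t)]):
            continue
        paths = all_shortest(s, t)
        for v in nodes:
            if v in (s, t):
                continue
            passing = sum(1 for p in paths if v in p)
            btw[v] += passing / len(paths)
    return btw


class TestBuildNetwork:
    def test_dedup_and_self_loop_drop(self):
        g = build_network([("A", "B"), ("B", "A"), ("A", "A")])
        assert set(g.nodes()) == {"A", "B"}
        assert g.number_of_edges() == 1

    def test_empty(self):
        assert build_network([]).number_of_nodes() == 0

    def test_random_pairs_edge_count(self):
        rng = np.random.default_rng(0)
        pairs = [tuple(rng.integers(0, 40, size=2)) for _ in range(1000)]
        g = build_network(pairs)
        distinct = {frozenset(p) for p in pairs if p[0] != p[1]}
        assert g.number_of_edges() == len(distinct)

    def test_malformed_row_rejected(self):
        with pytest.raises(ValueError):
            build_network([("A",)])


class TestLargestComponent:
    def test_picks_bigger(self):
        g = build_network([("A", "B"), ("B", "C"), ("D", "E")])
        comp = largest_component(g)
        assert set(comp.nodes()) == {"A", "B", "C"}

    def test_connected_graph_is_itself(self):
        g = build_network([("A", "B"), ("B", "C")])
        assert set(largest_component(g).nodes()) == set(g.nodes())

    def test_tie_breaks_to_lexicographically_smallest(self):
        g = build_network([("C", "D"), ("A", "B")])
        assert set(largest_component(g).nodes()) == {"A", "B"}


class TestCentralities:
    def test_path_of_three(self):
        g = build_network([("A", "B"), ("B", "C")])
        df = centralities(g)
        assert df.at["B", "degree"] == 2
        assert df.at["B", "betweenness"] == pytest.approx(1.0)
        assert df.at["A", "aspl"] == pytest.approx(1.5)
        # principal eigenvector of the 3-path is (1, sqrt2, 1)/sqrt2 after max-scaling
        assert df.at["B", "evc"] == pytest.approx(1.0, abs=1e-4)
        assert df.at["A", "evc"] == pytest.approx(np.sqrt(0.5), abs=1e-4)

    def test_star_of_four_leaves(self):
        g = build_network([("hub", f"leaf{i}") for i in range(4)])
        df = centralities(g)
        assert df.at["hub", "betweenness"] == pytest.approx(6.0)
        assert df.at["leaf0", "aspl"] == pytest.approx(1.75)
        assert df.at["hub", "evc"] == pytest.approx(1.0)
        assert df.at["leaf0", "evc"] == pytest.approx(0.5, abs=1e-6)

    def test_handshake_identity(self):
        edges = simulate_network(60, 2, seed=4)
        g = largest_component(build_network(edges))
        df = centralities(g)
        assert df["degree"].sum() == 2 * g.number_of_edges()

    def test_disconnected_rejected(self):
        g = build_network([("A", "B"), ("C", "D")])
        with pytest.raises(ValueError):
            centralities(g)

    def test_brute_force_oracle_small_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(3, 9))
            p = rng.uniform(0.3, 0.9)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            comp = largest_component(build_network(list(g.edges())))
            if comp.number_of_nodes() < 3:
                continue
            nodes = list(comp.nodes())
            edges = list(comp.edges())
            df = centralities(comp)
            deg = {v: sum(1 for e in edges if v in e) for v in nodes}
            dist = floyd_warshall(nodes, edges)
            btw = brute_betweenness(nodes, edges)
            A = np.zeros((len(nodes), len(nodes)))
            idx = {v: i for i, v in enumerate(nodes)}
            for a, b in edges:
                A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1
            w, V = np.linalg.eigh(A)
            v = np.abs(V[:, np.argmax(w)])
            v /= v.max()
            for node in nodes:
                assert df.at[node, "degree"] == deg[node]
                assert df.at[node, "betweenness"] == pytest.approx(btw[node], abs=1e-9)
                aspl = np.mean([dist[(node, o)] for o in nodes if o != node])
                assert df.at[node, "aspl"] == pytest.approx(aspl, abs=1e-12)
                assert df.at[node, "evc"] == pytest.approx(v[idx[node]], abs=1e-7)

    def test_tree_betweenness_sum_identity(self):
        edges = simulate_network(30, 1, seed=9)
        g = largest_component(build_network(edges))
        df = centralities(g)
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        pair_sum = sum(
            lengths[s][t] - 1 for s, t in itertools.combinations(g.nodes(), 2)
        )
        assert df["betweenness"].sum() == pytest.approx(pair_sum)

    def test_evc_eigen_residual_and_positivity(self):
        edges = simulate_network(300, 3, seed=5)
        g = largest_component(build_network(edges))
        df = centralities(g)
        nodes = list(df.index)
        A = nx.to_numpy_array(g, nodelist=nodes)
        v = df["evc"].to_numpy()
        lam = (v @ A @ v) / (v @ v)
        resid = np.linalg.norm(A @ v - lam * v) / np.linalg.norm(A @ v)
        assert resid < 1e-8
        assert (v > 0).all()
        assert v.max() == pytest.approx(1.0)

    def test_aspl_evc_rank_orders_anticorrelate(self):
        edges = simulate_network(400, 3, seed=6)
        g = largest_component(build_network(edges))
        df = centralities(g)
        rho = df["aspl"].rank().corr(df["evc"].rank())
        assert rho < 0


class TestCompareCentrality:
    @pytest.fixture
    def records(self):
        return pd.DataFrame(
            {
                "degree": [1, 2, 3, 4, 5, 6],
                "betweenness": [0, 1, 2, 3, 4, 5],
                "aspl": [6, 5, 4, 3, 2, 1],
                "evc": [0.1, 0.2, 0.3, 0.4, 0.5, 1.0],
            },
            index=list("abcdef"),
        )

    def test_exact_small_sample(self, records):
        res = compare_centrality(records, ["a", "b", "c"], ["d", "e", "f"], "degree", "less")
        assert res.p == pytest.approx(1 / 20)
        assert res.method == "exact"

    def test_identical_multisets_one_tailed_half(self):
        rec = pd.DataFrame(
            {"degree": [1, 2, 1, 2], "betweenness": 0, "aspl": 1, "evc": 0.5},
            index=list("wxyz"),
        )
        # study {1, 2} vs reference {1, 2}: perfectly symmetric -> p = 0.5
        res = compare_centrality(rec, ["w", "x"], ["y", "z"], "degree", "greater")
        assert res.p == pytest.approx(0.5)

    def test_null_calibration_uniform(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=60)
        rec = pd.DataFrame(
            {"degree": values, "betweenness": 0.0, "aspl": 1.0, "evc": 0.5},
            index=[f"g{i}" for i in range(60)],
        )
        ps = []
        for _ in range(500):
            study = rng.choice(rec.index, size=15, replace=False)
            ref = [g for g in rec.index if g not in set(study)]
            ps.append(compare_centrality(rec, list(study), ref, "degree", "greater").p)
        ps = np.sort(ps)
        # Kolmogorov-Smirnov distance to U(0,1)
        ks = np.max(np.abs(ps - (np.arange(1, 501) - 0.5) / 500))
        assert ks < 0.08

    def test_empty_set_rejected(self, records):
        with pytest.raises(ValueError):
            compare_centrality(records, [], ["a"], "degree", "less")


class TestCentralityLogistic:
    def test_symmetric_case_zero_slope(self):
        rec = pd.DataFrame(
            {"evc": [1.0, 1.0, 2.0, 2.0], "degree": 1, "betweenness": 0, "aspl": 1},
            index=list("abcd"),
        )
        labels = pd.Series([0, 1, 0, 1], index=list("abcd"))
        fit = centrality_logistic(rec, labels, transform="identity")
        assert fit.coefficient == pytest.approx(0.0, abs=1e-6)

    def test_planted_slope_recovered(self):
        edges = simulate_network(1500, 3, seed=10)
        from promselnet.network import build_network, centralities, largest_component

        g = largest_component(build_network(edges))
        rec = centralities(g)
        beta1 = 2.0
        beta0 = intercept_for_prevalence(rec["evc"], beta1, "log", 0.1)
        labels = pd.Series(
            plant_labels(rec["evc"].to_numpy(), beta0, beta1, "log", seed=3),
            index=rec.index,
        )
        fit = centrality_logistic(rec, labels, transform="log")
        assert fit.coefficient > 0
        assert fit.p < 0.05
        assert fit.coefficient == pytest.approx(beta1, rel=0.5)

    def test_perfect_separation_flagged(self):
        rec = pd.DataFrame(
            {"evc": [0.1, 0.2, 0.8, 0.9], "degree": 1, "betweenness": 0, "aspl": 1},
            index=list("abcd"),
        )
        labels = pd.Series([0, 0, 1, 1], index=list("abcd"))
        fit = centrality_logistic(rec, labels, transform="identity")
        assert fit.separated
        assert not np.isfinite(fit.coefficient)


class TestQuantileBins:
    def test_forty_values_twenty_bins(self):
        bins = quantile_bins(np.arange(1, 41), np.zeros(40), k=20)
        assert len(bins) == 20
        assert (bins["n"] == 2).all()

    def test_all_negative_labels(self):
        bins = quantile_bins(np.arange(100), np.zeros(100), k=20)
        assert (bins["frequency"] == 0).all()

    def test_partition_of_counts(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=500)
        y = rng.integers(0, 2, size=500)
        bins = quantile_bins(v, y, k=20)
        assert bins["n"].sum() == 500
        assert (bins["frequency"] * bins["n"]).sum() == pytest.approx(y.sum())

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_bins([1, 1, 2, 2], [0, 1, 0, 1], k=3)


class TestTopCentralAndReference:
    @pytest.fixture
    def records(self):
        return pd.DataFrame(
            {
                "evc": [1.0, 0.8, 0.8, 0.2],
                "degree": [5, 7, 3, 1],
                "betweenness": 0.0,
                "aspl": 1.0,
            },
            index=["a", "b", "c", "d"],
        )

    def test_singleton(self, records):
        assert top_central(records, ["d"], k=10) == ["d"]

    def test_tie_broken_by_degree(self, records):
        assert top_central(records, ["b", "c", "d"], k=2) == ["b", "c"]

    def test_k_larger_than_set(self, records):
        assert set(top_central(records, ["a", "d"], k=10)) == {"a", "d"}

    def test_central_reference_strict(self, records):
        assert central_reference(records, 0.8) == {"a"}
        assert central_reference(records, 1.0) == set()
        assert central_reference(records, 0.0) == {"a", "b", "c", "d"}
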