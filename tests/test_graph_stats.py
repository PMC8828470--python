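"""Cluster-level graph statistics: enrichment, interaction matrix, centralities."""

import itertools

import networkx as nx
import numpy as np
import pytest

from spomics import (
    centrality_scores,
    group_betweenness,
    interaction_matrix,
    knn_graph,
    nhood_enrichment,
)
from tests.conftest import graph_from_edges, make_dataset


def two_cliques(size=10):
    """Two disjoint cliques labeled by clique membership."""
    edges = [(i, j) for i in range(size) for j in range(i + 1, size)]
    edges += [(i + size, j + size) for i, j in edges]
    labels = ["A"] * size + ["B"] * size
    coords = [(i, 0) for i in range(size)] + [(i, 10) for i in range(size)]
    return make_dataset(coords, labels), graph_from_edges(2 * size, edges)


class TestNhoodEnrichment:
    def test_segregated_cliques_sign_structure(self):
        ds, g = two_cliques()
        res = nhood_enrichment(ds, g, "cluster", n_perms=1000, seed=0)
        assert res.zscore[0, 0] > 0 and res.zscore[1, 1] > 0
        assert res.zscore[0, 1] < 0

    def test_matches_permutation_oracle(self):
        """z from a long independent permutation run agrees with the module."""
        ds, g = two_cliques(size=5)
        res = nhood_enrichment(ds, g, "cluster", n_perms=10000, seed=1)
        # independent oracle: explicit edge-list recount per permutation
        codes, _ = ds.label_codes("cluster")
        coo = g.connectivity.tocoo()
        edges = [(i, j) for i, j in zip(coo.row, coo.col) if i < j]

        def count(lab):
            x = np.zeros((2, 2))
            for i, j in edges:
                a, b = sorted((lab[i], lab[j]))
                x[a, b] += 1
            x[1, 0] = x[0, 1]
            return x

        rng = np.random.default_rng(99)
        sims = np.array([count(codes[rng.permutation(len(codes))]) for _ in range(10000)])
        mu, sd = sims.mean(axis=0), sims.std(axis=0)
        z_oracle = (count(codes) - mu) / sd
        np.testing.assert_allclose(res.zscore, z_oracle, atol=0.25)  # two MC estimates

    def test_single_label_degenerate(self):
        ds = make_dataset([(0, 0), (1, 0), (2, 0)], labels=["A", "A", "A"])
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        res = nhood_enrichment(ds, g, "cluster", n_perms=50, seed=0)
        assert res.zscore[0, 0] == 0
        assert ("A", "A") in res.zero_sigma_pairs

    def test_empty_graph_raises(self):
        ds = make_dataset([(0, 0), (5, 5)], labels=["A", "B"])
        g = graph_from_edges(2, [])
        with pytest.raises(ValueError, match="edge"):
            nhood_enrichment(ds, g, "cluster", n_perms=10, seed=0)

    def test_seed_reproducibility(self):
        ds, g = two_cliques(size=6)
        a = nhood_enrichment(ds, g, "cluster", n_perms=200, seed=7)
        b = nhood_enrichment(ds, g, "cluster", n_perms=200, seed=7)
        np.testing.assert_array_equal(a.zscore, b.zscore)

    def test_count_invariant_under_joint_relabeling(self):
        """Permuting nodes and labels together leaves the count matrix fixed."""
        ds, g = two_cliques(size=5)
        res = nhood_enrichment(ds, g, "cluster", n_perms=10, seed=0)
        rng = np.random.default_rng(3)
        perm = rng.permutation(10)
        import pandas as pd
        import scipy.sparse as spr

        conn = g.connectivity.toarray()[np.ix_(perm, perm)]
        dist = g.distances.toarray()[np.ix_(perm, perm)]
        from spomics import SpatialGraph

        g2 = SpatialGraph(spr.csr_matrix(conn), spr.csr_matrix(dist))
        labels = np.asarray(ds.labels["cluster"])[perm]
        ds2 = make_dataset(ds.coords[perm], labels)
        res2 = nhood_enrichment(ds2, g2, "cluster", n_perms=10, seed=0)
        np.testing.assert_array_equal(res.count, res2.count)

    def test_null_z_approximately_standard_normal(self):
        """Erdos-Renyi + random labels: empirical z has mean ~0, sd in [0.8, 1.2]."""
        rng = np.random.default_rng(0)
        zs = []
        for rep in range(10):
            G = nx.gnp_random_graph(100, 0.08, seed=rep)
            edges = list(G.edges)
            g = graph_from_edges(100, edges)
            ds = make_dataset(rng.random((100, 2)), rng.choice(["a", "b", "c"], 100))
            res = nhood_enrichment(ds, g, "cluster", n_perms=1000, seed=rep)
            zs.extend(res.zscore[np.triu_indices(3)])
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.1
        assert 0.8 <= zs.std() <= 1.2


class TestInteractionMatrix:
    def test_path_hand_enumeration(self):
        ds = make_dataset([(0, 0), (1, 0), (2, 0)], labels=["A", "B", "B"])
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        m = interaction_matrix(ds, g, "cluster")
        assert m.loc["A", "B"] == 1 and m.loc["B", "A"] == 1 and m.loc["B", "B"] == 2

    def test_normalized_rows_sum_to_one(self, random_dataset):
        g = knn_graph(random_dataset, 4)
        m = interaction_matrix(random_dataset, g, "cluster", normalized=True)
        sums = m.to_numpy().sum(axis=1)
        np.testing.assert_allclose(sums[sums > 0], 1.0, atol=1e-12)

    def test_total_is_twice_edge_count(self, random_dataset):
        g = knn_graph(random_dataset, 4)
        m = interaction_matrix(random_dataset, g, "cluster")
        assert m.to_numpy().sum() == 2 * g.n_edges


class TestCentralities:
    def test_star_center(self):
        """K_{1,3} with S = {center}: degree = closeness = 1."""
        ds = make_dataset([(0, 0), (1, 0), (0, 1), (-1, 0)], labels=["hub", "x", "x", "x"])
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        t = centrality_scores(ds, g, "cluster")
        assert t.loc["hub", "degree_centrality"] == 1.0
        assert t.loc["hub", "closeness_centrality"] == 1.0

    def test_triangle_clustering(self):
        ds = make_dataset([(0, 0), (1, 0), (0, 1)], labels=["s", "o", "o"])
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        t = centrality_scores(ds, g, "cluster")
        assert t.loc["s", "average_clustering"] == 1.0

    def test_whole_graph_cluster_flagged(self):
        ds = make_dataset([(0, 0), (1, 0)], labels=["all", "all"])
        g = graph_from_edges(2, [(0, 1)])
        t = centrality_scores(ds, g, "cluster")
        assert t.loc["all", "degree_centrality"] == 0.0
        assert bool(t.loc["all", "degenerate"])

    def test_path_betweenness(self):
        """a-b-c with S={b}: the single a-c shortest path passes through b."""
        ds = make_dataset([(0, 0), (1, 0), (2, 0)], labels=["x", "mid", "x"])
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        t = group_betweenness(ds, g, "cluster")
        assert t.loc["mid", "group_betweenness"] == 1.0

    def test_complete_graph_betweenness_zero(self):
        n = 5
        edges = list(itertools.combinations(range(n), 2))
        ds = make_dataset([(i, 0) for i in range(n)], labels=["s", "o", "o", "o", "o"])
        g = graph_from_edges(n, edges)
        t = group_betweenness(ds, g, "cluster")
        assert t.loc["s", "group_betweenness"] == 0.0

    def test_articulation_point_betweenness(self):
        """Two 3-node blobs joined through one node: hand count of path fractions."""
        # blob1: 0,1,2 (triangle); blob2: 4,5,6 (triangle); 3 bridges 2 and 4
        edges = [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5), (5, 6), (4, 6)]
        labels = ["o", "o", "o", "S", "o", "o", "o"]
        ds = make_dataset([(i, 0) for i in range(7)], labels)
        g = graph_from_edges(7, edges)
        t = group_betweenness(ds, g, "cluster")
        # every path between {0,1,2} and {4,5,6} crosses node 3: 3x3 = 9 pairs,
        # each with all shortest paths through S
        assert t.loc["S", "group_betweenness"] == 9.0

    @pytest.mark.parametrize("rep", range(3))
    def test_oracle_equality_on_random_graphs(self, rep):
        """Centralities equal an independent enumeration oracle (all-pairs BFS /
        explicit shortest-path listing) on random labeled graphs."""
        rng = np.random.default_rng(rep)
        G = nx.gnp_random_graph(18, 0.2, seed=rep + 50)
        edges = list(G.edges)
        labels = rng.choice(["a", "b", "c"], 18)
        ds = make_dataset(rng.random((18, 2)), labels)
        g = graph_from_edges(18, edges)
        t = centrality_scores(ds, g, "cluster").join(group_betweenness(ds, g, "cluster"))
        for cat in ("a", "b", "c"):
            S = set(np.flatnonzero(labels == cat).tolist())
            V = set(G.nodes)
            boundary = {v for u in S for v in G.neighbors(u)} - S
            assert t.loc[cat, "degree_centrality"] == pytest.approx(
                len(boundary) / len(V - S)
            )
            # closeness via per-node BFS oracle
            dists = dict(nx.all_pairs_shortest_path_length(G))
            d_sv = {}
            for v in V - S:
                reach = [dists[u][v] for u in S if v in dists[u]]
                if reach:
                    d_sv[v] = min(reach)
            expected_clos = len(d_sv) / sum(d_sv.values()) if d_sv else 0.0
            assert t.loc[cat, "closeness_centrality"] == pytest.approx(expected_clos)
            # clustering oracle
            cl = nx.clustering(G)
            expected_clust = sum(cl[v] for v in S) / len(S) if S else 0.0
            assert t.loc[cat, "average_clustering"] == pytest.approx(expected_clust)
            # betweenness via explicit shortest-path enumeration
            total = 0.0
            outside = sorted(V - S)
            for ui in range(len(outside)):
                for vi in range(ui + 1, len(outside)):
                    u, v = outside[ui], outside[vi]
                    if v not in dists[u]:
                        continue
                    paths = list(nx.all_shortest_paths(G, u, v))
                    through = sum(1 for p in paths if S & set(p))
                    total += through / len(paths)
            assert t.loc[cat, "group_betweenness"] == pytest.approx(total)

    def test_centralities_bounded(self, random_dataset):
        g = knn_graph(random_dataset, 4)
        t = centrality_scores(random_dataset, g, "cluster")
        for col in ("degree_centrality", "closeness_centrality", "average_clustering"):
            assert ((t[col] >= 0) & (t[col] <= 1)).all()
        b = group_betweenness(random_dataset, g, "cluster")
        assert (b["group_betweenness"] >= 0).all()
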