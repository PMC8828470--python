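"""Cluster-level statistics on spatial neighbor graphs.

* :func:`nhood_enrichment` — permutation z-score for over/under-represented
  adjacency between cluster pairs: the observed count of edges joining the two
  clusters is compared with its distribution under uniform reshuffling of the
  labels over the fixed graph, ``Z_ij = (x_ij - mu_ij) / sigma_ij``.
* :func:`interaction_matrix` — raw (or row-normalized) counts of ordered
  neighboring label pairs.
* :func:`centrality_scores` / :func:`group_betweenness` — group centrality
  measures (degree, closeness, average clustering, betweenness) per cluster,
  treating the graph as unweighted.

Edge-counting conventions
-------------------------
``nhood_enrichment`` counts each undirected edge once (including within-
cluster edges).  ``interaction_matrix`` counts ordered node pairs, so its
off-diagonal entries are twice the undirected count and its total is always
``2 |E|``.  Each convention matches the formula it implements; both are
stated here to avoid surprises when comparing the two outputs.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import SpatialDataset, SpatialGraph

__all__ = [
    "EnrichmentResult",
    "nhood_enrichment",
    "interaction_matrix",
    "centrality_scores",
    "group_betweenness",
]


@dataclasses.dataclass
class EnrichmentResult:
    """Neighborhood enrichment z-scores and their permutation null moments.

    ``zscore[i, j]`` is the deviation of the observed pair count
    ``count[i, j]`` from the permutation mean ``perm_mean[i, j]`` in units of
    the permutation standard deviation.  Pairs whose null is degenerate
    (sigma = 0) get z = 0 and are listed in ``zero_sigma_pairs``.
    """

    clusters: list
    zscore: np.ndarray
    count: np.ndarray
    perm_mean: np.ndarray
    perm_sd: np.ndarray
    n_perms: int
    seed: int
    zero_sigma_pairs: list[tuple] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.clusters)
        for name in ("zscore", "count", "perm_mean", "perm_sd"):
            m = getattr(self, name)
            if m.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
        if not np.allclose(self.count, self.count.T):
            raise ValueError("count matrix must be symmetric")
        if not np.allclose(self.zscore, self.zscore.T):
            raise ValueError("zscore matrix must be symmetric")
        if self.n_perms < 1:
            raise ValueError("n_perms must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per unordered cluster pair."""
        rows = []
        k = len(self.clusters)
        for i in range(k):
            for j in range(i, k):
                rows.append(
                    {
                        "cluster_1": self.clusters[i],
                        "cluster_2": self.clusters[j],
                        "count": self.count[i, j],
                        "zscore": self.zscore[i, j],
                        "perm_mean": self.perm_mean[i, j],
                        "perm_sd": self.perm_sd[i, j],
                    }
                )
        df = pd.DataFrame(rows)
        return df.set_index(df["cluster_1"].astype(str) + "|" + df["cluster_2"].astype(str))


def _pair_counts_exact(onehot: np.ndarray, A: sp.csr_matrix) -> np.ndarray:
    """Undirected-once counts: x_ij = #edges with one end in i, other in j.

    ``E = L^T A L`` counts ordered node pairs and is symmetric.  An i-j edge
    with i != j contributes once to E[i, j] and once to E[j, i], so the
    off-diagonal already holds undirected counts; a within-cluster edge
    contributes twice to E[i, i], so the diagonal is halved.
    """
    E = onehot.T @ (A @ onehot)
    X = np.asarray(E, dtype=float).copy()
    np.fill_diagonal(X, np.diag(X) / 2.0)
    return X


def nhood_enrichment(
    dataset: SpatialDataset,
    graph: SpatialGraph,
    label_key: str,
    n_perms: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test for cluster-pair adjacency enrichment.

    The observed statistic ``x_ij`` is the number of graph edges joining a
    cluster-i node to a cluster-j node, each undirected edge counted once
    (within-cluster edges likewise counted once).  The labels are then
    reshuffled uniformly ``n_perms`` times with the connectivity held fixed;
    the permutation mean and standard deviation give
    ``Z_ij = (x_ij - mu_ij) / sigma_ij``.

    A degenerate null (sigma = 0, e.g. a single unique label) yields z = 0
    for the affected pair, recorded in ``zero_sigma_pairs``.
    """
    codes, cats = dataset.label_codes(label_key)
    A = (graph.connectivity != 0).astype(float).tocsr()
    if A.nnz == 0:
        raise ValueError("graph has no edges")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    k = len(cats)
    n = len(codes)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), codes] = 1.0

    observed = _pair_counts_exact(onehot, A)

    rng = np.random.default_rng(seed)
    acc = np.zeros((k, k))
    acc2 = np.zeros((k, k))
    for _ in range(n_perms):
        perm = rng.permutation(n)
        Xp = _pair_counts_exact(onehot[perm], A)
        acc += Xp
        acc2 += Xp * Xp
    mu = acc / n_perms
    var = np.maximum(acc2 / n_perms - mu * mu, 0.0)
    sd = np.sqrt(var)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (observed - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    zero_pairs = [
        (cats[i], cats[j]) for i in range(k) for j in range(i, k) if sd[i, j] == 0
    ]
    z = (z + z.T) / 2  # numerically symmetric
    return EnrichmentResult(
        clusters=list(cats),
        zscore=z,
        count=observed,
        perm_mean=mu,
        perm_sd=sd,
        n_perms=n_perms,
        seed=seed,
        zero_sigma_pairs=zero_pairs,
    )


def interaction_matrix(
    dataset: SpatialDataset,
    graph: SpatialGraph,
    label_key: str,
    normalized: bool = False,
) -> pd.DataFrame:
    """Ordered-pair counts of neighboring labels.

    ``entry(i, j)`` sums over ordered node pairs (u, v) with an edge u~v,
    label(u) = i and label(v) = j, so the matrix is symmetric, its total is
    ``2 |E|``, and off-diagonal entries are twice the undirected edge count
    used by :func:`nhood_enrichment`.  With ``normalized=True`` each non-zero
    row is divided by its sum.
    """
    codes, cats = dataset.label_codes(label_key)
    A = (graph.connectivity != 0).astype(float).tocsr()
    k = len(cats)
    n = len(codes)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), codes] = 1.0
    E = onehot.T @ (A @ onehot)
    if normalized:
        rowsum = E.sum(axis=1, keepdims=True)
        E = np.divide(E, rowsum, out=np.zeros_like(E), where=rowsum > 0)
    return pd.DataFrame(E, index=cats, columns=cats)


def _to_nx(graph: SpatialGraph) -> nx.Graph:
    """Unweighted undirected networkx view of the connectivity pattern."""
    A = (graph.connectivity != 0).astype(int)
    return nx.from_scipy_sparse_array(A)


def centrality_scores(
    dataset: SpatialDataset,
    graph: SpatialGraph,
    label_key: str,
) -> pd.DataFrame:
    """Group degree centrality, group closeness centrality and average
    clustering coefficient per cluster.

    For a cluster S on graph G = (V, E), treated as unweighted:

    * degree:     ``|N(S) - S| / (|V| - |S|)`` — fraction of non-members
      adjacent to the cluster;
    * closeness:  ``|V - S| / sum_{v not in S} d(S, v)`` with ``d(S, v)`` the
      hop distance from v to the nearest cluster member; unreachable nodes
      are excluded from both numerator and denominator (0 if none reachable);
    * clustering: mean local clustering coefficient over cluster members
      (0 for members of degree < 2).

    A cluster equal to all of V has no non-members; its degree and closeness
    are reported as 0 and flagged in the ``degenerate`` column.
    """
    codes, cats = dataset.label_codes(label_key)
    G = _to_nx(graph)
    nV = G.number_of_nodes()
    clustering = nx.clustering(G)
    rows = []
    for ci, cat in enumerate(cats):
        members = set(np.flatnonzero(codes == ci).tolist())
        non_members = set(range(nV)) - members
        degenerate = len(non_members) == 0
        if degenerate:
            c_deg = 0.0
            c_clos = 0.0
        else:
            boundary = {v for u in members for v in G.neighbors(u)} - members
            c_deg = len(boundary) / len(non_members)
            dist = nx.multi_source_dijkstra_path_length(G, members, weight=None) if members else {}
            reach = [v for v in non_members if v in dist]
            c_clos = len(reach) / sum(dist[v] for v in reach) if reach else 0.0
        c_clust = (
            sum(clustering[v] for v in members) / len(members) if members else 0.0
        )
        rows.append(
            {
                "cluster": cat,
                "degree_centrality": c_deg,
                "closeness_centrality": c_clos,
                "average_clustering": c_clust,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def group_betweenness(
    dataset: SpatialDataset,
    graph: SpatialGraph,
    label_key: str,
) -> pd.DataFrame:
    """Group betweenness per cluster: the summed proportion of shortest paths
    between non-member pairs that pass through the cluster.

    For each pair u < v outside S with ``g_uv`` shortest paths in G, the
    number passing through S is ``g_uv - g'_uv`` where ``g'_uv`` counts
    shortest paths of the *same length* in G with S removed (a shortest path
    avoids S exactly when it survives the deletion at unchanged length).
    Disconnected pairs are skipped.  Hop distances only; stored edge weights
    are ignored.
    """
    codes, cats = dataset.label_codes(label_key)
    G = _to_nx(graph)
    rows = []
    for ci, cat in enumerate(cats):
        members = set(np.flatnonzero(codes == ci).tolist())
        others = sorted(set(G.nodes) - members)
        H = G.subgraph(others)
        total = 0.0
        # single-source shortest-path counts from every non-member
        for idx, u in enumerate(others):
            dist_g, sig_g = _sp_counts(G, u)
            dist_h, sig_h = _sp_counts(H, u)
            for v in others[idx + 1 :]:
                g_uv = sig_g.get(v, 0.0)
                if g_uv == 0:
                    continue  # disconnected in G
                g_avoid = sig_h.get(v, 0.0) if dist_h.get(v) == dist_g[v] else 0.0
                total += (g_uv - g_avoid) / g_uv
        rows.append({"cluster": cat, "group_betweenness": total})
    return pd.DataFrame(rows).set_index("cluster")


def _sp_counts(G: nx.Graph, source) -> tuple[dict, dict]:
    """BFS shortest-path distances and path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1.0}
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            for v in G.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0.0
                    nxt.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        queue = nxt
    return dist, sigma
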