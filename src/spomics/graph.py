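"""Spatial neighbor graph construction.

Four modalities cover the common spatial-omics layouts:

* :func:`grid_graph` — lattice data (Visium-style hexagonal or square grids),
  with neighborhoods expressed as rings of spots and connectivity weights
  equal to the ring ordinal.
* :func:`knn_graph` — k-nearest neighbors for dissociated coordinates
  (seqFISH / MERFISH-style), symmetrized by union.
* :func:`radius_graph` — all pairs within a fixed Euclidean radius.
* :func:`delaunay_graph` — Delaunay triangulation edges.

All constructors return a :class:`~spomics.datamodel.SpatialGraph` with
symmetric connectivity and Euclidean distance matrices and a zero diagonal.
:func:`transform_graph` provides the spectral and cosine adjacency
transformations used by graph convolutional methods.
"""

from __future__ import annotations

import warnings
from collections import deque

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial.distance import pdist, squareform

from .datamodel import SpatialDataset, SpatialGraph

__all__ = [
    "grid_graph",
    "knn_graph",
    "radius_graph",
    "delaunay_graph",
    "transform_graph",
    "LatticeStructureError",
]


class LatticeStructureError(ValueError):
    """Coordinates do not form the requested regular lattice."""


def _pairwise(coords: np.ndarray) -> np.ndarray:
    return squareform(pdist(coords))


def _euclidean_distances_for(coords: np.ndarray, conn: sp.csr_matrix) -> sp.csr_matrix:
    """Distance matrix on the sparsity pattern of ``conn``."""
    conn = conn.tocoo()
    d = np.linalg.norm(coords[conn.row] - coords[conn.col], axis=1)
    return sp.csr_matrix((d, (conn.row, conn.col)), shape=conn.shape)


def grid_graph(dataset: SpatialDataset, n_neigh: int = 6, n_rings: int = 1) -> SpatialGraph:
    """Neighbor graph for lattice coordinates with ring-ordinal weights.

    Parameters
    ----------
    n_neigh
        6 for a triangular (hexagonal-neighborhood) lattice, 4 for a square
        lattice.
    n_rings
        How many rings of spots around each spot count as neighbors;
        ``connectivity[i, j]`` is the ring ordinal (1..n_rings) of j around i.

    The lattice pitch is inferred as the modal nearest-neighbor distance; a
    point's first ring is every point at that pitch (within 10% tolerance).
    Ring ordinals beyond 1 are hop distances on the first-ring graph
    (breadth-first expansion), which is robust to mild lattice distortion.
    """
    if n_neigh not in (4, 6):
        raise ValueError("n_neigh must be 4 (square) or 6 (hexagonal lattice)")
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    coords = dataset.coords
    n = coords.shape[0]
    if n < 2:
        raise LatticeStructureError("need at least 2 points for a grid graph")

    tree = cKDTree(coords)
    nn_d, _ = tree.query(coords, k=2)
    nn_d = nn_d[:, 1]
    # modal nearest-neighbor distance = lattice pitch (mode of values rounded
    # to 6 significant digits to absorb float noise)
    rounded = np.round(nn_d / np.median(nn_d), 6)
    vals, counts = np.unique(rounded, return_counts=True)
    pitch = vals[np.argmax(counts)] * np.median(nn_d)
    tol = 0.1 * pitch

    pairs = tree.query_pairs(pitch + tol, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        keep = np.abs(d - pitch) <= tol
        pairs = pairs[keep]
    ring1: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        ring1[i].append(j)
        ring1[j].append(i)

    isolated = sum(1 for nb in ring1 if not nb)
    if isolated > 0.05 * n:
        raise LatticeStructureError(
            f"{isolated}/{n} points have no neighbor at the inferred lattice pitch "
            f"{pitch:.4g}; coordinates are not lattice-like — use a generic graph "
            "(knn_graph / radius_graph / delaunay_graph) instead"
        )
    max_deg = max(len(nb) for nb in ring1)
    if max_deg > n_neigh:
        raise LatticeStructureError(
            f"found points with {max_deg} first-ring neighbors, inconsistent with "
            f"n_neigh={n_neigh}; check the lattice type"
        )

    rows, cols, ring_w = [], [], []
    for src in range(n):
        # BFS on the ring-1 graph up to n_rings hops
        ring_of = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            r = ring_of[u]
            if r == n_rings:
                continue
            for v in ring1[u]:
                if v not in ring_of:
                    ring_of[v] = r + 1
                    q.append(v)
        for v, r in ring_of.items():
            if v != src:
                rows.append(src)
                cols.append(v)
                ring_w.append(r)

    # hop distance on an undirected graph is symmetric, so conn is symmetric
    conn = sp.csr_matrix((np.array(ring_w, dtype=float), (rows, cols)), shape=(n, n))
    dist = _euclidean_distances_for(coords, conn)
    return SpatialGraph(
        connectivity=conn,
        distances=dist,
        coord_type="grid",
        meta={"n_neigh": n_neigh, "n_rings": n_rings, "pitch": float(pitch)},
    )


def knn_graph(dataset: SpatialDataset, n_neigh: int) -> SpatialGraph:
    """k-nearest-neighbor graph, symmetrized by union of the directed relation.

    Self-neighbors are excluded; distance ties are broken toward the lower
    observation index.  Duplicate coordinates would produce zero-distance
    edges, which the sparse representation cannot hold; such distances are
    stored as machine epsilon with a warning.
    """
    coords = dataset.coords
    n = coords.shape[0]
    if not 1 <= n_neigh < n:
        raise ValueError(f"n_neigh must be in [1, n_obs-1]={n - 1}, got {n_neigh}")

    D = _pairwise(coords)
    np.fill_diagonal(D, np.inf)
    # stable argsort on distance breaks ties toward the lower index
    order = np.argsort(D, axis=1, kind="stable")[:, :n_neigh]

    rows = np.repeat(np.arange(n), n_neigh)
    cols = order.ravel()
    adj = np.zeros((n, n), dtype=bool)
    adj[rows, cols] = True
    adj |= adj.T  # union symmetrization

    r, c = np.nonzero(adj)
    d = D[r, c]
    if np.any(d == 0):
        warnings.warn(
            "duplicate coordinates produce zero-distance edges; storing machine epsilon",
            stacklevel=2,
        )
        d = np.where(d == 0, np.finfo(float).eps, d)
    conn = sp.csr_matrix((np.ones_like(d), (r, c)), shape=(n, n))
    dist = sp.csr_matrix((d, (r, c)), shape=(n, n))
    return SpatialGraph(conn, dist, coord_type="generic", meta={"n_neigh": n_neigh})


def radius_graph(dataset: SpatialDataset, radius: float) -> SpatialGraph:
    """Graph joining every pair at Euclidean distance in (0, radius]."""
    if not np.isfinite(radius) or radius <= 0:
        raise ValueError(f"radius must be a positive finite number, got {radius}")
    coords = dataset.coords
    n = coords.shape[0]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        keep = d > 0  # coincident points are not neighbors of themselves
        pairs, d = pairs[keep], d[keep]
    else:
        d = np.empty(0)
    r = np.concatenate([pairs[:, 0], pairs[:, 1]]) if pairs.size else np.empty(0, int)
    c = np.concatenate([pairs[:, 1], pairs[:, 0]]) if pairs.size else np.empty(0, int)
    dd = np.concatenate([d, d])
    conn = sp.csr_matrix((np.ones_like(dd), (r, c)), shape=(n, n))
    dist = sp.csr_matrix((dd, (r, c)), shape=(n, n))
    return SpatialGraph(conn, dist, coord_type="generic", meta={"radius": float(radius)})


def delaunay_graph(dataset: SpatialDataset) -> SpatialGraph:
    """Graph whose edges are the Delaunay triangulation of the coordinates."""
    coords = dataset.coords
    n = coords.shape[0]
    if n < 3:
        raise ValueError("Delaunay triangulation needs at least 3 points")
    try:
        tri = Delaunay(coords)
    except Exception as exc:  # qhull raises its own error type on degeneracy
        raise ValueError(f"Delaunay triangulation failed (degenerate input?): {exc}") from exc
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    r = np.array([e[0] for e in edges] + [e[1] for e in edges])
    c = np.array([e[1] for e in edges] + [e[0] for e in edges])
    d = np.linalg.norm(coords[r] - coords[c], axis=1)
    conn = sp.csr_matrix((np.ones_like(d), (r, c)), shape=(n, n))
    dist = sp.csr_matrix((d, (r, c)), shape=(n, n))
    return SpatialGraph(conn, dist, coord_type="generic", meta={"delaunay": True})


def transform_graph(graph: SpatialGraph, mode: str) -> SpatialGraph:
    """Spectral or cosine transformation of the adjacency matrix.

    ``spectral`` computes ``D^{-1/2} A D^{-1/2}`` with D the degree diagonal
    (isolated nodes keep zero rows).  ``cosine`` computes the cosine
    similarity of adjacency rows, restricted to the original sparsity pattern
    with the diagonal removed.
    """
    A = graph.connectivity.tocsr().astype(float)
    if mode == "spectral":
        deg = np.asarray(A.sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
        Dhalf = sp.diags(inv_sqrt)
        out = (Dhalf @ A @ Dhalf).tocsr()
    elif mode == "cosine":
        norms = np.sqrt(np.asarray(A.multiply(A).sum(axis=1)).ravel())
        gram = (A @ A.T).tocoo()
        pattern = A.tocoo()
        gram_lookup = {(i, j): v for i, j, v in zip(gram.row, gram.col, gram.data)}
        rows, cols, vals = [], [], []
        for i, j in zip(pattern.row, pattern.col):
            if i == j:
                continue
            denom = norms[i] * norms[j]
            v = gram_lookup.get((i, j), 0.0) / denom if denom > 0 else 0.0
            rows.append(i)
            cols.append(j)
            vals.append(v)
        out = sp.csr_matrix((vals, (rows, cols)), shape=A.shape)
    else:
        raise ValueError(f"mode must be 'spectral' or 'cosine', got {mode!r}")
    return SpatialGraph(
        connectivity=out,
        distances=graph.distances.copy(),
        coord_type="generic",
        meta={**graph.meta, "transform": mode},
    )
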