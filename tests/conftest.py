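import numpy as np
import pandas as pd
import pytest
import scipy.sparse as spr

from spomics import SimulationSpec, SpatialDataset, SpatialGraph, simulate_points


@pytest.fixture
def hex_dataset():
    """10x10 hexagonal lattice with planted spatial expression."""
    return simulate_points(
        SimulationSpec(
            n_points=100,
            pattern="lattice",
            lattice_kind="hex",
            pitch=1.0,
            expression_model="planted-spatial",
            n_genes=5,
            n_spatial_genes=2,
            seed=11,
        )
    )


@pytest.fixture
def square_dataset():
    return simulate_points(
        SimulationSpec(
            n_points=100, pattern="lattice", lattice_kind="square", pitch=1.0, seed=12
        )
    )


@pytest.fixture
def random_dataset():
    """200 uniform points, 3 random clusters, noise expression."""
    return simulate_points(SimulationSpec(n_points=200, n_labels=3, n_genes=8, seed=13))


def make_dataset(coords, labels=None, X=None, label_key="cluster"):
    """Hand-built dataset from raw arrays (labels optional)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if X is None:
        X = np.zeros((n, 1))
    lab = {}
    if labels is not None:
        lab[label_key] = pd.Categorical([str(v) for v in labels])
    return SpatialDataset(
        X=np.asarray(X, dtype=float),
        obs_ids=np.array([f"o{i}" for i in range(n)], dtype=object),
        var_ids=np.array([f"g{j}" for j in range(np.asarray(X).shape[1])], dtype=object),
        coords=coords,
        labels=lab,
    )


def graph_from_edges(n, edges, coords=None):
    """Unweighted SpatialGraph from an undirected edge list (unit distances)."""
    rows, cols = [], []
    for i, j in edges:
        rows += [i, j]
        cols += [j, i]
    conn = spr.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    if coords is not None:
        coords = np.asarray(coords, dtype=float)
        d = np.linalg.norm(coords[rows] - coords[cols], axis=1)
        d[d == 0] = 1.0
    else:
        d = np.ones(len(rows))
    dist = spr.csr_matrix((d, (rows, cols)), shape=(n, n))
    return SpatialGraph(conn, dist, coord_type="generic")
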