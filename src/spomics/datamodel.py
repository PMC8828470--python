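"""Core containers tying expression, coordinates, labels, graphs and images together.

The central object is :class:`SpatialDataset`: an obs x gene expression matrix
plus per-observation 2-D coordinates and categorical labels.  Spatial neighbor
graphs (:class:`SpatialGraph`) and derived per-observation matrices (e.g. image
features) attach to it by key.  All statistics in this package read from these
two types.

Conventions
-----------
* Observation order is the coordinate-file order; every matrix is re-indexed
  to it on read.
* Coordinates are dimensionless Euclidean; ``x`` is horizontal and ``y``
  vertical.  When relating to images, ``(x, y)`` maps to ``(column, row)`` of
  pixel arrays with a top-left, 0-based origin.
* Sparse graph matrices use structural zeros for "no edge"; an explicit stored
  zero is never a valid edge weight.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpatialDataset",
    "SpatialGraph",
    "InteractionTable",
    "StatResult",
    "AlignmentError",
    "read_dataset",
    "write_dataset",
    "write_result",
    "read_result",
]


class AlignmentError(ValueError):
    """Observation ids do not line up across input files."""


@dataclasses.dataclass
class SpatialGraph:
    """Sparse symmetric spatial neighbor graph over observations.

    Parameters
    ----------
    connectivity
        Symmetric non-negative obs x obs sparse matrix with zero diagonal.
        For ``coord_type="grid"`` entries are ring ordinals (1, 2, ...);
        otherwise they are binary adjacency indicators or transformed weights.
    distances
        Euclidean distances on the same sparsity pattern; every stored
        distance is positive.
    coord_type
        ``"grid"`` for lattice graphs with ring weights, ``"generic"`` for
        kNN / radius / Delaunay graphs.
    meta
        Construction parameters (``n_neigh``, ``n_rings``, ``radius``,
        ``delaunay``...), kept for provenance.
    """

    connectivity: sp.csr_matrix
    distances: sp.csr_matrix
    coord_type: str = "generic"
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.connectivity = sp.csr_matrix(self.connectivity)
        self.distances = sp.csr_matrix(self.distances)
        self.validate()

    @property
    def n_obs(self) -> int:
        return self.connectivity.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return self.connectivity.nnz // 2

    def validate(self) -> None:
        c, d = self.connectivity, self.distances
        if c.shape != d.shape or c.shape[0] != c.shape[1]:
            raise ValueError("connectivity and distances must be square and congruent")
        if (abs(c - c.T) > 1e-10 * max(1.0, abs(c).max() if c.nnz else 1.0)).nnz:
            raise ValueError("connectivity matrix is not symmetric")
        if (abs(d - d.T) > 1e-10 * max(1.0, abs(d).max() if d.nnz else 1.0)).nnz:
            raise ValueError("distance matrix is not symmetric")
        if c.diagonal().any() or d.diagonal().any():
            raise ValueError("graph matrices must have zero diagonal")
        if d.nnz and d.data.min() <= 0:
            raise ValueError("stored distances must be positive")
        if c.nnz and c.data.min() < 0:
            raise ValueError("connectivity weights must be non-negative")
        if self.coord_type == "grid" and c.nnz:
            w = c.data
            if not np.allclose(w, np.round(w)) or w.min() < 1:
                raise ValueError("grid connectivity entries must be positive integers (ring ordinals)")


@dataclasses.dataclass
class SpatialDataset:
    """Expression matrix with per-observation coordinates and annotations.

    Attributes
    ----------
    X
        obs x gene matrix, dense ``ndarray`` or scipy sparse.
    obs_ids, var_ids
        Unique observation / gene identifiers.
    coords
        obs x 2 array of (x, y) positions in one consistent length unit.
    labels
        label-key -> per-observation categorical vector.
    graphs
        graph-key -> :class:`SpatialGraph`.
    obsm
        key -> obs x k numeric matrix (e.g. image features).
    """

    X: np.ndarray | sp.spmatrix
    obs_ids: np.ndarray
    var_ids: np.ndarray
    coords: np.ndarray
    labels: dict[str, pd.Categorical] = dataclasses.field(default_factory=dict)
    graphs: dict[str, SpatialGraph] = dataclasses.field(default_factory=dict)
    obsm: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.obs_ids = np.asarray(self.obs_ids, dtype=object)
        self.var_ids = np.asarray(self.var_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    @property
    def n_vars(self) -> int:
        return len(self.var_ids)

    def validate(self) -> None:
        n = self.X.shape[0]
        if len(self.obs_ids) != n:
            raise ValueError(f"{len(self.obs_ids)} obs_ids for {n} matrix rows")
        if self.X.shape[1] != len(self.var_ids):
            raise ValueError(f"{len(self.var_ids)} var_ids for {self.X.shape[1]} matrix columns")
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords must be ({n}, 2), got {self.coords.shape}")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if len(set(self.obs_ids)) != n:
            raise ValueError("obs_ids are not unique")
        if len(set(self.var_ids)) != len(self.var_ids):
            raise ValueError("var_ids are not unique")
        for key, vec in self.labels.items():
            if len(vec) != n:
                raise ValueError(f"label vector {key!r} has length {len(vec)} != n_obs {n}")

    def dense_X(self) -> np.ndarray:
        return self.X.toarray() if sp.issparse(self.X) else np.asarray(self.X)

    def gene_vector(self, gene: str) -> np.ndarray:
        """Expression of one gene across observations as a dense 1-D float array."""
        idx = np.flatnonzero(self.var_ids == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not in var_ids")
        col = self.X[:, idx[0]]
        return np.asarray(col.todense()).ravel() if sp.issparse(col) else np.asarray(col, dtype=float).ravel()

    def add_graph(self, key: str, graph: SpatialGraph) -> None:
        if graph.n_obs != self.n_obs:
            raise ValueError("graph size does not match dataset n_obs")
        graph.validate()
        self.graphs[key] = graph

    def label_codes(self, label_key: str) -> tuple[np.ndarray, list]:
        """Integer codes and category list for a label key."""
        if label_key not in self.labels:
            raise KeyError(f"label key {label_key!r} not present; have {sorted(self.labels)}")
        cat = self.labels[label_key]
        return np.asarray(cat.codes), list(cat.categories)


@dataclasses.dataclass
class InteractionTable:
    """Ligand-receptor interaction list with multi-subunit complex support.

    Each row is (source complex, target complex); a complex is an ordered
    tuple of one or more gene ids, parsed from underscore-joined strings
    (``"L1_L2"`` -> ``("L1", "L2")``).
    """

    sources: list[tuple[str, ...]]
    targets: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.sources) != len(self.targets):
            raise ValueError("sources and targets must have equal length")
        seen = set()
        src, tgt = [], []
        for s, t in zip(self.sources, self.targets):
            s, t = tuple(s), tuple(t)
            for g in s + t:
                if not isinstance(g, str) or not g:
                    raise ValueError(f"invalid gene id {g!r} in interaction {s}->{t}")
            if (s, t) not in seen:
                seen.add((s, t))
                src.append(s)
                tgt.append(t)
        self.sources, self.targets = src, tgt

    def __len__(self) -> int:
        return len(self.sources)

    def __iter__(self):
        return iter(zip(self.sources, self.targets))

    @staticmethod
    def parse_complex(spec: str) -> tuple[str, ...]:
        parts = tuple(p for p in str(spec).split("_"))
        if any(not p for p in parts):
            raise ValueError(f"malformed complex spec {spec!r}")
        return parts

    def labels(self) -> list[tuple[str, str]]:
        """Underscore-joined (source, target) string labels, one per interaction."""
        return [("_".join(s), "_".join(t)) for s, t in self]


@dataclasses.dataclass
class StatResult:
    """Generic per-index statistics table (scores, p-values, permutation info).

    ``table`` is indexed by cluster pair, cluster or gene and holds one column
    per defined field; p-value columns are in [0, 1] where defined (NaN
    otherwise).  This is the common on-disk currency of every test in the
    package.
    """

    table: pd.DataFrame
    n_perms: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for col in self.table.columns:
            if col.startswith("pvalue"):
                vals = self.table[col].to_numpy(dtype=float)
                ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
                if not ok.all():
                    raise ValueError(f"column {col!r} has p-values outside [0, 1]")
        if {"pvalue", "pvalue_adj"} <= set(self.table.columns):
            p = self.table["pvalue"].to_numpy(dtype=float)
            q = self.table["pvalue_adj"].to_numpy(dtype=float)
            both = ~np.isnan(p) & ~np.isnan(q)
            if np.any(q[both] < p[both] - 1e-12):
                raise ValueError("pvalue_adj must be >= pvalue where both are defined")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_expression(expr_path: Path) -> tuple[np.ndarray | sp.spmatrix, np.ndarray, np.ndarray]:
    """Read MTX (+ barcodes.tsv/genes.tsv sidecars) or CSV expression."""
    expr_path = Path(expr_path)
    if expr_path.suffix.lower() == ".mtx":
        X = scipy.io.mmread(expr_path).tocsr()
        folder = expr_path.parent
        barcodes = folder / "barcodes.tsv"
        genes = folder / "genes.tsv"
        if not barcodes.exists() or not genes.exists():
            raise FileNotFoundError(
                f"MTX input requires sidecars {barcodes} and {genes} with obs and gene ids"
            )
        obs_ids = pd.read_csv(barcodes, header=None, sep="\t")[0].astype(str).to_numpy()
        var_ids = pd.read_csv(genes, header=None, sep="\t")[0].astype(str).to_numpy()
        return X, obs_ids, var_ids
    df = pd.read_csv(expr_path, index_col=0)
    try:
        X = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values in {expr_path}: {exc}") from exc
    return X, df.index.astype(str).to_numpy(), df.columns.astype(str).to_numpy()


def read_dataset(
    expr_path: str | Path,
    coords_path: str | Path,
    labels_path: str | Path | None = None,
) -> SpatialDataset:
    """Read a dataset from an expression matrix, a coordinates table and labels.

    Parameters
    ----------
    expr_path
        MTX file (with ``barcodes.tsv`` / ``genes.tsv`` sidecars in the same
        folder) or a CSV with gene ids in the header row and obs ids in the
        first column.
    coords_path
        CSV with columns ``obs_id,x,y`` (extra coordinate columns are ignored).
    labels_path
        Optional CSV with ``obs_id`` plus one column per label key.

    Observations are ordered as in the coordinates file; expression and label
    rows are re-indexed to that order by ``obs_id``.
    """
    X, obs_ids, var_ids = _read_expression(Path(expr_path))
    coords_df = pd.read_csv(coords_path, comment="#")
    if "obs_id" not in coords_df.columns or not {"x", "y"} <= set(coords_df.columns):
        raise ValueError(f"coordinates file {coords_path} must have columns obs_id,x,y")
    coords_df["obs_id"] = coords_df["obs_id"].astype(str)

    order = coords_df["obs_id"].to_numpy()
    expr_pos = {o: i for i, o in enumerate(obs_ids)}
    missing = [o for o in order if o not in expr_pos]
    extra = sorted(set(obs_ids) - set(order))
    if missing or extra:
        raise AlignmentError(
            f"obs_id mismatch between {expr_path} and {coords_path}: "
            f"missing from expression: {missing[:10]}; missing from coords: {extra[:10]}"
        )
    perm = np.array([expr_pos[o] for o in order])
    X = X[perm]
    try:
        coords = coords_df[["x", "y"]].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric coordinates in {coords_path}: {exc}") from exc

    labels: dict[str, pd.Categorical] = {}
    if labels_path is not None:
        lab_df = pd.read_csv(labels_path, comment="#")
        if "obs_id" not in lab_df.columns:
            raise ValueError(f"labels file {labels_path} must have an obs_id column")
        lab_df["obs_id"] = lab_df["obs_id"].astype(str)
        lab_pos = {o: i for i, o in enumerate(lab_df["obs_id"])}
        missing = [o for o in order if o not in lab_pos]
        if missing:
            raise AlignmentError(f"obs ids missing from {labels_path}: {missing[:10]}")
        lperm = np.array([lab_pos[o] for o in order])
        for col in lab_df.columns:
            if col != "obs_id":
                labels[col] = pd.Categorical(lab_df[col].astype(str).to_numpy()[lperm])

    return SpatialDataset(X=X, obs_ids=order, var_ids=var_ids, coords=coords, labels=labels)


def write_dataset(dataset: SpatialDataset, prefix: str | Path) -> dict[str, Path]:
    """Write a dataset as ``<prefix>.expr.csv``, ``<prefix>.coords.csv`` and
    (if labels exist) ``<prefix>.labels.csv``; returns the written paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    expr = pd.DataFrame(dataset.dense_X(), index=dataset.obs_ids, columns=dataset.var_ids)
    paths["expr"] = prefix.with_suffix(".expr.csv")
    expr.to_csv(paths["expr"], index_label="obs_id")
    coords = pd.DataFrame(
        {"obs_id": dataset.obs_ids, "x": dataset.coords[:, 0], "y": dataset.coords[:, 1]}
    )
    paths["coords"] = prefix.with_suffix(".coords.csv")
    coords.to_csv(paths["coords"], index=False)
    if dataset.labels:
        lab = pd.DataFrame({"obs_id": dataset.obs_ids})
        for key, vec in dataset.labels.items():
            lab[key] = np.asarray(vec)
        paths["labels"] = prefix.with_suffix(".labels.csv")
        lab.to_csv(paths["labels"], index=False)
    return paths


def write_result(result: StatResult, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write a :class:`StatResult` as CSV, one row per index.

    Undefined (NaN) p-values become empty cells.  Floats are written with 17
    significant digits so a read-back reproduces values to full double
    precision.  ``header_lines`` are prepended as ``#`` comments (provenance).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    result.table.to_csv(buf, index_label=result.table.index.name or "index", float_format="%.17g")
    path.write_text(buf.getvalue())


def read_result(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_result` (comment headers skipped)."""
    return pd.read_csv(path, comment="#", index_col=0)
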