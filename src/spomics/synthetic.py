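"""Synthetic spatial-omics data generators.

These produce every input the statistics need — point patterns, cluster
labels, expression matrices with planted spatial or ligand-receptor
structure, and blob images with known ground truth — as pure functions of a
:class:`SimulationSpec` (seed included), so tests and examples are fully
reproducible without any downloads.

Patterns
--------
* ``poisson`` — homogeneous Poisson (complete spatial randomness): uniform
  points in the window.
* ``clustered`` — Thomas process: Poisson parents with Gaussian-scattered
  offspring, the standard clustered alternative for point-pattern tests.
* ``lattice`` — hexagonal (triangular) or square grid with a fixed pitch,
  emulating array-based spatial transcriptomics layouts.

Label models: uniform random with given proportions, or spatial blocks
(vertical strips), which create genuine label-space structure.  Expression
models: i.i.d. noise, noise plus block-elevated "spatially variable" genes,
or noise plus cluster-restricted ligand/receptor pairs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datamodel import SpatialDataset
from .imagekit import ImageStore

__all__ = ["SimulationSpec", "simulate_points", "simulate_blob_image"]


@dataclasses.dataclass
class SimulationSpec:
    """Declarative description of one synthetic dataset.

    Parameters
    ----------
    n_points
        Target number of observations (exact for poisson/lattice; the Thomas
        process hits it exactly by resampling offspring counts).
    window
        (width, height) of the observation window, origin at (0, 0).
    pattern
        "poisson", "clustered" or "lattice".
    lattice_kind, pitch, parent_rate, offspring_sd
        Pattern-specific knobs: lattice type and spacing; Thomas parent
        intensity (parents per unit area) and offspring scatter.
    label_model
        "random" (uniform with ``proportions``) or "blocks" (k vertical
        strips of equal width).
    n_labels, proportions
        Number of label levels and (for "random") their probabilities.
    expression_model
        "noise", "planted-spatial" or "planted-ligrec".
    n_genes, noise_sd
        Matrix width and the i.i.d. Gaussian noise level (truncated at 0 so
        expression stays non-negative).
    n_spatial_genes, block_effect
        For "planted-spatial": how many genes are elevated by
        ``block_effect`` inside the first spatial block.
    ligrec_pairs, ligrec_effect
        For "planted-ligrec": list of (ligand gene index, receptor gene
        index, sender label, receiver label); each ligand is elevated in its
        sender cluster and each receptor in its receiver cluster.
    seed
        Mandatory; every random draw flows from it.
    """

    n_points: int = 200
    window: tuple[float, float] = (100.0, 100.0)
    pattern: str = "poisson"
    lattice_kind: str = "hex"
    pitch: float = 1.0
    parent_rate: float = 0.002
    offspring_sd: float = 2.0
    label_model: str = "random"
    n_labels: int = 3
    proportions: tuple[float, ...] | None = None
    expression_model: str = "noise"
    n_genes: int = 20
    noise_sd: float = 1.0
    n_spatial_genes: int = 3
    block_effect: float = 3.0
    ligrec_pairs: tuple = ()
    ligrec_effect: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points <= 0 or self.pitch <= 0 or self.parent_rate <= 0:
            raise ValueError("sizes and rates must be positive")
        if self.offspring_sd <= 0 or self.noise_sd < 0 or self.n_labels < 1:
            raise ValueError("invalid noise/label parameters")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _poisson_points(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    w, h = spec.window
    return rng.random((spec.n_points, 2)) * np.array([w, h])


def _thomas_points(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Thomas process conditioned on the total point count."""
    w, h = spec.window
    n_parents = max(1, rng.poisson(spec.parent_rate * w * h))
    parents = rng.random((n_parents, 2)) * np.array([w, h])
    assignment = rng.integers(0, n_parents, size=spec.n_points)
    pts = parents[assignment] + rng.normal(0, spec.offspring_sd, size=(spec.n_points, 2))
    return np.clip(pts, [0, 0], [w, h])


def _lattice_points(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Grid of ~n_points sites with the requested pitch; hex rows are offset."""
    side = int(np.ceil(np.sqrt(spec.n_points)))
    pts = []
    for r in range(side):
        for c in range(side):
            if spec.lattice_kind == "hex":
                x = c * spec.pitch + (r % 2) * spec.pitch / 2.0
                y = r * spec.pitch * np.sqrt(3) / 2.0
            else:
                x = c * spec.pitch
                y = r * spec.pitch
            pts.append((x, y))
    return np.array(pts[: spec.n_points], dtype=float)


def _labels(spec: SimulationSpec, coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    k = spec.n_labels
    if spec.label_model == "random":
        p = spec.proportions if spec.proportions is not None else np.full(k, 1.0 / k)
        p = np.asarray(p, dtype=float)
        p = p / p.sum()
        return rng.choice(k, size=len(coords), p=p)
    if spec.label_model == "blocks":
        # k vertical strips of equal width across the occupied x-range
        x = coords[:, 0]
        edges = np.linspace(x.min(), x.max() + 1e-9, k + 1)
        return np.clip(np.searchsorted(edges, x, side="right") - 1, 0, k - 1)
    raise ValueError(f"unknown label model {spec.label_model!r}")


def _expression(
    spec: SimulationSpec, coords: np.ndarray, labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = len(coords)
    X = np.maximum(rng.normal(1.0, spec.noise_sd, size=(n, spec.n_genes)), 0.0)
    if spec.expression_model == "noise":
        return X
    if spec.expression_model == "planted-spatial":
        x = coords[:, 0]
        in_block = x <= np.quantile(x, 0.5)  # left half-plane carries the signal
        for g in range(min(spec.n_spatial_genes, spec.n_genes)):
            X[in_block, g] += spec.block_effect
        return X
    if spec.expression_model == "planted-ligrec":
        for lig_idx, rec_idx, sender, receiver in spec.ligrec_pairs:
            X[labels == sender, lig_idx] += spec.ligrec_effect
            X[labels == receiver, rec_idx] += spec.ligrec_effect
        return X
    raise ValueError(f"unknown expression model {spec.expression_model!r}")


def simulate_points(spec: SimulationSpec) -> SpatialDataset:
    """Generate a :class:`SpatialDataset` from a :class:`SimulationSpec`.

    Deterministic given the spec (including the seed): identical specs give
    identical datasets.  Labels are stored under key ``"cluster"`` as
    ``"c0" ... "c{k-1}"``; genes are ``"g0" ... "g{m-1}"``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.pattern == "poisson":
        coords = _poisson_points(spec, rng)
    elif spec.pattern == "clustered":
        coords = _thomas_points(spec, rng)
    elif spec.pattern == "lattice":
        coords = _lattice_points(spec, rng)
    else:
        raise ValueError(f"unknown pattern {spec.pattern!r}")
    labels = _labels(spec, coords, rng)
    X = _expression(spec, coords, labels, rng)
    n = len(coords)
    return SpatialDataset(
        X=X,
        obs_ids=np.array([f"obs{i}" for i in range(n)], dtype=object),
        var_ids=np.array([f"g{j}" for j in range(spec.n_genes)], dtype=object),
        coords=coords,
        labels={
            "cluster": pd.Categorical(
                [f"c{v}" for v in labels], categories=[f"c{v}" for v in range(spec.n_labels)]
            )
        },
    )


def simulate_blob_image(
    n_blobs: int,
    radius: float,
    size: tuple[int, int] = (128, 128),
    intensity: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    min_gap: float | None = None,
) -> tuple[ImageStore, np.ndarray]:
    """Image of non-overlapping bright disks plus Gaussian noise.

    Returns the :class:`ImageStore` (layer ``"image"``, float in [0, ~1]) and
    the true centers as an (n_blobs, 2) array of (x, y) pixel coordinates —
    the ground truth for segmentation tests.  Centers are placed by rejection
    sampling with a minimum center distance of ``min_gap`` (default
    ``2 * radius + 2``); an infeasible packing raises after 10^4 failures.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    gap = min_gap if min_gap is not None else 2 * radius + 2
    centers: list[tuple[float, float]] = []
    failures = 0
    while len(centers) < n_blobs:
        cx = rng.uniform(radius, w - radius)
        cy = rng.uniform(radius, h - radius)
        if all((cx - x) ** 2 + (cy - y) ** 2 >= gap**2 for x, y in centers):
            centers.append((cx, cy))
        else:
            failures += 1
            if failures > 10_000:
                raise ValueError(
                    f"cannot place {n_blobs} blobs of radius {radius} in {size} without overlap"
                )
    img = np.zeros((h, w), dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for cx, cy in centers:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2] = intensity
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, size=img.shape)
    store = ImageStore()
    store.add("image", np.clip(img, 0, None))
    return store, np.array(centers, dtype=float)
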