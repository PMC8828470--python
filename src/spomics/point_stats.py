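"""Coordinate-space point-pattern statistics.

:func:`ripley` computes Ripley's F, G and L functions per cluster, describing
whether the labeled points are randomly placed, dispersed or clustered:

* ``L(t) = sqrt(K(t) / pi)`` with the unbiased estimator
  ``K(t) = A / (n (n-1)) * sum_{i != j} 1[d_ij < t]`` and A the bounding-box
  area of all coordinates (no edge correction).  Under complete spatial
  randomness L(t) is approximately t.
* ``G(t)`` — empirical CDF of within-cluster nearest-neighbor distances.
* ``F(t)`` — empty-space function: empirical CDF of distances from uniform
  random reference points in the bounding box to the nearest cluster point.

:func:`co_occurrence` computes the conditional/marginal label frequency ratio
within distance shells around the points of a conditioning cluster: values
above 1 mean the cluster co-occurs with the conditioning cluster at that
range more often than its overall abundance predicts.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .datamodel import SpatialDataset

__all__ = ["RipleyResult", "CoOccurrenceResult", "ripley", "co_occurrence"]


@dataclasses.dataclass
class RipleyResult:
    """Per-cluster Ripley curves over a common support.

    ``values[cluster]`` is the curve evaluated at ``support``; F and G curves
    are CDFs in [0, 1]; L is non-negative.  ``area`` is the bounding-box area
    used by the K estimator; ``n_points`` gives the per-cluster point count.
    """

    mode: str
    support: np.ndarray
    values: dict[str, np.ndarray]
    area: float
    n_points: dict[str, int]

    def __post_init__(self) -> None:
        s = np.asarray(self.support, dtype=float)
        if s[0] != 0 or np.any(np.diff(s) <= 0):
            raise ValueError("support must be strictly increasing from 0")
        for c, v in self.values.items():
            if len(v) != len(s):
                raise ValueError(f"curve for {c!r} does not match support length")
            if self.mode in ("F", "G"):
                if np.any(v < -1e-12) or np.any(v > 1 + 1e-12) or np.any(np.diff(v) < -1e-12):
                    raise ValueError(f"{self.mode} curve for {c!r} is not a CDF")
            elif np.any(v < 0):
                raise ValueError(f"L curve for {c!r} has negative values")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, v in self.values.items():
            for t, val in zip(self.support, v):
                rows.append({"cluster": c, "t": t, "value": val})
        return pd.DataFrame(rows)


@dataclasses.dataclass
class CoOccurrenceResult:
    """Cluster co-occurrence ratios around one conditioning cluster.

    ``ratio`` is clusters x intervals; ``interval_edges`` has one more entry
    than there are intervals.  Empty shells give NaN columns.
    """

    conditioning: str
    interval_edges: np.ndarray
    clusters: list
    ratio: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.interval_edges, dtype=float)
        if np.any(np.diff(e) <= 0):
            raise ValueError("interval edges must be strictly increasing")
        if self.ratio.shape != (len(self.clusters), len(e) - 1):
            raise ValueError("ratio must be clusters x intervals")
        with np.errstate(invalid="ignore"):
            if np.any(self.ratio[~np.isnan(self.ratio)] < 0):
                raise ValueError("ratios must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        mids = 0.5 * (self.interval_edges[:-1] + self.interval_edges[1:])
        rows = []
        for ci, c in enumerate(self.clusters):
            for m, r in zip(mids, self.ratio[ci]):
                rows.append({"cluster": c, "interval_mid": m, "ratio": r})
        return pd.DataFrame(rows)


def _bounding_box(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return coords.min(axis=0), coords.max(axis=0)


def ripley(
    dataset: SpatialDataset,
    label_key: str,
    mode: str,
    n_steps: int = 50,
    n_ref: int | None = None,
    seed: int | None = None,
) -> RipleyResult:
    """Ripley F, G or L curve per cluster.

    The support is ``n_steps`` equally spaced radii from 0 to half the
    bounding-box diagonal of *all* coordinates, shared across clusters so
    curves are directly comparable.  Clusters with fewer than 2 points are
    skipped with a warning.

    Parameters
    ----------
    mode
        "L" (variance-stabilized K), "G" (nearest-neighbor CDF) or
        "F" (empty-space CDF, needs ``seed`` for the uniform reference
        points; ``n_ref`` defaults to the cluster size).
    """
    if mode not in ("F", "G", "L"):
        raise ValueError(f"mode must be one of F, G, L; got {mode!r}")
    if mode == "F" and seed is None:
        raise ValueError("mode='F' draws random reference points and requires a seed")
    codes, cats = dataset.label_codes(label_key)
    coords = dataset.coords
    lo, hi = _bounding_box(coords)
    area = float(np.prod(hi - lo))
    diag = float(np.linalg.norm(hi - lo))
    support = np.linspace(0.0, diag / 2.0, n_steps)

    rng = np.random.default_rng(seed) if seed is not None else None
    values: dict[str, np.ndarray] = {}
    n_points: dict[str, int] = {}
    for ci, cat in enumerate(cats):
        pts = coords[codes == ci]
        n = len(pts)
        if n < 2:
            warnings.warn(f"cluster {cat!r} has {n} point(s); skipped", stacklevel=2)
            continue
        n_points[str(cat)] = n
        if mode == "L":
            d = pdist(pts)
            # K(t) = A/(n(n-1)) * #{ordered pairs with d < t}; pdist gives each
            # unordered pair once, hence the factor 2
            counts = np.searchsorted(np.sort(d), support, side="left") * 2
            K = area / (n * (n - 1)) * counts
            values[str(cat)] = np.sqrt(K / np.pi)
        elif mode == "G":
            D = squareform(pdist(pts))
            np.fill_diagonal(D, np.inf)
            nn = D.min(axis=1)
            values[str(cat)] = np.searchsorted(np.sort(nn), support, side="right") / n
        else:  # F
            m = n_ref if n_ref is not None else n
            ref = lo + rng.random((m, 2)) * (hi - lo)
            nn = cdist(ref, pts).min(axis=1)
            values[str(cat)] = np.searchsorted(np.sort(nn), support, side="right") / m
    return RipleyResult(mode=mode, support=support, values=values, area=area, n_points=n_points)


def co_occurrence(
    dataset: SpatialDataset,
    label_key: str,
    conditioning: str,
    n_intervals: int = 50,
    interval: np.ndarray | None = None,
    cumulative: bool = False,
) -> CoOccurrenceResult:
    """Conditional/marginal cluster frequency ratio by distance shell.

    For each annular shell ``(d_low, d_high]`` around the conditioning
    cluster's points (counts pooled over all centers, so one point may count
    for several centers) and each cluster c::

        ratio(c, shell) = p(c | point in shell) / p(c)

    with p(c) the global label frequency.  Shells with no points give NaN.
    Default edges are ``n_intervals`` equal steps from the smallest positive
    pairwise distance to half the maximum pairwise distance; pass
    ``interval`` for explicit edges or ``cumulative=True`` to use growing
    balls ``(0, d_high]`` instead of annuli.
    """
    codes, cats = dataset.label_codes(label_key)
    cat_strs = [str(c) for c in cats]
    if str(conditioning) not in cat_strs:
        raise ValueError(f"unknown conditioning category {conditioning!r}; have {cat_strs}")
    cond_idx = cat_strs.index(str(conditioning))
    centers = dataset.coords[codes == cond_idx]
    if len(centers) == 0:
        raise ValueError(f"conditioning cluster {conditioning!r} is empty")

    coords = dataset.coords
    if interval is not None:
        edges = np.asarray(interval, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("interval must be a strictly increasing 1-D edge array")
    else:
        d_all = pdist(coords)
        pos = d_all[d_all > 0]
        if pos.size == 0:
            raise ValueError("all points are coincident; no distance scale")
        edges = np.linspace(pos.min(), d_all.max() / 2.0, n_intervals + 1)

    # distances from every conditioning center to every point; the center
    # itself (distance 0) never falls in a shell because edges are positive
    D = cdist(centers, coords)
    k = len(cats)
    n_int = len(edges) - 1
    global_freq = np.bincount(codes, minlength=k) / len(codes)
    ratio = np.full((k, n_int), np.nan)
    for s in range(n_int):
        lo = 0.0 if cumulative else edges[s]
        hi = edges[s + 1]
        in_shell = (D > lo) & (D <= hi)
        pooled = codes[np.nonzero(in_shell)[1]]  # label of each (center, point) hit
        if pooled.size == 0:
            continue
        cond_freq = np.bincount(pooled, minlength=k) / pooled.size
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio[:, s] = np.where(global_freq > 0, cond_freq / global_freq, np.nan)
    return CoOccurrenceResult(
        conditioning=str(conditioning),
        interval_edges=edges,
        clusters=cat_strs,
        ratio=ratio,
    )
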