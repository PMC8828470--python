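"""Tissue-image container, preprocessing, segmentation and spot-level features.

The :class:`ImageStore` holds named 2-D multi-channel pixel layers that share
one coordinate frame with the spot coordinates of a
:class:`~spomics.datamodel.SpatialDataset`: a spot center (x, y) addresses
pixel (column=x, row=y), origin top-left.

The workflow mirrors common tissue-image pipelines: optional grayscale
conversion / Gaussian smoothing (:func:`process`, with tiled execution for
large images), marker-based watershed segmentation of nuclei
(:func:`segment_watershed`), square crop extraction at spot locations
(:func:`generate_spot_crops`) and per-spot feature aggregation
(:func:`calculate_features`) producing an obs x features matrix that slots
into the dataset next to the gene matrix.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import graycomatrix, graycoprops, peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .datamodel import SpatialDataset

__all__ = [
    "ImageStore",
    "SpotGeometry",
    "load_image",
    "process",
    "segment_watershed",
    "generate_spot_crops",
    "calculate_features",
]

# luminance weights of the grayscale conversion (ITU-R 709 primaries)
_GRAY_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])


class ImageStore:
    """Named pixel layers of shape (height, width, channels) sharing one frame.

    Layers are unsigned 8/16-bit integers or floats in [0, 1]; segmentation
    layers hold non-negative integer labels with 0 = background.
    """

    def __init__(self) -> None:
        self.layers: dict[str, np.ndarray] = {}

    @property
    def shape(self) -> tuple[int, int] | None:
        for arr in self.layers.values():
            return arr.shape[:2]
        return None

    def add(self, name: str, array: np.ndarray) -> None:
        arr = np.asarray(array)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError(f"layer {name!r} must be 2-D or (h, w, c), got shape {arr.shape}")
        if np.issubdtype(arr.dtype, np.integer) and arr.min() < 0:
            raise ValueError(f"integer layer {name!r} must be non-negative")
        if self.shape is not None and arr.shape[:2] != self.shape:
            raise ValueError(
                f"layer {name!r} shape {arr.shape[:2]} does not match store shape {self.shape}"
            )
        self.layers[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.layers:
            raise KeyError(f"no layer {name!r}; have {sorted(self.layers)}")
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers


@dataclasses.dataclass
class SpotGeometry:
    """Spot centers and crop sizing.

    ``centers`` are obs x 2 pixel coordinates (x = column, y = row);
    the square crop side is ``round(diameter * spot_scale * scale)`` pixels,
    at least 1.
    """

    centers: np.ndarray
    diameter: float
    spot_scale: float = 1.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValueError("centers must be obs x 2")
        if self.diameter <= 0 or self.spot_scale <= 0 or self.scale <= 0:
            raise ValueError("diameter, spot_scale and scale must be positive")

    @property
    def crop_side(self) -> int:
        return max(1, int(round(self.diameter * self.spot_scale * self.scale)))

    @classmethod
    def from_dataset(cls, dataset: SpatialDataset, diameter: float, **kw) -> "SpotGeometry":
        return cls(centers=dataset.coords, diameter=diameter, **kw)


def load_image(path: str | Path, layer: str, store: ImageStore | None = None) -> ImageStore:
    """Load a TIFF or PNG into a (new or existing) :class:`ImageStore`.

    Grayscale images are promoted to a single channel; the layer must match
    the spatial shape of any layers already present.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    store = store if store is not None else ImageStore()
    store.add(layer, arr)
    return store


def _gray(arr: np.ndarray) -> np.ndarray:
    if arr.shape[2] != 3:
        raise ValueError(f"grayscale conversion needs 3 channels, got {arr.shape[2]}")
    out = np.tensordot(arr.astype(float), _GRAY_WEIGHTS, axes=([2], [0]))
    return out[:, :, None]


def _smooth(arr: np.ndarray, sigma: float) -> np.ndarray:
    out = np.empty_like(arr, dtype=float)
    for c in range(arr.shape[2]):
        out[:, :, c] = gaussian(arr[:, :, c].astype(float), sigma=sigma, preserve_range=True)
    return out


def process(
    img: ImageStore,
    layer: str,
    method,
    sigma: float = 2.0,
    tile_size: int | None = None,
    overlap: int | None = None,
    new_layer: str | None = None,
) -> str:
    """Apply grayscale conversion, Gaussian smoothing or a custom transform.

    ``method`` is ``"gray"``, ``"smooth"`` or any pure function mapping a
    (h, w, c) float array to a pixel array.  With ``tile_size`` set the image
    is processed in overlapping square tiles and reassembled from the tile
    interiors; for smoothing, an overlap of at least ``4 * sigma`` makes the
    tiled result match whole-image processing except for floating-point
    round-off (the default overlap is ``ceil(4 * sigma)``).

    Returns the name of the layer written (``<layer>_<method>`` by default).
    """
    arr = img[layer]
    if method == "gray":
        fn = _gray
        name = new_layer or f"{layer}_gray"
    elif method == "smooth":
        fn = lambda a: _smooth(a, sigma)  # noqa: E731
        name = new_layer or f"{layer}_smooth"
    elif callable(method):
        fn = method
        name = new_layer or f"{layer}_custom"
    else:
        raise ValueError(f"method must be 'gray', 'smooth' or a callable, got {method!r}")

    if tile_size is None:
        out = np.asarray(fn(arr))
    else:
        if overlap is None:
            overlap = int(np.ceil(4 * sigma))
        out = _tiled_apply(arr, fn, tile_size, overlap)
    if out.ndim == 2:
        out = out[:, :, None]
    img.add(name, out)
    return name


def _tiled_apply(arr: np.ndarray, fn, tile_size: int, overlap: int) -> np.ndarray:
    """Apply ``fn`` on overlapping tiles, keeping each tile's interior."""
    h, w = arr.shape[:2]
    probe = np.asarray(fn(arr[: min(h, tile_size), : min(w, tile_size)]))
    n_out = probe.shape[2] if probe.ndim == 3 else 1
    out = np.zeros((h, w, n_out), dtype=float)
    for y0 in range(0, h, tile_size):
        for x0 in range(0, w, tile_size):
            ylo, xlo = max(0, y0 - overlap), max(0, x0 - overlap)
            yhi, xhi = min(h, y0 + tile_size + overlap), min(w, x0 + tile_size + overlap)
            tile_out = np.asarray(fn(arr[ylo:yhi, xlo:xhi]))
            if tile_out.ndim == 2:
                tile_out = tile_out[:, :, None]
            y1, x1 = min(h, y0 + tile_size), min(w, x0 + tile_size)
            out[y0:y1, x0:x1] = tile_out[y0 - ylo : y0 - ylo + (y1 - y0), x0 - xlo : x0 - xlo + (x1 - x0)]
    return out


def segment_watershed(
    img: ImageStore,
    layer: str,
    invert: bool = False,
    threshold="otsu",
    min_peak_distance: int = 5,
    new_layer: str | None = None,
) -> str:
    """Marker-based watershed segmentation of a single-channel layer.

    Foreground is the set of pixels above the threshold (below it when
    ``invert`` is set, for dark nuclei on a bright background); markers are
    local maxima of the Euclidean distance transform at least
    ``min_peak_distance`` apart, and the watershed floods the negative
    distance transform within the foreground so touching objects split at
    the ridge between their markers.  Output labels are consecutive integers
    from 1 with 0 = background; an empty foreground yields all zeros with a
    warning.
    """
    arr = img[layer]
    if arr.shape[2] != 1:
        raise ValueError("watershed needs a single-channel layer; run process(..., 'gray') first")
    plane = arr[:, :, 0].astype(float)
    thr = threshold_otsu(plane) if threshold == "otsu" else float(threshold)
    fg = plane < thr if invert else plane > thr
    name = new_layer or f"{layer}_seg"
    if not fg.any():
        warnings.warn("empty foreground; segmentation produced 0 objects", stacklevel=2)
        img.add(name, np.zeros(plane.shape, dtype=np.int32)[:, :, None])
        return name
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=min_peak_distance, labels=fg)
    markers = np.zeros(plane.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        # degenerate but non-empty foreground: single marker at the distance peak
        r, c = np.unravel_index(np.argmax(dist), dist.shape)
        markers[r, c] = 1
    labels = watershed(-dist, markers, mask=fg)
    # relabel consecutively from 1
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    img.add(name, remap[labels][:, :, None])
    return name


def generate_spot_crops(img: ImageStore, geometry: SpotGeometry, layer: str):
    """Yield (obs_index, crop, padded) square crops at each spot center.

    Crops follow the observation order; centers near the border give
    zero-padded crops with ``padded=True``.
    """
    arr = img[layer]
    h, w = arr.shape[:2]
    side = geometry.crop_side
    half = side // 2
    for i, (cx, cy) in enumerate(geometry.centers):
        col, row = int(round(cx)), int(round(cy))
        r0, c0 = row - half, col - half
        r1, c1 = r0 + side, c0 + side
        crop = np.zeros((side, side, arr.shape[2]), dtype=arr.dtype)
        rr0, cc0 = max(0, r0), max(0, c0)
        rr1, cc1 = min(h, r1), min(w, c1)
        padded = (rr0 != r0) or (cc0 != c0) or (rr1 != r1) or (cc1 != c1)
        if rr1 > rr0 and cc1 > cc0:
            crop[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0] = arr[rr0:rr1, cc0:cc1]
        yield i, crop, padded


def _summary_features(crop: np.ndarray, layer: str, quantiles) -> dict[str, float]:
    out = {}
    for c in range(crop.shape[2]):
        vals = crop[:, :, c].astype(float).ravel()
        out[f"summary_{layer}_ch{c}_mean"] = float(vals.mean())
        out[f"summary_{layer}_ch{c}_std"] = float(vals.std())
        for q in quantiles:
            out[f"summary_{layer}_ch{c}_quantile_{q}"] = float(np.quantile(vals, q))
    return out


def _histogram_features(crop: np.ndarray, layer: str, bins: int, vrange) -> dict[str, float]:
    out = {}
    for c in range(crop.shape[2]):
        vals = crop[:, :, c].astype(float).ravel()
        lo, hi = vrange if vrange is not None else (vals.min(), vals.max())
        if hi <= lo:
            hi = lo + 1.0
        counts, _ = np.histogram(vals, bins=bins, range=(lo, hi))
        for b, cnt in enumerate(counts):
            out[f"histogram_{layer}_ch{c}_bin{b}"] = float(cnt)
    return out


_TEXTURE_PROPS = ("contrast", "dissimilarity", "homogeneity", "ASM", "correlation")


def _quantize(plane: np.ndarray, levels: int, vrange) -> np.ndarray:
    if np.issubdtype(plane.dtype, np.unsignedinteger):
        maxv = np.iinfo(plane.dtype).max
        if maxv == levels - 1:
            return plane.astype(np.uint8) if levels <= 256 else plane
        scaled = plane.astype(float) / maxv
    else:
        if vrange is None:
            raise ValueError(
                "texture features on a float layer need an explicit quantization "
                "range, e.g. texture_range=(0.0, 1.0)"
            )
        lo, hi = vrange
        scaled = np.clip((plane.astype(float) - lo) / (hi - lo), 0, 1)
    return np.minimum((scaled * levels).astype(np.int32), levels - 1).astype(np.uint8)


def _texture_features(
    crop: np.ndarray, layer: str, levels: int, distances, angles, vrange
) -> dict[str, float]:
    out = {}
    for c in range(crop.shape[2]):
        q = _quantize(crop[:, :, c], levels, vrange)
        glcm = graycomatrix(q, distances=distances, angles=angles, levels=levels, symmetric=True, normed=True)
        for prop in _TEXTURE_PROPS:
            vals = graycoprops(glcm, prop)  # distances x angles
            for di, d in enumerate(distances):
                out[f"texture_{layer}_ch{c}_{prop.lower()}_d{d}"] = float(vals[di].mean())
    return out


def _segmentation_features_all(
    img: ImageStore,
    geometry: SpotGeometry,
    label_layer: str,
    intensity_layer: str | None,
) -> list[dict[str, float]]:
    """Object count / area / intensity statistics per spot.

    Objects are segmented on the full label image; each object is assigned
    to a spot when its centroid falls inside that spot's crop window
    (centroid-in-crop, so an object belongs to at most one spot per
    non-overlapping windows).  Areas and intensities are whole-object
    statistics, not clipped to the window.
    """
    lab = img[label_layer][:, :, 0].astype(np.int64)
    props = regionprops(lab)
    centroids = np.array([p.centroid for p in props]) if props else np.empty((0, 2))  # (row, col)
    areas = np.array([p.area for p in props], dtype=float)
    inten = img[intensity_layer] if intensity_layer is not None else None
    n_ch = inten.shape[2] if inten is not None else 0
    obj_mean_int = np.zeros((len(props), n_ch))
    for oi, p in enumerate(props):
        for c in range(n_ch):
            obj_mean_int[oi, c] = inten[:, :, c][tuple(p.coords.T)].mean()
    obj_pix = areas  # pixel count per object, for pixel-weighted intensity pooling

    side = geometry.crop_side
    half = side // 2
    rows_out = []
    for cx, cy in geometry.centers:
        col, row = int(round(cx)), int(round(cy))
        r0, c0 = row - half, col - half
        r1, c1 = r0 + side, c0 + side
        if len(props):
            inside = (
                (centroids[:, 0] >= r0)
                & (centroids[:, 0] < r1)
                & (centroids[:, 1] >= c0)
                & (centroids[:, 1] < c1)
            )
        else:
            inside = np.zeros(0, dtype=bool)
        sel = np.flatnonzero(inside)
        count = len(sel)
        out = {
            f"segmentation_{label_layer}_count": float(count),
            f"segmentation_{label_layer}_area_mean": float(areas[sel].mean()) if count else 0.0,
            f"segmentation_{label_layer}_area_std": float(areas[sel].std()) if count else 0.0,
        }
        for c in range(n_ch):
            if count:
                w = obj_pix[sel]
                out[f"segmentation_{label_layer}_ch{c}_mean_intensity"] = float(
                    np.average(obj_mean_int[sel, c], weights=w)
                )
            else:
                out[f"segmentation_{label_layer}_ch{c}_mean_intensity"] = 0.0
        rows_out.append(out)
    return rows_out


def calculate_features(
    dataset: SpatialDataset,
    img: ImageStore,
    geometry: SpotGeometry,
    layer: str,
    features=("summary",),
    obsm_key: str = "img_features",
    summary_quantiles=(0.9, 0.5, 0.1),
    histogram_bins: int = 10,
    histogram_range=None,
    texture_levels: int = 256,
    texture_distances=(1,),
    texture_angles=(0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4),
    texture_range=None,
    label_layer: str | None = None,
    intensity_layer: str | None = None,
) -> pd.DataFrame:
    """Aggregate image features per observation from spot crops.

    ``features`` is any subset of {"summary", "histogram", "texture",
    "segmentation"}:

    * summary — mean, standard deviation and quantiles per channel;
    * histogram — per-bin pixel counts of each channel's histogram;
    * texture — gray-level co-occurrence matrix properties (contrast,
      dissimilarity, homogeneity, angular second moment, correlation),
      GLCM symmetrized and normalized to probabilities, averaged over the
      four axis/diagonal directions at each offset distance;
    * segmentation — object count, area mean/sd and per-channel mean
      intensity over object pixels, from a label layer (``label_layer``).

    The resulting obs x features table (deterministic column order,
    observation order preserved) is also attached to ``dataset.obsm`` under
    ``obsm_key``.
    """
    features = set(features)
    unknown = features - {"summary", "histogram", "texture", "segmentation"}
    if unknown:
        raise ValueError(f"unknown feature set(s): {sorted(unknown)}")
    if "segmentation" in features:
        if label_layer is None or label_layer not in img:
            raise ValueError("segmentation features need label_layer pointing to a label layer in the store")
        seg_rows = _segmentation_features_all(img, geometry, label_layer, intensity_layer)

    records = []
    for i, crop, _padded in generate_spot_crops(img, geometry, layer):
        row: dict[str, float] = {}
        if "summary" in features:
            row.update(_summary_features(crop, layer, summary_quantiles))
        if "histogram" in features:
            row.update(_histogram_features(crop, layer, histogram_bins, histogram_range))
        if "texture" in features:
            row.update(
                _texture_features(
                    crop, layer, texture_levels, list(texture_distances), list(texture_angles), texture_range
                )
            )
        if "segmentation" in features:
            row.update(seg_rows[i])
        records.append(row)
    table = pd.DataFrame.from_records(records, index=pd.Index(dataset.obs_ids, name="obs_id"))
    table = table[sorted(table.columns)]
    dataset.obsm[obsm_key] = table.to_numpy()
    return table
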