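"""Nuclear segmentation from the DAPI channel.

Pipeline: grayscale conversion to the 8-bit-equivalent scale, global
binarization (Otsu by default), morphological closing (three dilations then
three erosions by default) to remove noise, watershed splitting of touching
nuclei on the Euclidean distance transform, and extraction of size-filtered
labelled regions with their shape properties.

The Otsu threshold is computed over the 256 integer gray levels by
maximizing between-class variance, with foreground defined as pixels
*strictly above* the threshold (ties to background) and the lowest
maximizing level taken on ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

__all__ = [
    "CellRegion", "to_grayscale", "otsu_threshold", "binarize",
    "cross_selem", "close_mask", "watershed_split", "extract_regions",
    "segment_dapi",
]

#: 3x3 cross (4-connectivity) structuring element, the closing default
def cross_selem() -> np.ndarray:
    return ndi.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class CellRegion:
    """A segmented nuclear region with shape descriptors.

    ``bbox`` is half-open ``(row0, col0, row1, col1)``; areas are given both
    in pixels and µm² (via the scan's pixel size).
    """

    label_id: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    area_px: int
    area_um2: float
    eccentricity: float
    solidity: float
    perimeter_px: float


def to_grayscale(raster: np.ndarray) -> np.ndarray:
    """Convert a channel raster to the 8-bit-equivalent gray scale [0, 255].

    Single-channel integer rasters are rescaled by their dtype's full range
    (8-bit data passes through numerically unchanged); RGB is reduced with
    ITU-R BT.601 luma first.
    """
    arr = np.asarray(raster)
    if arr.ndim == 3 and arr.shape[2] == 3:
        luma = (0.299 * arr[..., 0].astype(float)
                + 0.587 * arr[..., 1].astype(float)
                + 0.114 * arr[..., 2].astype(float))
        if np.issubdtype(arr.dtype, np.integer):
            return luma * (255.0 / np.iinfo(arr.dtype).max)
        return luma
    if arr.ndim != 2:
        raise ValueError(f"unsupported raster with {arr.ndim} dimensions")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) * (255.0 / np.iinfo(arr.dtype).max)
    return arr.astype(float)


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu threshold on the 256 integer gray levels.

    Returns the level t in [0, 255] maximizing the between-class variance of
    the split {pixels <= t} vs {pixels > t}; the lowest maximizing level is
    returned when several tie.  Raises on a constant image (no separable
    classes) — callers that can tolerate it should catch and fall back.
    """
    g = np.clip(np.rint(np.asarray(gray, dtype=float)), 0, 255).astype(np.intp)
    hist = np.bincount(g.ravel(), minlength=256).astype(float)
    n = hist.sum()
    if n == 0:
        raise ValueError("empty image")
    w0 = np.cumsum(hist)            # pixels <= t
    s0 = np.cumsum(hist * np.arange(256))
    w1 = n - w0
    mu_total = s0[-1]
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise ValueError("constant image: Otsu classes are not separable")
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (mu_total - s0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[~valid] = -np.inf
    return int(np.argmax(var_between))


def binarize(gray: np.ndarray, method: str = "otsu",
             fixed_value: float | None = None) -> np.ndarray:
    """Binarize a gray raster; foreground = pixels strictly above threshold."""
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty raster")
    if method == "otsu":
        try:
            thr: float = otsu_threshold(gray)
        except ValueError:
            warnings.warn("constant image: Otsu has no separable classes; "
                          "returning an empty foreground mask", stacklevel=2)
            return np.zeros(gray.shape, dtype=bool)
    elif method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed binarization requires fixed_value")
        thr = float(fixed_value)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return gray > thr


def close_mask(mask: np.ndarray, iterations: int = 3,
               selem: np.ndarray | None = None) -> np.ndarray:
    """Morphological closing: `iterations` dilations then `iterations` erosions.

    Uses a 3x3 cross by default; ``iterations=0`` is the identity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return mask.copy()
    if selem is None:
        selem = cross_selem()
    dil = ndi.binary_dilation(mask, structure=selem, iterations=iterations)
    return ndi.binary_erosion(dil, structure=selem, iterations=iterations,
                              border_value=1)


def watershed_split(mask: np.ndarray,
                    min_marker_distance_px: int = 10) -> np.ndarray:
    """Split touching objects by watershed on the distance transform.

    Markers are local maxima of the Euclidean distance transform separated
    by at least ``min_marker_distance_px``; the watershed floods the negated
    distance map restricted to the mask.  Every foreground pixel receives a
    label; labels are contiguous from 1.  An empty mask yields an all-zero
    labelling.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    coords = peak_local_max(distance, min_distance=min_marker_distance_px,
                            labels=mask, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    if len(coords) == 0:
        # degenerate: fall back to connected components
        markers, _ = ndi.label(mask)
    else:
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-distance, markers=markers, mask=mask)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def extract_regions(labels: np.ndarray, pixel_size_um: float,
                    area_min_um2: float = 20.0,
                    area_max_um2: float = 2000.0) -> list[CellRegion]:
    """Extract size-filtered regions with shape properties.

    Regions with area outside ``[area_min_um2, area_max_um2]`` are dropped
    (single-pixel noise and large aggregates).  Output order is
    deterministic: sorted by (bbox row0, col0, label).
    """
    px_area_um2 = pixel_size_um ** 2
    out = []
    for rp in regionprops(labels):
        area_um2 = rp.area * px_area_um2
        if not area_min_um2 <= area_um2 <= area_max_um2:
            continue
        out.append(CellRegion(
            label_id=int(rp.label),
            bbox=tuple(int(v) for v in rp.bbox),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            area_px=int(rp.area),
            area_um2=float(area_um2),
            eccentricity=float(rp.eccentricity),
            solidity=float(rp.solidity),
            perimeter_px=float(max(rp.perimeter, 1.0)),
        ))
    out.sort(key=lambda r: (r.bbox[0], r.bbox[1], r.label_id))
    return out


def segment_dapi(dapi: np.ndarray, pixel_size_um: float,
                 method: str = "otsu", fixed_value: float | None = None,
                 closing_iterations: int = 3,
                 min_marker_distance_px: int = 10,
                 area_min_um2: float = 20.0, area_max_um2: float = 2000.0
                 ) -> tuple[np.ndarray, list[CellRegion]]:
    """Full DAPI segmentation chain; returns (labelled raster, regions)."""
    gray = to_grayscale(dapi)
    mask = binarize(gray, method=method, fixed_value=fixed_value)
    closed = close_mask(mask, iterations=closing_iterations)
    labels = watershed_split(closed, min_marker_distance_px=min_marker_distance_px)
    regions = extract_regions(labels, pixel_size_um,
                              area_min_um2=area_min_um2,
                              area_max_um2=area_max_um2)
    return labels, regions
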