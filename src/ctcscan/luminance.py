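"""Per-cell background-corrected marker luminance on the 8-bit scale.

For each segmented cell a cutout is taken around its nucleus in every
channel.  The marker channels are corrected for local staining background
(median of pixels outside the dilated nuclear mask, subtracted and clamped
at zero), the stained foreground inside the cutout is found by Otsu
binarization of the corrected marker patch, and the cell's luminance is the
mean corrected gray value over that foreground.  This removes additive
differences in staining conditions and nonspecific luminescence between
cell images, so luminances are comparable across samples and usable for
control-population threshold calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .scan_io import MARKERS, ScanSet
from .segmentation import CellRegion, otsu_threshold, to_grayscale

__all__ = ["CellCutout", "LuminanceMeasurement", "make_cutout",
           "background_correct", "measure_luminance", "luminance_table"]


@dataclass
class CellCutout:
    """Per-channel sub-rasters around one cell, plus the aligned region mask."""

    cell_id: int
    channels: dict[str, np.ndarray]
    mask: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.channels.values()} | {self.mask.shape}
        if len(shapes) != 1:
            raise ValueError("cutout channels and mask must share one shape")
        if not self.mask.any():
            raise ValueError("cutout mask is empty")


@dataclass(frozen=True)
class LuminanceMeasurement:
    sample_id: str
    cell_id: int
    marker: str
    raw_mean: float
    background_level: float
    corrected_mean: float
    foreground_pixel_count: int
    qc_flag: str = ""


def make_cutout(scan: ScanSet, region: CellRegion, labels: np.ndarray,
                margin_px: int = 10) -> CellCutout:
    """Cut out all channels around a region with a fixed margin."""
    h, w = scan.shape
    r0, c0, r1, c1 = region.bbox
    sl = (slice(max(r0 - margin_px, 0), min(r1 + margin_px, h)),
          slice(max(c0 - margin_px, 0), min(c1 + margin_px, w)))
    channels = {ch: to_grayscale(scan.channels[ch][sl])
                for ch in scan.channels}
    mask = labels[sl] == region.label_id
    return CellCutout(cell_id=region.label_id, channels=channels, mask=mask,
                      origin=(sl[0].start, sl[1].start))


def background_correct(cutout: CellCutout, marker: str,
                       global_background: float | None = None
                       ) -> tuple[np.ndarray, float]:
    """Subtract the local staining background from a marker sub-raster.

    The background level is the median of marker pixels outside the region
    mask dilated by 3 px; the corrected raster is raw − background, clamped
    at 0.  If the mask fills the cutout there are no background pixels; the
    caller-provided global scan estimate (default 0) is used with a warning.
    """
    raw = np.asarray(cutout.channels[marker], dtype=float)
    dilated = ndi.binary_dilation(cutout.mask, iterations=3)
    outside = ~dilated
    if outside.any():
        level = float(np.median(raw[outside]))
    else:
        level = float(global_background or 0.0)
        warnings.warn("region mask fills the entire cutout; falling back to "
                      "the global scan background estimate", stacklevel=2)
    return np.clip(raw - level, 0.0, None), level


def measure_luminance(cutout: CellCutout, marker: str, sample_id: str = "",
                      global_background: float | None = None
                      ) -> LuminanceMeasurement:
    """Background-corrected mean marker luminance of one cell.

    The stained foreground is found by Otsu within the corrected cutout
    (strictly-above threshold), restricted to the cell's own neighborhood
    (region mask dilated by 3 px) so that staining of adjacent cells inside
    the cutout frame cannot leak into this cell's measurement.  Degenerate
    cases — a constant corrected patch or fewer than 3 foreground pixels —
    fall back to the DAPI region mask and are flagged; an all-zero marker
    patch yields luminance 0 by convention.
    """
    corrected, level = background_correct(cutout, marker,
                                          global_background=global_background)
    raw = np.asarray(cutout.channels[marker], dtype=float)
    qc = ""
    if corrected.max() <= 0:
        fg = cutout.mask
        qc = "null_expression"
        mean_val = 0.0
        n_fg = int(fg.sum())
    else:
        neighborhood = ndi.binary_dilation(cutout.mask, iterations=3)
        try:
            thr = otsu_threshold(corrected)
            fg = (corrected > thr) & neighborhood
        except ValueError:
            fg = np.zeros_like(cutout.mask)
        if fg.sum() < 3:
            fg = cutout.mask
            qc = "otsu_degenerate_fallback_mask"
        mean_val = float(corrected[fg].mean())
        n_fg = int(fg.sum())
    return LuminanceMeasurement(
        sample_id=sample_id, cell_id=cutout.cell_id, marker=marker,
        raw_mean=float(raw[fg].mean()) if n_fg else 0.0,
        background_level=level, corrected_mean=mean_val,
        foreground_pixel_count=n_fg, qc_flag=qc)


def luminance_table(scan: ScanSet, regions: list[CellRegion],
                    labels: np.ndarray, margin_px: int = 10) -> pd.DataFrame:
    """Per-cell luminance table for one scan: one row per cell.

    Columns: sample_id, cell_id, centroid, one ``<marker>_corrected_mean``
    and ``<marker>_background`` pair per marker, plus QC flags.
    """
    rows = []
    for reg in regions:
        cut = make_cutout(scan, reg, labels, margin_px=margin_px)
        row: dict = {"sample_id": scan.sample_id, "cell_id": reg.label_id,
                     "centroid_row": reg.centroid[0],
                     "centroid_col": reg.centroid[1]}
        flags = []
        for m in MARKERS:
            meas = measure_luminance(cut, m, sample_id=scan.sample_id)
            row[f"{m}_corrected_mean"] = meas.corrected_mean
            row[f"{m}_background"] = meas.background_level
            if meas.qc_flag:
                flags.append(f"{m}:{meas.qc_flag}")
        row["qc_flags"] = ";".join(flags)
        rows.append(row)
    cols = (["sample_id", "cell_id", "centroid_row", "centroid_col"]
            + [f"{m}_corrected_mean" for m in MARKERS]
            + [f"{m}_background" for m in MARKERS] + ["qc_flags"])
    return pd.DataFrame(rows, columns=cols)
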