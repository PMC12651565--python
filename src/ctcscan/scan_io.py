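"""Scan image I/O: TIFF read/write, focus stacking, and grid stitching.

A sample is captured as a grid of tiles per channel, each tile as a Z-stack
(5 µm step on the reference instrument).  This module composes stacks into
all-in-focus tiles (sharpest-plane selection by variance of Laplacian),
stitches tile grids at nominal integer offsets with linear feather blending
in overlap zones, and reads/writes everything as plain TIFF plus a
sample-sheet CSV.

Coordinates are 0-based ``(row, col)``, row-major.  Pixel data stays in its
native integer dtype; conversion to the 8-bit-equivalent luminance scale
happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

CHANNELS = ("DAPI", "EpCAM", "CSV")
#: marker channels quantified per cell (DAPI is the nuclear/segmentation stain)
MARKERS = ("EpCAM", "CSV")

SAMPLE_SHEET_COLUMNS = ["sample_id", "group", "channel", "path",
                        "grid_row", "grid_col", "z_index"]

__all__ = [
    "CHANNELS", "MARKERS", "TileImage", "ZStack", "ScanSet",
    "focus_stack", "stitch", "cut_tiles",
    "write_scan", "read_scan", "read_scan_from_sheet",
]


@dataclass(frozen=True)
class TileImage:
    """One captured tile: a single channel at one grid position and Z plane."""

    pixels: np.ndarray
    channel: str
    grid_pos: tuple[int, int] = (0, 0)
    z_index: int = 0
    pixel_size_um: float = 0.377

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("tile pixels must be a 2-D raster")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass(frozen=True)
class ZStack:
    """Ordered Z planes of one tile (same channel and grid position)."""

    tiles: tuple[TileImage, ...]
    z_step_um: float = 5.0

    def __post_init__(self) -> None:
        if len(self.tiles) == 0:
            raise ValueError("a ZStack needs at least one plane")
        zs = [t.z_index for t in self.tiles]
        if zs != list(range(len(zs))):
            raise ValueError("z indices must be consecutive from 0")


@dataclass
class ScanSet:
    """Co-registered stitched channels for one sample."""

    sample_id: str
    group: str
    channels: dict[str, np.ndarray]
    pixel_size_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"channel {missing[0]} not found")
        shapes = {self.channels[c].shape for c in CHANNELS}
        if len(shapes) != 1:
            raise ValueError("channels are not co-registered: shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[CHANNELS[0]].shape


def _sharpness(img: np.ndarray) -> float:
    """Focus score: variance of the Laplacian."""
    return float(ndi.laplace(img.astype(float)).var())


def focus_stack(stack: ZStack) -> TileImage:
    """Select the all-in-focus plane of a Z-stack.

    Per-tile (not per-pixel) selection: the plane with the highest variance
    of Laplacian wins; ties go to the lowest z index.
    """
    scores = [_sharpness(t.pixels) for t in stack.tiles]
    best = int(np.argmax(scores))  # argmax takes the first (lowest z) on ties
    return stack.tiles[best]


def stitch(tiles: list[TileImage], layout: tuple[int, int],
           overlap_fraction: float = 0.0) -> np.ndarray:
    """Stitch a complete tile grid into one raster.

    Tiles are placed at nominal integer offsets
    ``step = tile_size * (1 - overlap_fraction)``; in overlap zones pixels
    are combined by linear feather blending (weight ramps to zero at each
    tile's border along the overlapping direction).
    """
    if not 0.0 <= overlap_fraction < 0.5:
        raise ValueError("overlap_fraction must be in [0, 0.5)")
    rows, cols = layout
    grid: dict[tuple[int, int], TileImage] = {}
    for t in tiles:
        grid[t.grid_pos] = t
    missing = [(r, c) for r in range(rows) for c in range(cols)
               if (r, c) not in grid]
    if missing:
        raise ValueError(f"incomplete tile grid; missing positions {missing}")
    th, tw = grid[(0, 0)].pixels.shape
    if any(t.pixels.shape != (th, tw) for t in grid.values()):
        raise ValueError("tiles must share a uniform shape")
    dtype = grid[(0, 0)].pixels.dtype
    step_r = int(round(th * (1.0 - overlap_fraction)))
    step_c = int(round(tw * (1.0 - overlap_fraction)))
    H = step_r * (rows - 1) + th
    W = step_c * (cols - 1) + tw

    acc = np.zeros((H, W), dtype=float)
    wacc = np.zeros((H, W), dtype=float)
    ramp_r = _feather(th, th - step_r)
    ramp_c = _feather(tw, tw - step_c)
    for (r, c), t in grid.items():
        wr = ramp_r.copy()
        wc = ramp_c.copy()
        # border tiles keep full weight at the scan edge
        if r == 0:
            wr[: th - step_r] = 1.0
        if r == rows - 1:
            wr[step_r:] = 1.0
        if c == 0:
            wc[: tw - step_c] = 1.0
        if c == cols - 1:
            wc[step_c:] = 1.0
        wgt = np.outer(wr, wc)
        sl = (slice(r * step_r, r * step_r + th),
              slice(c * step_c, c * step_c + tw))
        acc[sl] += t.pixels.astype(float) * wgt
        wacc[sl] += wgt
    out = acc / np.maximum(wacc, 1e-12)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(dtype)


def _feather(size: int, overlap: int) -> np.ndarray:
    """1-D feather weights: linear ramps over the overlap at both ends."""
    w = np.ones(size, dtype=float)
    if overlap <= 0:
        return w
    ramp = (np.arange(1, overlap + 1)) / (overlap + 1)
    w[:overlap] = ramp
    w[-overlap:] = ramp[::-1]
    return w


def cut_tiles(image: np.ndarray, channel: str, layout: tuple[int, int],
              overlap_fraction: float = 0.0,
              pixel_size_um: float = 0.377) -> list[TileImage]:
    """Cut a stitched raster into an overlapping tile grid (inverse of stitch).

    Tile size is derived so that stitching the result at the same overlap
    reproduces the original dimensions.
    """
    rows, cols = layout
    H, W = image.shape
    th = _tile_extent(H, rows, overlap_fraction)
    tw = _tile_extent(W, cols, overlap_fraction)
    step_r = int(round(th * (1.0 - overlap_fraction)))
    step_c = int(round(tw * (1.0 - overlap_fraction)))
    tiles = []
    for r in range(rows):
        for c in range(cols):
            sl = (slice(r * step_r, r * step_r + th),
                  slice(c * step_c, c * step_c + tw))
            tiles.append(TileImage(pixels=image[sl].copy(), channel=channel,
                                   grid_pos=(r, c), pixel_size_um=pixel_size_um))
    return tiles


def _tile_extent(total: int, n: int, overlap_fraction: float) -> int:
    if n == 1:
        return total
    # solve total = step*(n-1) + th with step = round(th*(1-overlap))
    th = int(round(total / (1 + (n - 1) * (1 - overlap_fraction))))
    for cand in range(max(th - 2, 1), th + 3):
        step = int(round(cand * (1.0 - overlap_fraction)))
        if step * (n - 1) + cand == total:
            return cand
    raise ValueError("image dimensions not compatible with requested tiling")


def write_scan(scan: ScanSet, out_dir: str | Path) -> pd.DataFrame:
    """Write one TIFF per channel plus a sample-sheet CSV; returns the sheet."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ch in CHANNELS:
        path = out / f"{scan.sample_id}_{ch}.tif"
        tifffile.imwrite(path, scan.channels[ch])
        rows.append({"sample_id": scan.sample_id, "group": scan.group,
                     "channel": ch, "path": str(path),
                     "grid_row": 0, "grid_col": 0, "z_index": 0})
    sheet = pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)
    sheet.to_csv(out / f"{scan.sample_id}_sheet.csv", index=False)
    return sheet


def read_scan(manifest: pd.DataFrame, pixel_size_um: float = 0.377) -> ScanSet:
    """Build a validated ScanSet from a sample-sheet manifest (one sample).

    The manifest must contain one stitched image path per channel.  Missing
    channels and co-registration failures raise with the channel named.
    """
    sample_ids = manifest["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValueError("manifest must describe exactly one sample")
    channels: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        rows = manifest[manifest["channel"] == ch]
        if len(rows) == 0:
            raise ValueError(f"channel {ch} not found")
        path = Path(rows["path"].iloc[0])
        if not path.exists():
            raise FileNotFoundError(f"channel {ch}: file {path} does not exist")
        channels[ch] = tifffile.imread(path)
    group = str(manifest["group"].iloc[0]) if "group" in manifest else "unknown"
    return ScanSet(sample_id=str(sample_ids[0]), group=group,
                   channels=channels, pixel_size_um=pixel_size_um,
                   provenance={"source": manifest["path"].tolist()})


def read_scan_from_sheet(sheet_path: str | Path,
                         sample_id: str | None = None) -> ScanSet:
    sheet = pd.read_csv(sheet_path)
    if sample_id is not None:
        sheet = sheet[sheet["sample_id"] == sample_id]
    return read_scan(sheet)
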