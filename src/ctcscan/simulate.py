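"""Synthetic multichannel fluorescence slide scans with known ground truth.

Emulates negative-enrichment CTC slides: a field of DAPI-stained nuclei
(mostly leukocyte background cells), a rare spiked subpopulation with
elevated surface-marker expression, non-cellular debris, a smooth additive
staining gradient, optional vignetting, and Gaussian sensor noise.  Marker
expression is lognormal on the 8-bit gray scale, with separate background
and CTC populations per marker.

Every scan is deterministic in ``(config, seed)`` and ships a per-object
ground-truth table, so segmentation, classification, luminance measurement
and threshold calibration can all be validated against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .scan_io import CHANNELS, MARKERS, ScanSet

__all__ = [
    "MarkerModel",
    "SimulationConfig",
    "simulate_scan",
    "simulate_cohort",
    "analytic_marker_quantile",
    "match_regions_to_truth",
]


@dataclass(frozen=True)
class MarkerModel:
    """Two-component lognormal expression model for one marker.

    Parameters are on the natural-log scale of 8-bit gray levels; the
    background component describes ordinary blood cells, the ctc component
    the spiked subpopulation.  ``mu_ctc >= mu_bg`` is required so the
    spike-in is detectable by construction.
    """

    mu_bg: float
    sigma_bg: float
    mu_ctc: float
    sigma_ctc: float

    def __post_init__(self) -> None:
        if self.sigma_bg < 0 or self.sigma_ctc < 0:
            raise ValueError("lognormal sigma must be >= 0")
        if self.mu_ctc < self.mu_bg:
            raise ValueError("mu_ctc must be >= mu_bg for a detectable spike-in")


# Defaults chosen so the healthy-cell luminance distribution spans roughly
# the single-digit-to-low-hundreds gray range seen on real 8-bit scans, and
# CTCs sit clearly above the 95th control percentile for EpCAM but only
# weakly elevated for CSV (an epithelial vs mesenchymal marker contrast).
DEFAULT_MARKER_MODELS: dict[str, MarkerModel] = {
    "EpCAM": MarkerModel(mu_bg=math.log(14.0), sigma_bg=0.62,
                         mu_ctc=math.log(90.0), sigma_ctc=0.35),
    "CSV": MarkerModel(mu_bg=math.log(31.0), sigma_bg=0.50,
                       mu_ctc=math.log(60.0), sigma_ctc=0.40),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Scene description for one simulated scan.

    Attributes
    ----------
    image_height_px, image_width_px
        Stitched scan dimensions in pixels.
    tile_rows, tile_cols
        Grid used when the scan is cut into capture tiles (see
        :func:`ctcscan.scan_io.cut_tiles`); rendering is always whole-scene.
    n_background_cells, n_ctc, n_debris
        Object counts; all nonnegative.
    nucleus_radius_mean_log, nucleus_radius_sd_log
        Lognormal parameters of the nucleus radius in pixels.
    marker_models
        Per-marker :class:`MarkerModel`.
    background_gradient_amplitude
        Peak-to-peak amplitude (gray levels) of a smooth degree-2 polynomial
        additive background, modelling slide-to-slide staining differences.
    noise_sigma
        Gaussian sensor noise standard deviation in gray levels.
    vignetting_strength
        Radial intensity falloff fraction in [0, 1).
    bit_depth
        8 or 16.
    pixel_size_um
        Physical pixel pitch (20x slide-scanner class by default).
    """

    image_height_px: int = 256
    image_width_px: int = 256
    tile_rows: int = 1
    tile_cols: int = 1
    n_background_cells: int = 60
    n_ctc: int = 0
    n_debris: int = 0
    nucleus_radius_mean_log: float = math.log(10.0)
    nucleus_radius_sd_log: float = 0.10
    marker_models: dict[str, MarkerModel] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_MODELS))
    background_gradient_amplitude: float = 0.0
    noise_sigma: float = 0.0
    vignetting_strength: float = 0.0
    bit_depth: int = 8
    pixel_size_um: float = 0.377
    dapi_mean: float = 150.0
    dapi_jitter: float = 25.0

    def __post_init__(self) -> None:
        for name in ("image_height_px", "image_width_px", "tile_rows", "tile_cols"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("n_background_cells", "n_ctc", "n_debris"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not 0.0 <= self.vignetting_strength < 1.0:
            raise ValueError("vignetting_strength must be in [0, 1)")
        for marker in MARKERS:
            if marker not in self.marker_models:
                raise ValueError(f"marker_models missing entry for {marker}")


def analytic_marker_quantile(config: SimulationConfig, marker: str,
                             coverage_percent: float) -> float:
    """Closed-form quantile of the background marker population.

    Returns the gray level below which ``coverage_percent`` % of background
    (healthy) cells fall, i.e. the exact value a percentile-threshold
    calibration should recover from infinitely many control cells.
    """
    if not 0.0 < coverage_percent < 100.0:
        raise ValueError("coverage_percent must be in (0, 100)")
    model = config.marker_models[marker]
    if model.sigma_bg == 0.0:
        return math.exp(model.mu_bg)
    z = stats.norm.ppf(coverage_percent / 100.0)
    return math.exp(model.mu_bg + model.sigma_bg * z)


def _place_centers(rng: np.random.Generator, shape: tuple[int, int],
                   radii: np.ndarray, margin: float = 2.0,
                   max_tries: int = 2000) -> np.ndarray:
    """Dart-throwing placement with a no-overlap constraint.

    Raises if the scene cannot hold the requested objects without forcing
    overlap (packing limit).
    """
    h, w = shape
    n = len(radii)
    centers = np.empty((n, 2), dtype=float)
    for i in range(n):
        r = radii[i]
        if 2 * r + 2 >= min(h, w):
            raise ValueError("image too small for requested object size")
        placed = False
        for _ in range(max_tries):
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            if i == 0:
                placed = True
            else:
                d = np.hypot(centers[:i, 0] - cy, centers[:i, 1] - cx)
                placed = bool(np.all(d > radii[:i] + r + margin))
            if placed:
                centers[i] = (cy, cx)
                break
        if not placed:
            raise ValueError(
                f"could not place object {i + 1}/{n} without overlap; "
                "image too small for the requested object count")
    return centers


def _ellipse_coverage(shape: tuple[int, int], center: tuple[float, float],
                      a: float, b: float, theta: float) -> tuple[np.ndarray, tuple]:
    """Anti-aliased filled ellipse as a [0,1] coverage patch plus its slice."""
    h, w = shape
    cy, cx = center
    rmax = max(a, b) + 2.0
    r0 = max(int(math.floor(cy - rmax)), 0)
    r1 = min(int(math.ceil(cy + rmax)) + 1, h)
    c0 = max(int(math.floor(cx - rmax)), 0)
    c1 = min(int(math.ceil(cx + rmax)) + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = (dy * ct + dx * st) / a
    v = (-dy * st + dx * ct) / b
    rho = np.hypot(u, v)
    # 1-px soft edge: full coverage inside, linear ramp across the boundary.
    edge = min(a, b)
    cov = np.clip((1.0 - rho) * edge + 0.5, 0.0, 1.0)
    return cov, (slice(r0, r1), slice(c0, c1))


def _debris_patch(rng: np.random.Generator, size: int) -> np.ndarray:
    """Ragged low-solidity blob: thresholded smoothed noise, centre component."""
    noise = rng.standard_normal((size, size))
    smooth = ndi.gaussian_filter(noise, sigma=size / 8.0)
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    bump = np.exp(-(((yy - c) ** 2 + (xx - c) ** 2) / (2 * (size / 3.5) ** 2)))
    fieldv = smooth / (np.abs(smooth).max() + 1e-9) + 1.2 * bump
    mask = fieldv > np.percentile(fieldv, 72.0)
    lab, n = ndi.label(mask)
    if n == 0:
        mask = bump > 0.5
    else:
        centre_label = lab[int(c), int(c)]
        if centre_label == 0:
            sizes = ndi.sum(mask, lab, index=np.arange(1, n + 1))
            centre_label = int(np.argmax(sizes)) + 1
        mask = lab == centre_label
    return mask.astype(float)


def simulate_scan(config: SimulationConfig, seed: int,
                  sample_id: str = "sim", group: str = "unknown"
                  ) -> tuple[ScanSet, pd.DataFrame]:
    """Render one scan and its ground truth.

    Returns a :class:`~ctcscan.scan_io.ScanSet` (all three channels,
    co-registered) and a ground-truth DataFrame with one row per object:
    ``object_id, kind, row, col, nucleus_radius_px, lum_EpCAM, lum_CSV``.
    """
    rng = np.random.default_rng(seed)
    h, w = config.image_height_px, config.image_width_px
    shape = (h, w)
    n_cells = config.n_background_cells + config.n_ctc

    # radii: cells lognormal; debris drawn wider so its area passes the
    # nucleus-scale size filter but its shape does not look like a nucleus
    cell_radii = np.exp(rng.normal(config.nucleus_radius_mean_log,
                                   config.nucleus_radius_sd_log, size=n_cells))
    debris_radii = rng.uniform(10.0, 16.0, size=config.n_debris)
    radii = np.concatenate([cell_radii, debris_radii])
    centers = (np.empty((0, 2)) if len(radii) == 0
               else _place_centers(rng, shape, radii))

    dapi = np.zeros(shape, dtype=float)
    marker_imgs = {m: np.zeros(shape, dtype=float) for m in MARKERS}
    records: list[dict] = []

    kinds = (["cell"] * config.n_background_cells + ["ctc"] * config.n_ctc
             + ["debris"] * config.n_debris)
    for i, kind in enumerate(kinds):
        cy, cx = centers[i]
        r = radii[i]
        rec: dict = {"object_id": i, "kind": kind, "row": cy, "col": cx,
                     "nucleus_radius_px": r}
        if kind == "debris":
            size = int(2 * r) | 1
            patch = _debris_patch(rng, size)
            r0 = int(round(cy - size / 2))
            c0 = int(round(cx - size / 2))
            sl = (slice(max(r0, 0), min(r0 + size, h)),
                  slice(max(c0, 0), min(c0 + size, w)))
            p = patch[max(0, -r0):max(0, -r0) + (sl[0].stop - sl[0].start),
                      max(0, -c0):max(0, -c0) + (sl[1].stop - sl[1].start)]
            level = rng.uniform(60.0, 120.0)
            dapi[sl] = np.maximum(dapi[sl], level * p)
            for m in MARKERS:
                rec[f"lum_{m}"] = 0.0
            records.append(rec)
            continue
        # nuclei: anti-aliased ellipses, eccentricity <= 0.6 (axis ratio >= 0.8)
        ratio = rng.uniform(0.8, 1.0)
        a = r / math.sqrt(ratio)
        b = r * math.sqrt(ratio)
        theta = rng.uniform(0.0, math.pi)
        cov, sl = _ellipse_coverage(shape, (cy, cx), a, b, theta)
        level = config.dapi_mean + rng.uniform(-config.dapi_jitter,
                                               config.dapi_jitter)
        dapi[sl] = np.maximum(dapi[sl], level * cov)
        # surface-marker halo: nuclear mask dilated by 2 px, constant at the
        # cell's drawn expression level
        halo = ndi.binary_dilation(cov >= 0.5, iterations=2)
        for m in MARKERS:
            model = config.marker_models[m]
            if kind == "ctc":
                lum = math.exp(rng.normal(model.mu_ctc, model.sigma_ctc))
            else:
                lum = math.exp(rng.normal(model.mu_bg, model.sigma_bg))
            vmax = 2 ** config.bit_depth - 1
            lum = min(lum, float(vmax))
            marker_imgs[m][sl] = np.maximum(marker_imgs[m][sl], lum * halo)
            rec[f"lum_{m}"] = lum
        records.append(rec)

    # degradations, applied last: additive gradient, vignetting, noise, clip
    vmax = 2 ** config.bit_depth - 1
    degr = []
    if config.background_gradient_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        y = yy / max(h - 1, 1) - 0.5
        x = xx / max(w - 1, 1) - 0.5
        coef = rng.standard_normal(5)
        poly = (coef[0] * y + coef[1] * x + coef[2] * y * x
                + coef[3] * y ** 2 + coef[4] * x ** 2)
        span = poly.max() - poly.min()
        if span > 0:
            poly = (poly - poly.min()) / span * config.background_gradient_amplitude
        degr.append(("gradient", poly))
    channels = {}
    planes = {"DAPI": dapi, **marker_imgs}
    for ch in CHANNELS:
        img = planes[ch].copy()
        for _, poly in degr:
            img = img + poly
        if config.vignetting_strength > 0:
            yy, xx = np.mgrid[0:h, 0:w]
            ry = (yy / max(h - 1, 1) - 0.5) * 2
            rx = (xx / max(w - 1, 1) - 0.5) * 2
            img = img * (1.0 - config.vignetting_strength * (ry ** 2 + rx ** 2) / 2)
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=shape)
        dtype = np.uint8 if config.bit_depth == 8 else np.uint16
        channels[ch] = np.clip(np.rint(img), 0, vmax).astype(dtype)

    truth = pd.DataFrame(
        records, columns=["object_id", "kind", "row", "col",
                          "nucleus_radius_px"] + [f"lum_{m}" for m in MARKERS])
    scan = ScanSet(sample_id=sample_id, group=group, channels=channels,
                   pixel_size_um=config.pixel_size_um,
                   provenance={"simulated": True, "seed": int(seed)})
    return scan, truth


def simulate_cohort(n_case: int, n_control: int, ctc_poisson_mean: float,
                    config: SimulationConfig, seed: int
                    ) -> tuple[pd.DataFrame, list[ScanSet], list[pd.DataFrame]]:
    """Simulate a case/control cohort of scans.

    Controls carry zero CTCs; each case draws its CTC count from a Poisson
    with the given mean (per 5 mL blood equivalent).  Per-sample seeds are
    derived from the cohort seed and recorded in the sample sheet, so any
    single sample can be regenerated in isolation.
    """
    if n_case < 0 or n_control < 0:
        raise ValueError("cohort sizes must be >= 0")
    rng = np.random.default_rng(seed)
    rows, scans, truths = [], [], []
    for i in range(n_case + n_control):
        is_case = i < n_case
        sid = f"case_{i:03d}" if is_case else f"control_{i - n_case:03d}"
        group = "case" if is_case else "control"
        n_ctc = int(rng.poisson(ctc_poisson_mean)) if is_case else 0
        sample_seed = int(rng.integers(0, 2 ** 31 - 1))
        cfg = replace(config, n_ctc=n_ctc)
        scan, truth = simulate_scan(cfg, sample_seed, sample_id=sid, group=group)
        rows.append({"sample_id": sid, "group": group, "n_ctc_true": n_ctc,
                     "seed": sample_seed})
        scans.append(scan)
        truths.append(truth)
    sheet = pd.DataFrame(rows, columns=["sample_id", "group", "n_ctc_true", "seed"])
    return sheet, scans, truths


def match_regions_to_truth(regions, truth: pd.DataFrame,
                           max_dist_px: float = 12.0) -> list[str | None]:
    """Assign each segmented region the kind of the nearest ground-truth object.

    Greedy nearest-centroid matching within ``max_dist_px``; unmatched
    regions get ``None``.  Used to score segmentation and classification
    against the simulator.
    """
    kinds: list[str | None] = []
    if len(truth) == 0:
        return [None] * len(regions)
    t_rc = truth[["row", "col"]].to_numpy(dtype=float)
    for reg in regions:
        cy, cx = reg.centroid
        d = np.hypot(t_rc[:, 0] - cy, t_rc[:, 1] - cx)
        j = int(np.argmin(d))
        kinds.append(str(truth["kind"].iloc[j]) if d[j] <= max_dist_px else None)
    return kinds
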