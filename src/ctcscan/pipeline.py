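"""End-to-end orchestration: scan → cells → luminance → thresholds → report.

Thin glue over the stage modules, used both by the CLI and programmatically.
Each helper is pure given its inputs, so any stage can be re-run in
isolation from persisted intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration, cell_filter, diagnostics, luminance, segmentation
from .scan_io import ScanSet
from .segmentation import CellRegion

__all__ = ["SegmentationParams", "process_scan", "pooled_luminance",
           "analyze_cohort", "synthetic_annotation_set",
           "desk_scale_config", "run_simulated_cohort"]


@dataclass(frozen=True)
class SegmentationParams:
    method: str = "otsu"
    fixed_value: float | None = None
    closing_iterations: int = 3
    min_marker_distance_px: int = 10
    area_min_um2: float = 20.0
    area_max_um2: float = 2000.0
    cutout_margin_px: int = 10


def process_scan(scan: ScanSet, params: SegmentationParams = SegmentationParams(),
                 classifier: cell_filter.ClassifierModel | None = None
                 ) -> tuple[pd.DataFrame, list[CellRegion], np.ndarray]:
    """Segment one scan, optionally filter debris, and measure luminance.

    Returns (per-cell luminance table, kept regions, labelled raster).
    """
    labels, regions = segmentation.segment_dapi(
        scan.channels["DAPI"], scan.pixel_size_um, method=params.method,
        fixed_value=params.fixed_value,
        closing_iterations=params.closing_iterations,
        min_marker_distance_px=params.min_marker_distance_px,
        area_min_um2=params.area_min_um2, area_max_um2=params.area_max_um2)
    if classifier is not None and regions:
        gray = segmentation.to_grayscale(scan.channels["DAPI"])
        feats = cell_filter.features_frame(regions, gray, labels)
        is_cell, _ = cell_filter.classify_regions(classifier, feats)
        regions = [r for r, keep in zip(regions, is_cell) if keep]
    table = luminance.luminance_table(scan, regions, labels,
                                      margin_px=params.cutout_margin_px)
    return table, regions, labels


def pooled_luminance(scans: list[ScanSet],
                     params: SegmentationParams = SegmentationParams(),
                     classifier: cell_filter.ClassifierModel | None = None
                     ) -> pd.DataFrame:
    tables = [process_scan(s, params, classifier)[0] for s in scans]
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)


def desk_scale_config(**overrides):
    """Default desk-scale scene for cohort experiments.

    Small fields (224 px square, 25 background cells per 5 mL-equivalent
    sample) with realistic noise and a staining gradient; chosen so a full
    multi-seed cohort experiment runs on a laptop while preserving the
    statistical structure of whole-slide cohorts, with enough free area to
    pack the largest plausible spike-in without forced overlap.
    """
    from .simulate import SimulationConfig
    base = dict(image_height_px=224, image_width_px=224,
                n_background_cells=25, noise_sigma=2.0,
                background_gradient_amplitude=8.0)
    base.update(overrides)
    return SimulationConfig(**base)


def run_simulated_cohort(poisson_mean: float, seed: int, n_case: int = 38,
                         n_control: int = 17, n_training_controls: int = 10,
                         config=None) -> CohortAnalysis:
    """Simulate and fully analyze one case/control cohort.

    Cases carry Poisson(``poisson_mean``) spiked CTCs; thresholds are
    calibrated on ``n_training_controls`` random controls and diagnostics
    evaluated on the cases plus the held-out controls.
    """
    from .simulate import simulate_cohort
    if config is None:
        config = desk_scale_config()
    sheet, scans, _ = simulate_cohort(n_case, n_control, poisson_mean,
                                      config, seed)
    lum = pooled_luminance(scans)
    return analyze_cohort(sheet, lum,
                          n_training_controls=n_training_controls, seed=seed)


def synthetic_annotation_set(n_annotations: int, seed: int,
                             config=None,
                             params: SegmentationParams = SegmentationParams()
                             ) -> tuple[pd.DataFrame, np.ndarray]:
    """Build a labelled annotation set from simulated scans.

    Simulates mixed cell/debris scenes, segments them, assigns each region
    the ground-truth kind of its nearest simulated object, and extracts
    features — an in-silico stand-in for a curated annotation library of
    cell and non-cell cutouts.  Returns (feature frame, labels) with labels
    in {"cell", "non_cell"} (spiked CTCs count as cells).
    """
    from .simulate import SimulationConfig, match_regions_to_truth, simulate_scan
    if config is None:
        config = SimulationConfig(image_height_px=512, image_width_px=512,
                                  n_background_cells=40, n_debris=14,
                                  noise_sigma=2.0)
    feats, labels_out = [], []
    scan_seed = seed
    while sum(len(f) for f in feats) < n_annotations:
        scan, truth = simulate_scan(config, scan_seed)
        scan_seed += 1
        labels, regions = segmentation.segment_dapi(
            scan.channels["DAPI"], scan.pixel_size_um, method=params.method,
            closing_iterations=params.closing_iterations,
            min_marker_distance_px=params.min_marker_distance_px,
            area_min_um2=params.area_min_um2,
            area_max_um2=params.area_max_um2)
        kinds = match_regions_to_truth(regions, truth)
        keep = [i for i, k in enumerate(kinds) if k is not None]
        regions = [regions[i] for i in keep]
        gray = segmentation.to_grayscale(scan.channels["DAPI"])
        feats.append(cell_filter.features_frame(regions, gray, labels))
        labels_out.extend("non_cell" if kinds[i] == "debris" else "cell"
                          for i in keep)
    df = pd.concat(feats, ignore_index=True).iloc[:n_annotations]
    return df, np.asarray(labels_out[:n_annotations])


@dataclass
class CohortAnalysis:
    thresholds: list
    counts: pd.DataFrame
    report: diagnostics.CohortReport
    training_controls: list[str] = field(default_factory=list)
    test_samples: list[str] = field(default_factory=list)


def analyze_cohort(sample_sheet: pd.DataFrame, lum: pd.DataFrame,
                   n_training_controls: int = 10, seed: int = 0,
                   coverages=calibration.DEFAULT_COVERAGES,
                   positivity_cutoff: int | None = None,
                   clinical: pd.DataFrame | None = None) -> CohortAnalysis:
    """Calibrate thresholds on random training controls, evaluate on the rest.

    Training controls are excluded from the diagnostic test set (cases plus
    held-out controls), mirroring a train/test split of the healthy cohort.
    """
    controls = sample_sheet.loc[sample_sheet["group"] == "control",
                                "sample_id"].tolist()
    train_ids, held_ids = calibration.select_training_controls(
        controls, n_training_controls, seed)
    thresholds = calibration.calibrate_thresholds(lum, train_ids,
                                                  coverages=tuple(coverages))
    test_sheet = sample_sheet[~sample_sheet["sample_id"].isin(train_ids)]
    counts = diagnostics.count_table(lum, thresholds, test_sheet)
    report = diagnostics.cohort_report(counts,
                                       positivity_cutoff=positivity_cutoff,
                                       clinical=clinical)
    return CohortAnalysis(thresholds=thresholds, counts=counts, report=report,
                          training_controls=train_ids,
                          test_samples=test_sheet["sample_id"].tolist())
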