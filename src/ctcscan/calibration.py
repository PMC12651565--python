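"""Coverage-threshold calibration from healthy-control cell populations.

A marker threshold at coverage C is the luminance below or at which C% of
pooled healthy-control cells fall; candidate cells in test samples are then
counted as those *exceeding* the threshold.  The nearest-rank (ceiling)
order statistic is used so the stated coverage holds as an inequality:
the m-th smallest of n pooled values with m = ceil(C/100 · n).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

DEFAULT_COVERAGES = (99.0, 95.0, 90.0)

__all__ = ["DEFAULT_COVERAGES", "CoverageThreshold",
           "select_training_controls", "control_threshold",
           "calibrate_thresholds", "save_thresholds", "load_thresholds"]


@dataclass(frozen=True)
class CoverageThreshold:
    """A marker luminance threshold at a control-coverage level."""

    marker: str
    coverage_percent: float
    threshold: float
    n_control_cells: int
    control_sample_ids: tuple[str, ...] = ()


def select_training_controls(control_ids: list[str], k: int, seed: int
                             ) -> tuple[list[str], list[str]]:
    """Seeded random split of control samples into training and held-out sets.

    The training controls calibrate thresholds; held-out controls join the
    diagnostic test set so threshold calibration and evaluation never share
    samples.
    """
    if k > len(control_ids):
        raise ValueError(f"cannot select {k} of {len(control_ids)} controls")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(control_ids), size=k, replace=False)
    chosen_set = set(int(i) for i in chosen)
    train = [control_ids[i] for i in sorted(chosen_set)]
    held = [c for i, c in enumerate(control_ids) if i not in chosen_set]
    return train, held


def control_threshold(values: np.ndarray, coverage_percent: float,
                      marker: str = "", sample_ids: tuple[str, ...] = (),
                      method: str = "nearest_rank") -> CoverageThreshold:
    """Threshold covering ``coverage_percent`` % of pooled control cells.

    nearest_rank (default): the m-th smallest value, m = ceil(C/100 · n),
    guaranteeing at least C% of control cells are ≤ threshold.  A linear
    interpolation alternative is available via ``method="linear"``.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot calibrate a threshold from an empty set")
    if not 0.0 < coverage_percent < 100.0:
        raise ValueError("coverage_percent must be in (0, 100)")
    srt = np.sort(vals)
    if method == "nearest_rank":
        m = math.ceil(coverage_percent / 100.0 * vals.size)
        thr = float(srt[m - 1])
    elif method == "linear":
        thr = float(np.quantile(vals, coverage_percent / 100.0))
    else:
        raise ValueError(f"unknown percentile method {method!r}")
    return CoverageThreshold(marker=marker, coverage_percent=coverage_percent,
                             threshold=thr, n_control_cells=int(vals.size),
                             control_sample_ids=tuple(sample_ids))


def calibrate_thresholds(luminance, training_ids: list[str],
                         markers: tuple[str, ...] = ("EpCAM", "CSV"),
                         coverages: tuple[float, ...] = DEFAULT_COVERAGES,
                         method: str = "nearest_rank"
                         ) -> list[CoverageThreshold]:
    """Calibrate all marker × coverage thresholds from a luminance table.

    ``luminance`` is the pooled per-cell table (as produced by
    :func:`ctcscan.luminance.luminance_table`, concatenated over samples);
    only rows from ``training_ids`` contribute.
    """
    sub = luminance[luminance["sample_id"].isin(training_ids)]
    out = []
    for marker in markers:
        vals = sub[f"{marker}_corrected_mean"].to_numpy(dtype=float)
        for cov in coverages:
            out.append(control_threshold(vals, cov, marker=marker,
                                         sample_ids=tuple(training_ids),
                                         method=method))
    return out


def save_thresholds(thresholds: list[CoverageThreshold],
                    path: str | Path) -> None:
    payload = [asdict(t) for t in thresholds]
    for t in payload:
        t["control_sample_ids"] = list(t["control_sample_ids"])
    Path(path).write_text(json.dumps(payload, indent=2))


def load_thresholds(path: str | Path) -> list[CoverageThreshold]:
    payload = json.loads(Path(path).read_text())
    return [CoverageThreshold(
        marker=t["marker"], coverage_percent=t["coverage_percent"],
        threshold=t["threshold"], n_control_cells=t["n_control_cells"],
        control_sample_ids=tuple(t.get("control_sample_ids", ())))
        for t in payload]
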