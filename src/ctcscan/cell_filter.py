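"""Cell vs non-cell (debris, optical noise) sorting of segmented regions.

Real assays curate an annotation library of cell and non-cell cutouts and
train a classifier to pre-sort candidate regions before human review.  Here
that role is filled by a transparent feature-based model: shape and DAPI
texture features per region, a class-weighted regularized logistic
regression, and an explicit review-queue export/import so human overrides
always take precedence over machine labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .segmentation import CellRegion

FEATURE_NAMES = [
    "area_um2", "eccentricity", "solidity", "circularity", "perimeter_px",
    "dapi_mean", "dapi_std", "dapi_entropy", "edge_gradient_mean",
    "bbox_aspect_ratio",
]

__all__ = ["FEATURE_NAMES", "ClassifierModel", "extract_features",
           "features_frame", "train_classifier", "classify_regions",
           "export_review_queue", "import_review"]


@dataclass
class ClassifierModel:
    """A fitted cell/non-cell classifier with its feature schema."""

    pipeline: Pipeline
    feature_names: list[str]
    decision_threshold: float
    cv_accuracy: float
    n_train: int
    class_balance: dict[str, int]
    seed: int


def extract_features(region: CellRegion, dapi_gray: np.ndarray,
                     labels: np.ndarray | None = None) -> np.ndarray:
    """Shape + DAPI texture feature vector for one region.

    When the labelled raster is supplied the membership mask is taken from
    it directly; otherwise it is reconstructed from the DAPI patch.
    Conventions for degenerate regions: perimeter is floored at 1 px and
    circularity (4πA/P²) is capped at 4π so a 1-px region stays finite.
    Features depend only on the region's own pixels, so they are invariant
    to translating the region within the scan.
    """
    r0, c0, r1, c1 = region.bbox
    sub = dapi_gray[r0:r1, c0:c1].astype(float)
    if labels is not None:
        mask = labels[r0:r1, c0:c1] == region.label_id
    else:
        mask = _region_mask(region, dapi_gray)
    vals = sub[mask]
    area = float(region.area_px)
    perim = max(float(region.perimeter_px), 1.0)
    circularity = min(4.0 * np.pi * area / perim ** 2, 4.0 * np.pi)
    hist, _ = np.histogram(np.clip(vals, 0, 255), bins=32, range=(0, 255))
    p = hist / max(hist.sum(), 1)
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum()) if len(p) else 0.0
    boundary = mask & ~ndi.binary_erosion(mask)
    gy = ndi.sobel(sub, axis=0)
    gx = ndi.sobel(sub, axis=1)
    grad = np.hypot(gy, gx)
    edge_grad = float(grad[boundary].mean()) if boundary.any() else 0.0
    h = max(r1 - r0, 1)
    w = max(c1 - c0, 1)
    aspect = max(h, w) / min(h, w)
    return np.array([
        region.area_um2, region.eccentricity, region.solidity, circularity,
        perim, float(vals.mean()), float(vals.std()), entropy, edge_grad,
        aspect,
    ])


def _region_mask(region: CellRegion, dapi_gray: np.ndarray) -> np.ndarray:
    """Membership mask within the bbox, reconstructed from the DAPI patch.

    The segmented foreground is everything above zero-ish background in the
    patch; for robustness the patch's own Otsu split is used when the patch
    is not flat, restricted to the connected component nearest the centroid.
    """
    r0, c0, r1, c1 = region.bbox
    sub = dapi_gray[r0:r1, c0:c1].astype(float)
    if sub.size == 1:
        return np.ones_like(sub, dtype=bool)
    lo, hi = sub.min(), sub.max()
    if hi - lo < 1e-9:
        return np.ones_like(sub, dtype=bool)
    mask = sub > (lo + 0.25 * (hi - lo))
    lab, n = ndi.label(mask)
    if n > 1:
        cy = region.centroid[0] - r0
        cx = region.centroid[1] - c0
        iy = int(np.clip(round(cy), 0, sub.shape[0] - 1))
        ix = int(np.clip(round(cx), 0, sub.shape[1] - 1))
        target = lab[iy, ix]
        if target == 0:
            sizes = ndi.sum(mask, lab, index=np.arange(1, n + 1))
            target = int(np.argmax(sizes)) + 1
        mask = lab == target
    if not mask.any():
        mask = np.ones_like(sub, dtype=bool)
    return mask


def features_frame(regions: list[CellRegion], dapi_gray: np.ndarray,
                   labels: np.ndarray | None = None) -> pd.DataFrame:
    rows = [extract_features(r, dapi_gray, labels) for r in regions]
    df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    df.insert(0, "label_id", [r.label_id for r in regions])
    return df


def train_classifier(features: np.ndarray | pd.DataFrame,
                     labels: list[str] | np.ndarray,
                     seed: int = 0,
                     decision_threshold: float = 0.5,
                     min_annotations: int = 20) -> ClassifierModel:
    """Train the cell/non-cell model on an annotation set.

    Labels are ``{"cell", "non_cell"}``; both classes must be present and
    at least ``min_annotations`` examples supplied.  The model is a
    standardized, class-weighted L2 logistic regression; held-out accuracy
    is estimated by seeded stratified 5-fold CV and stored on the model.
    """
    if isinstance(features, pd.DataFrame):
        features = features[FEATURE_NAMES].to_numpy()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(X) < min_annotations:
        raise ValueError(
            f"insufficient annotations: {len(X)} < {min_annotations}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("annotations contain a single class; need both "
                         "cell and non_cell examples")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("logit", LogisticRegression(C=1.0, class_weight="balanced",
                                     max_iter=2000, random_state=seed)),
    ])
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    acc = float(cross_val_score(pipe, X, (y == "cell").astype(int),
                                cv=cv, scoring="accuracy").mean())
    pipe.fit(X, (y == "cell").astype(int))
    return ClassifierModel(
        pipeline=pipe, feature_names=list(FEATURE_NAMES),
        decision_threshold=float(decision_threshold), cv_accuracy=acc,
        n_train=len(X),
        class_balance={str(c): int(n) for c, n in zip(classes, counts)},
        seed=seed)


def classify_regions(model: ClassifierModel,
                     features: np.ndarray | pd.DataFrame
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Score regions; returns (is_cell boolean array, cell probability).

    A region is called a cell when its probability is at least the model's
    decision threshold (threshold 0 keeps everything).
    """
    if isinstance(features, pd.DataFrame):
        if list(features.columns[-len(FEATURE_NAMES):]) != FEATURE_NAMES and \
                not set(FEATURE_NAMES).issubset(features.columns):
            raise ValueError("feature schema mismatch")
        features = features[FEATURE_NAMES].to_numpy()
    X = np.asarray(features, dtype=float)
    if X.shape[0] == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if X.shape[1] != len(model.feature_names):
        raise ValueError("feature schema mismatch: expected "
                         f"{len(model.feature_names)} features, got {X.shape[1]}")
    proba = model.pipeline.predict_proba(X)[:, 1]
    return proba >= model.decision_threshold, proba


def export_review_queue(regions: list[CellRegion], scores: np.ndarray,
                        scan, out_dir: str | Path,
                        margin_px: int = 10,
                        decision_threshold: float = 0.5) -> pd.DataFrame:
    """Write a reviewer gallery (per-channel PNG panels) and review CSV.

    The CSV carries one row per region with the machine call and an empty
    ``review_label`` column for overrides; it round-trips through
    :func:`import_review`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    h, w = scan.shape
    for reg, score in zip(regions, scores):
        r0, c0, r1, c1 = reg.bbox
        sl = (slice(max(r0 - margin_px, 0), min(r1 + margin_px, h)),
              slice(max(c0 - margin_px, 0), min(c1 + margin_px, w)))
        panels = [np.asarray(scan.channels[ch][sl]) for ch in scan.channels]
        panel = np.concatenate([_to_u8(p) for p in panels], axis=1)
        png = out / f"region_{reg.label_id:05d}.png"
        iio.imwrite(png, panel)
        rows.append({"label_id": reg.label_id, "score": float(score),
                     "machine_label": "cell" if score >= decision_threshold
                     else "non_cell",
                     "review_label": "", "cutout": png.name})
    df = pd.DataFrame(rows, columns=["label_id", "score", "machine_label",
                                     "review_label", "cutout"])
    df.to_csv(out / "review_queue.csv", index=False)
    return df


def _to_u8(arr: np.ndarray) -> np.ndarray:
    arr = arr.astype(float)
    top = arr.max() if arr.max() > 0 else 1.0
    return np.clip(arr / top * 255.0, 0, 255).astype(np.uint8)


def import_review(review: pd.DataFrame | str | Path,
                  known_label_ids: set[int] | None = None) -> pd.DataFrame:
    """Merge reviewer overrides; human labels strictly win over machine labels.

    Returns the review table with a ``final_label`` column.  Rows whose
    ``label_id`` is not in ``known_label_ids`` (when given) raise.
    """
    if not isinstance(review, pd.DataFrame):
        review = pd.read_csv(review, keep_default_na=False)
    review = review.copy()
    if known_label_ids is not None:
        unknown = set(review["label_id"].astype(int)) - set(known_label_ids)
        if unknown:
            raise ValueError(f"review references unknown region ids: "
                             f"{sorted(unknown)}")
    overrides = review["review_label"].astype(str).str.strip()
    bad = ~overrides.isin(["", "cell", "non_cell"])
    if bad.any():
        raise ValueError(f"invalid review labels: "
                         f"{sorted(overrides[bad].unique())}")
    review["final_label"] = np.where(overrides != "", overrides,
                                     review["machine_label"])
    review["overridden"] = overrides != ""
    return review
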