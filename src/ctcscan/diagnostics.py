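"""Candidate-cell counting and diagnostic performance statistics.

Per sample, candidate CTCs are the cells whose corrected marker luminance
*strictly exceeds* a control-calibrated coverage threshold; counts are
reported per 5 mL blood.  Diagnostic evaluation across a case/control
cohort uses:

* Mann–Whitney U (exact enumeration in the small untied regime, midrank
  tie-corrected normal approximation otherwise);
* ROC analysis with the AUC computed from midranks (identical to U/(mn),
  ties counted ½), DeLong structural-component standard errors, and
  logit-scale 95% confidence intervals;
* the Youden J index to choose the operating integer cutoff
  (sensitivity + specificity − 1, smallest maximizing cutoff);
* the paired DeLong test to compare AUCs of two assays scored on the same
  samples (covariance of the structural components included);
* Fisher's exact test (two-sided probability-mass convention) and the
  df=1 chi-square without continuity correction for 2×2 association tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CoverageThreshold

__all__ = [
    "SampleCount", "ROCAnalysis", "PairedAUCComparison",
    "count_candidates", "count_table", "detection_rate", "mann_whitney_u",
    "auc_from_counts", "roc_auc", "youden_optimal_cutoff",
    "delong_components", "delong_paired_test",
    "fisher_exact_2x2", "chi_square_2x2", "cohort_report",
]


@dataclass(frozen=True)
class SampleCount:
    """Number of threshold-exceeding cells for one sample, per 5 mL blood."""

    sample_id: str
    group: str
    marker: str
    coverage_percent: float
    count: int
    blood_volume_ml: float = 5.0


@dataclass
class ROCAnalysis:
    marker: str
    coverage_percent: float
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    cutoff_table: pd.DataFrame
    optimal_cutoff: int
    n_case: int
    n_control: int


@dataclass(frozen=True)
class PairedAUCComparison:
    auc_a: float
    auc_b: float
    delta_auc: float
    var_delta: float
    z: float
    p_value: float


def count_candidates(luminance: pd.DataFrame, threshold: CoverageThreshold,
                     sample_id: str, group: str = "unknown",
                     blood_volume_ml: float = 5.0) -> SampleCount:
    """Count cells strictly exceeding the threshold for one sample.

    Ties at the threshold are negative ("exceeding" is strict).  Counts from
    other blood volumes are normalized to cells / 5 mL, rounding half up.
    """
    sub = luminance[luminance["sample_id"] == sample_id]
    vals = sub[f"{threshold.marker}_corrected_mean"].to_numpy(dtype=float)
    raw = int((vals > threshold.threshold).sum())
    if blood_volume_ml != 5.0:
        raw = int(math.floor(raw * 5.0 / blood_volume_ml + 0.5))
    return SampleCount(sample_id=sample_id, group=group,
                       marker=threshold.marker,
                       coverage_percent=threshold.coverage_percent,
                       count=raw, blood_volume_ml=5.0)


def count_table(luminance: pd.DataFrame, thresholds: list[CoverageThreshold],
                sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """All samples × thresholds count table (long form)."""
    rows = []
    for _, s in sample_sheet.iterrows():
        for thr in thresholds:
            sc = count_candidates(luminance, thr, s["sample_id"],
                                  group=s["group"])
            rows.append({"sample_id": sc.sample_id, "group": sc.group,
                         "marker": sc.marker,
                         "coverage_percent": sc.coverage_percent,
                         "count": sc.count})
    return pd.DataFrame(rows, columns=["sample_id", "group", "marker",
                                       "coverage_percent", "count"])


def detection_rate(counts: list[SampleCount] | pd.DataFrame,
                   group: str) -> float:
    """Fraction of samples in a group with at least one candidate cell."""
    if isinstance(counts, pd.DataFrame):
        sub = counts[counts["group"] == group]["count"].to_numpy()
    else:
        sub = np.array([c.count for c in counts if c.group == group])
    if sub.size == 0:
        raise ValueError(f"no samples in group {group!r}")
    return float((sub >= 1).mean())


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when n_x + n_y ≤ 12 and there are no ties; otherwise
    the midrank statistic with tie-corrected normal approximation
    (continuity-corrected).  Returns (U for x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    if x.size + y.size <= 12 and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def auc_from_counts(case_vals, control_vals) -> float:
    """AUC by midranks: P(case > control) + ½ P(tie); equals U/(mn) exactly."""
    case_vals = np.asarray(case_vals, dtype=float)
    control_vals = np.asarray(control_vals, dtype=float)
    m, n = case_vals.size, control_vals.size
    if m == 0 or n == 0:
        raise ValueError("both groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([case_vals, control_vals]))
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


def delong_components(case_vals, control_vals
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """DeLong structural components (midrank formulation).

    Returns (auc, V10 per case, V01 per control) where
    V10_i = mean_j ψ(case_i, control_j), V01_j = mean_i ψ, with ψ = 1, ½, 0
    for case >, =, < control.
    """
    xs = np.asarray(case_vals, dtype=float)
    ys = np.asarray(control_vals, dtype=float)
    m, n = xs.size, ys.size
    z = np.concatenate([xs, ys])
    tz = stats.rankdata(z)
    tx = stats.rankdata(xs)
    ty = stats.rankdata(ys)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = v10.size, v01.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return s10 / m + s01 / n


def _logit_ci(auc: float, se: float, level_z: float = 1.959963984540054
              ) -> tuple[float, float]:
    if se == 0.0:
        return (auc, auc)
    eps = 1e-6
    a = min(max(auc, eps), 1 - eps)
    logit = math.log(a / (1 - a))
    dse = se / (a * (1 - a))
    lo = 1.0 / (1.0 + math.exp(-(logit - level_z * dse)))
    hi = 1.0 / (1.0 + math.exp(-(logit + level_z * dse)))
    return (lo, hi)


def roc_auc(case_counts, control_counts, marker: str = "",
            coverage_percent: float = float("nan")) -> ROCAnalysis:
    """ROC analysis of per-sample counts (cases vs controls).

    AUC from midranks; SE by DeLong structural components; 95% CI computed
    on the logit scale and back-transformed (asymmetric, respects [0, 1]).
    The cutoff table scans every integer cutoff c with positivity defined
    as count ≥ c, reporting SN, SP, PPV, NPV and Youden J.
    """
    xs = np.asarray(case_counts, dtype=float)
    ys = np.asarray(control_counts, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both groups must be nonempty")
    auc, v10, v01 = delong_components(xs, ys)
    se = math.sqrt(max(_auc_variance(v10, v01), 0.0))
    ci = _logit_ci(auc, se)
    cutoffs = np.unique(np.concatenate([[0.0], xs, ys])).astype(int)
    cutoffs = np.unique(np.concatenate([cutoffs, cutoffs + 1]))
    rows = []
    for c in cutoffs:
        tp = float((xs >= c).sum())
        fn = float((xs < c).sum())
        tn = float((ys < c).sum())
        fp = float((ys >= c).sum())
        sn = tp / (tp + fn)
        sp = tn / (tn + fp)
        ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
        npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
        rows.append({"cutoff": int(c), "SN": sn, "SP": sp, "PPV": ppv,
                     "NPV": npv, "J": sn + sp - 1.0})
    table = pd.DataFrame(rows)
    roc = ROCAnalysis(marker=marker, coverage_percent=coverage_percent,
                      auc=auc, auc_se=se, ci95=ci, cutoff_table=table,
                      optimal_cutoff=0, n_case=xs.size, n_control=ys.size)
    roc.optimal_cutoff = youden_optimal_cutoff(roc)
    return roc


def youden_optimal_cutoff(roc: ROCAnalysis) -> int:
    """Smallest integer cutoff attaining the maximum Youden J index."""
    t = roc.cutoff_table
    if len(t) == 0:
        raise ValueError("ROC has no cutoff rows")
    jmax = t["J"].max()
    return int(t.loc[t["J"] >= jmax - 1e-12, "cutoff"].min())


def delong_paired_test(scores_a, scores_b, labels) -> PairedAUCComparison:
    """Paired DeLong test comparing the AUCs of two assays on the same samples.

    ``labels`` is boolean/0-1 (1 = case).  The variance of ΔAUC includes the
    covariance of the paired structural components.  A degenerate zero
    variance (e.g. both assays constant) yields p = 1 with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    lab = np.asarray(labels).astype(bool)
    if a.shape != b.shape or a.shape != lab.shape:
        raise ValueError("assays and labels must align on the same samples")
    auc_a, v10a, v01a = delong_components(a[lab], a[~lab])
    auc_b, v10b, v01b = delong_components(b[lab], b[~lab])
    m, n = int(lab.sum()), int((~lab).sum())
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    delta = auc_a - auc_b
    if var_delta <= 0:
        if abs(delta) > 0:
            warnings.warn("zero DeLong variance with nonzero AUC difference",
                          stacklevel=2)
        else:
            warnings.warn("degenerate DeLong variance; p set to 1",
                          stacklevel=2)
        return PairedAUCComparison(auc_a, auc_b, delta, 0.0, 0.0, 1.0)
    z = delta / math.sqrt(var_delta)
    p = 2.0 * stats.norm.sf(abs(z))
    return PairedAUCComparison(auc_a, auc_b, delta, var_delta, float(z),
                               float(min(p, 1.0)))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table, probability-mass convention.

    With margins fixed, p is the sum of hypergeometric probabilities of all
    tables whose probability does not exceed the observed table's (with the
    customary 1+1e-7 tie slack).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integer counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, n1, total = a + b, a + c, a + b + c + d
    if total == 0:
        return 1.0
    lo = max(0, r1 + n1 - total)
    hi = min(r1, n1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, total, n1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) for a 2×2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    for name, margin in (("row", row), ("column", col)):
        if (margin == 0).any():
            idx = int(np.argmin(margin))
            raise ValueError(f"zero {name} margin at index {idx}; "
                             "chi-square requires all margins > 0")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


@dataclass
class CohortReport:
    roc_table: pd.DataFrame
    delong_matrix: pd.DataFrame
    detection_rates: pd.DataFrame
    positivity: pd.DataFrame
    association: pd.DataFrame = field(default_factory=pd.DataFrame)


def cohort_report(counts: pd.DataFrame, positivity_cutoff: int | None = None,
                  clinical: pd.DataFrame | None = None,
                  reference_assay: tuple[str, float] = ("EpCAM", 95.0)
                  ) -> CohortReport:
    """Aggregate a counts table into the full diagnostic report.

    Produces a per-assay ROC table (AUC, CI, SN/SP/PPV/NPV at the Youden
    cutoff), the pairwise DeLong p matrix (unit diagonal), detection rates
    per group, and positivity calls at ``positivity_cutoff`` (the reference
    assay's Youden cutoff when None; the field convention is ≥ 2 cells/5 mL).
    Optional clinical 2×2 association tables use Fisher's exact test.
    """
    if counts["group"].isna().any() or (counts["group"] == "").any():
        raise ValueError("missing group labels in counts table")
    assays = (counts[["marker", "coverage_percent"]]
              .drop_duplicates().itertuples(index=False))
    assays = [(a.marker, a.coverage_percent) for a in assays]
    roc_rows, rocs = [], {}
    wide = counts.pivot_table(index=["sample_id", "group"],
                              columns=["marker", "coverage_percent"],
                              values="count").reset_index()
    labels = (wide["group"] == "case").to_numpy()
    for marker, cov in assays:
        vals = wide[(marker, cov)].to_numpy(dtype=float)
        roc = roc_auc(vals[labels], vals[~labels], marker=marker,
                      coverage_percent=cov)
        rocs[(marker, cov)] = roc
        best = roc.cutoff_table[roc.cutoff_table["cutoff"]
                                == roc.optimal_cutoff].iloc[0]
        roc_rows.append({
            "assay": f"{marker} ({cov:g})", "marker": marker,
            "coverage_percent": cov, "cutoff": roc.optimal_cutoff,
            "AUC": roc.auc, "CI_low": roc.ci95[0], "CI_high": roc.ci95[1],
            "SN": best["SN"], "SP": best["SP"], "PPV": best["PPV"],
            "NPV": best["NPV"]})
    roc_table = pd.DataFrame(roc_rows)

    names = [f"{m} ({c:g})" for m, c in assays]
    dl = pd.DataFrame(np.ones((len(assays), len(assays))), index=names,
                      columns=names)
    for i, (m1, c1) in enumerate(assays):
        for j, (m2, c2) in enumerate(assays):
            if j <= i:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp = delong_paired_test(
                    wide[(m1, c1)].to_numpy(dtype=float),
                    wide[(m2, c2)].to_numpy(dtype=float), labels)
            dl.iloc[i, j] = cmp.p_value
            dl.iloc[j, i] = cmp.p_value

    det_rows = []
    for marker, cov in assays:
        sub = counts[(counts["marker"] == marker)
                     & (counts["coverage_percent"] == cov)]
        for grp in sorted(sub["group"].unique()):
            det_rows.append({"assay": f"{marker} ({cov:g})", "group": grp,
                             "detection_rate": detection_rate(sub, grp)})
    det = pd.DataFrame(det_rows)

    ref = rocs.get(reference_assay)
    cutoff = (positivity_cutoff if positivity_cutoff is not None
              else (ref.optimal_cutoff if ref is not None else 2))
    ref_marker, ref_cov = reference_assay
    sub = counts[(counts["marker"] == ref_marker)
                 & (counts["coverage_percent"] == ref_cov)]
    pos = sub[["sample_id", "group", "count"]].copy()
    pos["positive"] = pos["count"] >= cutoff
    pos["cutoff"] = cutoff

    assoc = pd.DataFrame()
    if clinical is not None:
        assoc_rows = []
        merged = pos.merge(clinical, on="sample_id", how="inner")
        for col in clinical.columns:
            if col == "sample_id":
                continue
            levels = sorted(merged[col].dropna().unique())
            if len(levels) != 2:
                continue
            tab = np.array([
                [int(((merged[col] == lv) & merged["positive"]).sum()),
                 int(((merged[col] == lv) & ~merged["positive"]).sum())]
                for lv in levels])
            assoc_rows.append({"factor": col, "levels": "/".join(map(str, levels)),
                               "test": "fisher_exact",
                               "p_value": fisher_exact_2x2(tab)})
        assoc = pd.DataFrame(assoc_rows)

    return CohortReport(roc_table=roc_table, delong_matrix=dl,
                        detection_rates=det, positivity=pos,
                        association=assoc)
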