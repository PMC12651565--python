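"""Counting rules and diagnostic statistics against enumeration oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from ctcscan import diagnostics as dg
from ctcscan.calibration import CoverageThreshold


def _lum_frame(values, sample_id="s1"):
    return pd.DataFrame({
        "sample_id": sample_id,
        "cell_id": range(len(values)),
        "EpCAM_corrected_mean": values,
        "CSV_corrected_mean": 0.0})


THR = CoverageThreshold("EpCAM", 95.0, 34.5, 336)


class TestCounting:
    def test_no_cells_zero_count(self):
        sc = dg.count_candidates(_lum_frame([]), THR, "s1")
        assert sc.count == 0

    def test_strict_exceedance_tie_negative(self):
        sc = dg.count_candidates(_lum_frame([10, 34.5, 60, 90]), THR, "s1")
        assert sc.count == 2

    def test_other_blood_volume_normalized_round_half_up(self):
        sc = dg.count_candidates(_lum_frame([60, 70, 80]), THR, "s1",
                                 blood_volume_ml=10.0)
        assert sc.count == 2  # 3 cells/10 mL → 1.5/5 mL → 2


class TestDetectionRate:
    def test_all_zero(self):
        counts = [dg.SampleCount(f"s{i}", "case", "EpCAM", 95, 0)
                  for i in range(4)]
        assert dg.detection_rate(counts, "case") == 0.0

    def test_half_detected(self):
        counts = [dg.SampleCount(f"s{i}", "case", "EpCAM", 95, c)
                  for i, c in enumerate([0, 1, 2, 0])]
        assert dg.detection_rate(counts, "case") == 0.5

    def test_empty_group_error(self):
        with pytest.raises(ValueError, match="no samples"):
            dg.detection_rate([], "case")


def exact_mw_p(x, y):
    """Oracle: full enumeration of group assignments; two-sided p as twice
    the smaller tail, clipped at 1 (exact, no ties)."""
    pooled = np.concatenate([x, y])
    m = len(x)
    mn = m * len(y)
    u_obs = (np.sum([np.sum(xi > y) for xi in x])
             + 0.5 * np.sum([np.sum(xi == y) for xi in x]))
    us = []
    for idx in itertools.combinations(range(len(pooled)), m):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(np.sum([np.sum(xi > ys) for xi in xs]))
    us = np.array(us)
    lo = (us <= u_obs).mean()
    hi = (us >= u_obs).mean()
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_identical_multisets_null(self):
        x = np.array([3.0, 1.0, 7.0, 5.0])
        u, p = dg.mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p >= 0.99

    def test_fully_separated_small_sample_exact(self):
        u, p = dg.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1)

    def test_exact_regime_matches_full_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(2, 13 - m))
            pooled = rng.permutation(np.arange(100, dtype=float))[:m + n]
            x, y = pooled[:m], pooled[m:]
            _, p = dg.mann_whitney_u(x, y)
            assert p == pytest.approx(exact_mw_p(x, y), abs=1e-10)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            dg.mann_whitney_u([], [1.0])


class TestAUC:
    def test_perfect_separation(self):
        roc = dg.roc_auc([2, 3], [0, 1])
        assert roc.auc == 1.0

    def test_auc_equals_u_over_mn_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = int(rng.integers(2, 20))
            n = int(rng.integers(2, 20))
            x = rng.integers(0, 6, m).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            u, _ = dg.mann_whitney_u(x, y)
            assert dg.auc_from_counts(x, y) == pytest.approx(u / (m * n),
                                                             abs=1e-12)
            assert dg.roc_auc(x, y).auc == pytest.approx(u / (m * n),
                                                         abs=1e-12)

    def test_auc_within_ci(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(4, 30).astype(float)
        y = rng.poisson(1, 12).astype(float)
        roc = dg.roc_auc(x, y)
        assert roc.ci95[0] <= roc.auc <= roc.ci95[1]
        assert 0 <= roc.ci95[0] <= roc.ci95[1] <= 1

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            dg.roc_auc([], [1])


class TestYouden:
    def test_perfect_separation_cutoff(self):
        roc = dg.roc_auc([2, 3, 5], [0, 1, 1])
        assert roc.optimal_cutoff == 2
        best = roc.cutoff_table[roc.cutoff_table["cutoff"] == 2].iloc[0]
        assert best["J"] == pytest.approx(1.0)

    def test_flat_j_smallest_cutoff(self):
        roc = dg.roc_auc([5, 5], [5, 5])  # AUC 0.5, J flat at 0
        assert roc.optimal_cutoff == roc.cutoff_table["cutoff"].min()

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.poisson(3, 20).astype(float)
            y = rng.poisson(1, 10).astype(float)
            roc = dg.roc_auc(x, y)
            best_j, best_c = -2.0, None
            for c in range(0, int(max(x.max(), y.max())) + 2):
                j = (x >= c).mean() + (y < c).mean() - 1
                if j > best_j + 1e-12:
                    best_j, best_c = j, c
            assert roc.optimal_cutoff == best_c


class TestDeLong:
    def test_self_comparison_p_one(self):
        rng = np.random.default_rng(4)
        scores = rng.poisson(2, 40).astype(float)
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        with pytest.warns(UserWarning):
            cmp = dg.delong_paired_test(scores, scores, labels)
        assert cmp.delta_auc == 0.0
        assert cmp.p_value == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        labels = np.r_[np.ones(25, bool), np.zeros(20, bool)]
        a = rng.poisson(3, 45).astype(float) + labels
        b = rng.poisson(2, 45).astype(float)
        c1 = dg.delong_paired_test(a, b, labels)
        c2 = dg.delong_paired_test(b, a, labels)
        assert c1.delta_auc == pytest.approx(-c2.delta_auc)
        assert c1.p_value == pytest.approx(c2.p_value)
        assert c1.var_delta >= 0

    def test_degenerate_variance_p_one(self):
        labels = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        a = np.zeros(10)
        b = np.zeros(10)
        with pytest.warns(UserWarning, match="degenerate"):
            cmp = dg.delong_paired_test(a, b, labels)
        assert cmp.p_value == 1.0

    def test_single_roc_se_matches_closed_form_no_ties(self):
        # Hanley-McNeil style check: for continuous scores the DeLong SE
        # must agree with the structural-component definition computed
        # directly from the placement matrix.
        rng = np.random.default_rng(6)
        x = rng.normal(1, 1, 15)
        y = rng.normal(0, 1, 10)
        auc, v10, v01 = dg.delong_components(x, y)
        psi = (x[:, None] > y[None, :]) + 0.5 * (x[:, None] == y[None, :])
        np.testing.assert_allclose(v10, psi.mean(axis=1))
        np.testing.assert_allclose(v01, psi.mean(axis=0))
        assert auc == pytest.approx(psi.mean())


def fisher_oracle(table):
    """Exact-arithmetic enumeration of the two-sided Fisher p."""
    (a, b), (c, d) = table
    r1, n1, total = a + b, a + c, a + b + c + d
    denom = math.comb(total, r1)
    pmf = {}
    for k in range(max(0, r1 + n1 - total), min(r1, n1) + 1):
        pmf[k] = Fraction(math.comb(n1, k) * math.comb(total - n1, r1 - k),
                          denom)
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


class TestFisherChi2:
    def test_exact_independence(self):
        assert dg.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_clinical_association_table_vs_enumeration(self):
        # representative clinical 2x2: CTC positivity vs peritoneal cytology
        table = [[21, 8], [7, 2]]
        assert dg.fisher_exact_2x2(table) == pytest.approx(
            fisher_oracle(table), abs=1e-12)

    def test_random_tables_vs_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            t = rng.integers(0, 12, (2, 2))
            assert dg.fisher_exact_2x2(t) == pytest.approx(
                fisher_oracle(t.tolist()), abs=1e-12)

    def test_chi_square_zero_margin_named(self):
        with pytest.raises(ValueError, match="column margin"):
            dg.chi_square_2x2([[0, 5], [0, 3]])

    def test_chi_square_df1_no_correction(self):
        stat, p = dg.chi_square_2x2([[10, 20], [20, 10]])
        # hand computation: N=60, expected all 15 → chi2 = 4*25/15 = 6.667
        assert stat == pytest.approx(100 / 15)
        assert 0 < p < 0.05


@pytest.fixture(scope="module")
def cohort_counts():
    rng = np.random.default_rng(11)
    rows = []
    for i in range(30):
        grp = "case" if i < 20 else "control"
        for marker in ("EpCAM", "CSV"):
            base = rng.poisson(3 if grp == "case" else 1)
            for cov, frac in ((99.0, 0.3), (95.0, 0.7), (90.0, 1.0)):
                rows.append({"sample_id": f"s{i:02d}", "group": grp,
                             "marker": marker, "coverage_percent": cov,
                             "count": int(round(base * frac))})
    return pd.DataFrame(rows)


class TestCohortReport:
    def test_shape_contract(self, cohort_counts):
        rep = dg.cohort_report(cohort_counts)
        assert len(rep.roc_table) == 6  # 2 markers x 3 coverages
        assert rep.delong_matrix.shape == (6, 6)
        assert np.allclose(np.diag(rep.delong_matrix.to_numpy()), 1.0)
        assert ((rep.delong_matrix.to_numpy() >= 0)
                & (rep.delong_matrix.to_numpy() <= 1)).all()

    def test_count_monotone_in_coverage(self, cohort_counts):
        wide = cohort_counts.pivot_table(
            index=["sample_id", "marker"], columns="coverage_percent",
            values="count")
        assert (wide[99.0] <= wide[95.0]).all()
        assert (wide[95.0] <= wide[90.0]).all()

    def test_regeneration_from_saved_counts_identical(self, cohort_counts,
                                                      tmp_path):
        rep1 = dg.cohort_report(cohort_counts)
        path = tmp_path / "counts.csv"
        cohort_counts.to_csv(path, index=False)
        rep2 = dg.cohort_report(pd.read_csv(path))
        pd.testing.assert_frame_equal(rep1.roc_table, rep2.roc_table)
        pd.testing.assert_frame_equal(rep1.delong_matrix, rep2.delong_matrix)

    def test_missing_group_label_error(self, cohort_counts):
        bad = cohort_counts.copy()
        bad.loc[0, "group"] = ""
        with pytest.raises(ValueError, match="group"):
            dg.cohort_report(bad)

    def test_association_with_clinical_factor(self, cohort_counts):
        rng = np.random.default_rng(12)
        samples = cohort_counts["sample_id"].unique()
        clinical = pd.DataFrame({
            "sample_id": samples,
            "stage": rng.choice(["I-II", "III-IV"], len(samples))})
        rep = dg.cohort_report(cohort_counts, clinical=clinical)
        assert len(rep.association) == 1
        assert 0 <= rep.association["p_value"].iloc[0] <= 1
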