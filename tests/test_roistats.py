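import itertools

import numpy as np
import pytest
from scipy import stats

from petmoco.geometry import InvalidInputError, VolumeGrid
from petmoco.roistats import (
    RelDiffTable,
    ROITable,
    bonferroni,
    group_summary,
    mann_whitney_u,
    registration_qc,
    relative_diff,
    roi_means,
)


def toy_labels(shape=(6, 6, 6)):
    lab = np.zeros(shape)
    lab[:3] = 1
    lab[3:] = 2
    return VolumeGrid(lab, 1.0, (0, 0, 0))


ROI_DEFS = {"A": (1,), "B": (2,), "ALL": (1, 2)}


class TestRoiMeans:
    def test_uniform_volume(self):
        v = VolumeGrid(np.full((6, 6, 6), 5.0), 1.0, (0, 0, 0))
        t = roi_means(v, toy_labels(), ROI_DEFS)
        assert t.means == {"A": 5.0, "B": 5.0, "ALL": 5.0}

    def test_two_roi_split(self):
        vals = np.zeros((6, 6, 6))
        vals[:3] = 1.0
        vals[3:] = 3.0
        t = roi_means(VolumeGrid(vals, 1.0, (0, 0, 0)), toy_labels(), ROI_DEFS)
        assert t.means["A"] == 1.0 and t.means["B"] == 3.0
        assert t.means["ALL"] == 2.0

    def test_checkerboard_matches_voxel_loop_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.random((6, 6, 6))
        labels = toy_labels()
        t = roi_means(VolumeGrid(vals, 1.0, (0, 0, 0)), labels, ROI_DEFS)
        for roi, ids in ROI_DEFS.items():
            total, count = 0.0, 0
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        if int(labels.values[i, j, k]) in ids:
                            total += vals[i, j, k]
                            count += 1
            assert t.means[roi] == pytest.approx(total / count, rel=1e-12)
            assert t.counts[roi] == count

    def test_empty_roi_named_in_error(self):
        with pytest.raises(InvalidInputError, match="MISSING"):
            roi_means(VolumeGrid(np.zeros((6, 6, 6)), 1.0, (0, 0, 0)),
                      toy_labels(), {"MISSING": (9,)})


class TestRelativeDiff:
    def _table(self, **means):
        return ROITable(dict(means), {k: 1 for k in means})

    def test_equal_images_give_zero(self):
        t = relative_diff(self._table(A=5.0), self._table(A=5.0))
        assert t.values["A"] == 0.0

    def test_direct_formula(self):
        t = relative_diff(self._table(A=10.0), self._table(A=9.9))
        assert t.values["A"] == pytest.approx(1.0)

    def test_sign_convention(self):
        t = relative_diff(self._table(A=2.0), self._table(A=2.5))
        assert t.values["A"] == pytest.approx(-25.0)

    def test_zero_ddmc_reported_missing(self):
        t = relative_diff(self._table(A=0.0, B=1.0), self._table(A=1.0, B=1.0))
        assert t.missing == ("A",) and "A" not in t.values

    def test_swap_antisymmetry_against_direct_evaluation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            d, n = rng.uniform(0.5, 5, 2)
            fwd = relative_diff(self._table(A=d), self._table(A=n)).values["A"]
            rev = relative_diff(self._table(A=n), self._table(A=d)).values["A"]
            assert fwd == pytest.approx((d - n) / d * 100)
            assert rev == pytest.approx((n - d) / n * 100)


class TestGroupSummary:
    def test_single_scan_degenerate(self):
        gs = group_summary({"g": [RelDiffTable({"A": 1.5})]})
        assert gs.stats["g"]["A"] == (1.5, 1.5, 1.5)

    def test_textbook_quartiles(self):
        tables = [RelDiffTable({"A": float(v)}) for v in (1, 2, 3, 4, 5)]
        med, q1, q3 = group_summary({"g": tables}).stats["g"]["A"]
        assert (med, q1, q3) == (3.0, 2.0, 4.0)

    def test_matches_sort_based_oracle_and_order_invariance(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 1, 100)
        tables = [RelDiffTable({"A": float(v)}) for v in vals]
        gs = group_summary({"g": tables})
        s = np.sort(vals)

        def quantile(q):  # linear interpolation between order statistics
            pos = q * (len(s) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(s) - 1)
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        med, q1, q3 = gs.stats["g"]["A"]
        assert med == pytest.approx(quantile(0.5))
        assert q1 == pytest.approx(quantile(0.25))
        assert q3 == pytest.approx(quantile(0.75))
        shuffled = [tables[i] for i in rng.permutation(100)]
        assert group_summary({"g": shuffled}).stats["g"]["A"] == gs.stats["g"]["A"]
        assert gs.stats["g"]["A"][1] <= med <= gs.stats["g"]["A"][2]

    def test_empty_group_omitted(self):
        gs = group_summary({"g": [], "h": [RelDiffTable({"A": 1.0})]})
        assert "g" not in gs.stats and "h" in gs.stats


def brute_force_mwu_p(a, b):
    """Oracle: U by pairwise comparison, p by full enumeration of labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    n, n_a = len(pooled), len(a)

    def u_stat(sample_a, sample_b):
        u = 0.0
        for x in sample_a:
            for y in sample_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_stat(a, b)
    us = []
    for comb in itertools.combinations(range(n), n_a):
        sa = [pooled[i] for i in comb]
        sb = [pooled[i] for i in range(n) if i not in comb]
        us.append(u_stat(sa, sb))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        r = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p == 1.0

    def test_no_overlap_two_by_two(self):
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.u == 0.0
        assert r.p == pytest.approx(2 / 6)
        assert r.method == "exact"

    def test_no_overlap_three_by_three(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.p == pytest.approx(2 / 20)

    def test_constant_samples_degenerate(self):
        r = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert r.p == 1.0 and r.method == "degenerate"

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(2, 8)))
            b = rng.normal(0.5, 1, int(rng.integers(2, 8)))
            ours = mann_whitney_u(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.u == pytest.approx(float(ref.statistic))
            assert ours.p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        r = mann_whitney_u(a, b)
        assert r.method == "normal-approx"
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert r.p == pytest.approx(float(ref.pvalue))

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            mann_whitney_u([], [1.0])


class TestBonferroni:
    def _res(self, p):
        from petmoco.roistats import MannWhitneyResult
        return MannWhitneyResult(1.0, p, "exact", 3, 3)

    def test_eleven_way_family(self):
        tr = bonferroni({"A": self._res(0.004), "B": self._res(0.02)}, alpha=0.05, m=11)
        assert tr.significant["A"] is True    # 0.004 < 0.05/11
        assert tr.significant["B"] is False   # 0.02  > 0.05/11

    def test_single_test_family(self):
        tr = bonferroni({"A": self._res(0.01)}, alpha=0.05, m=1)
        assert tr.significant["A"] is True

    def test_family_size_defaults_to_roi_count(self):
        tr = bonferroni({"A": self._res(0.03), "B": self._res(0.001)}, alpha=0.05)
        assert tr.m == 2
        assert tr.significant == {"A": False, "B": True}


class TestRegistrationQC:
    def test_identical_vectors_pass_with_zero(self):
        r = registration_qc((1, 2, 3), (1, 2, 3))
        assert r.passed and r.difference_mm == 0.0

    def test_three_four_five_boundary_inclusive(self):
        r = registration_qc((0.6, 0.8, 0.0), (0.0, 0.0, 0.0))
        assert r.difference_mm == pytest.approx(1.0)
        assert r.passed

    def test_just_over_tolerance_fails(self):
        r = registration_qc((0, 0, 1.01), (0, 0, 0))
        assert not r.passed

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            registration_qc((np.nan, 0, 0), (0, 0, 0))
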