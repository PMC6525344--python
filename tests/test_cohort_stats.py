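import numpy as np
import pytest
from hypothesis import given, strategies as st

from onlshape.cohort_stats import (
    SubjectRecord,
    mh_mv_ratio,
    pearson,
    table1_summary,
    table2_correlations,
    two_group_compare,
)
from onlshape.ellipse_fit import ShapeParams
from onlshape.errors import ParameterError, StatisticsError
from onlshape.surface_io import SubjectMeta


def record(group="ERM", mh=0.7, mv=0.5, axis=5.0, circ=0.8, ar=0.74, axr=1.5,
           onl=84.0, sid="s"):
    return SubjectRecord(
        meta=SubjectMeta(sid, group, "OS", mh, mv, 0.2),
        shape=ShapeParams(circularity=circ, area_ratio=ar, axis_ratio=axr, axis_deg=axis),
        onl_height_um=onl, level_um=150.0,
    )


class TestMhMvRatio:
    def test_plain_ratio(self):
        assert mh_mv_ratio(0.7, 0.35) == pytest.approx(2.0)

    def test_zero_mh_substituted(self):
        assert mh_mv_ratio(0.0, 0.5) == pytest.approx(0.1)

    def test_zero_mv_substituted(self):
        assert mh_mv_ratio(1.3, 0.0) == pytest.approx(26.0)

    def test_both_zero(self):
        assert mh_mv_ratio(0.0, 0.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            mh_mv_ratio(2.5, 0.5)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_hand_computed_example(self):
        # direct sum-of-products computation gives r = 0.8 for this pair
        r, p = pearson([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8)
        assert p == pytest.approx(0.104, abs=0.001)

    def test_constant_vector_rejected(self):
        with pytest.raises(StatisticsError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_vector_rejected(self):
        with pytest.raises(StatisticsError):
            pearson([1.0, 2.0], [3.0, 4.0])

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=20, unique=True))
    def test_symmetry_and_affine_invariance(self, xs):
        rng = np.random.default_rng(0)
        x = np.array(xs)
        y = x + rng.normal(0, 10, x.size)
        if np.ptp(y) == 0:
            return
        r_xy, _ = pearson(x, y)
        r_yx, _ = pearson(y, x)
        assert r_xy == pytest.approx(r_yx)
        r_scaled, _ = pearson(3.0 * x + 7.0, y)
        assert r_scaled == pytest.approx(r_xy, abs=1e-9)
        r_neg, _ = pearson(-x, y)
        assert r_neg == pytest.approx(-r_xy, abs=1e-9)


class TestTwoGroupCompare:
    def test_identical_groups(self):
        *_, t, p = two_group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_shifted_groups(self):
        ma, sda, mb, sdb, t, p = two_group_compare([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert mb - ma == pytest.approx(10.0)
        assert sda == pytest.approx(1.0)  # n-1 denominator
        assert p < 0.01
        # Welch closed form: t = -10 / sqrt(1/3 + 1/3)
        assert t == pytest.approx(-10 / np.sqrt(2 / 3))

    def test_zero_variance_flagged(self):
        with pytest.raises(StatisticsError):
            two_group_compare([5.0, 5.0, 5.0], [7.0, 7.0])

    def test_small_group_rejected(self):
        with pytest.raises(StatisticsError):
            two_group_compare([1.0], [2.0, 3.0])


class TestTable1:
    def cohort(self):
        rng = np.random.default_rng(5)
        recs = [record(sid=f"e{i}", circ=0.79 + 0.05 * rng.standard_normal(),
                       onl=84 + 10 * rng.standard_normal()) for i in range(10)]
        recs += [record(sid=f"c{i}", group="control",
                        circ=0.85 + 0.05 * rng.standard_normal(),
                        onl=54 + 5 * rng.standard_normal()) for i in range(8)]
        return recs

    def test_group_means_and_pvalues(self):
        t1 = table1_summary(self.cohort())
        row = t1[t1.variable == "onl_height_um"].iloc[0]
        assert row.erm_n == 10 and row.control_n == 8
        assert row.erm_mean > row.control_mean
        assert row.p < 0.001

    def test_mchart_rows_erm_only(self):
        t1 = table1_summary(self.cohort())
        mh = t1[t1.variable == "mh"].iloc[0]
        assert mh.erm_mean == pytest.approx(0.7)
        assert np.isnan(mh.control_mean)

    def test_single_group_leaves_comparison_empty(self):
        t1 = table1_summary([record(sid=f"e{i}", circ=0.7 + 0.01 * i) for i in range(5)])
        assert t1.p.isna().all()

    def test_deterministic(self):
        recs = self.cohort()
        assert table1_summary(recs).equals(table1_summary(recs))


class TestTable2:
    def cohort(self, n=20, rho=-0.9, seed=2):
        rng = np.random.default_rng(seed)
        ar = 0.74 + 0.03 * rng.standard_normal(n)
        z = rho * (ar - ar.mean()) / ar.std() + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        mh = np.clip(0.7 + 0.3 * z, 0.2, 2.0).round(1)
        recs = [record(sid=f"e{i}", mh=float(mh[i]), mv=0.5, ar=float(ar[i]),
                       axis=float(rng.uniform(-40, 40))) for i in range(n)]
        return recs

    def test_detects_negative_correlation(self):
        t2 = table2_correlations(self.cohort())
        row = t2[(t2.variable == "area_ratio") & (t2.subset == "all")].iloc[0]
        assert row.r < 0 and row.p < 0.05 and row.significant

    def test_wide_window_equals_full_set(self):
        recs = self.cohort()
        t2 = table2_correlations(recs, axis_window_deg=90.0)
        full = t2[t2.subset == "all"].reset_index(drop=True)
        sub = t2[t2.subset == "axis_within_window"].reset_index(drop=True)
        assert (sub.n == full.n).all()
        np.testing.assert_allclose(sub.r.values, full.r.values)

    def test_subset_consistency_with_external_filter(self):
        recs = self.cohort()
        t2 = table2_correlations(recs, axis_window_deg=10.0)
        inside = [r for r in recs if abs(r.shape.axis_deg) <= 10.0]
        if len(inside) >= 3:
            t2_ext = table2_correlations(inside, axis_window_deg=1e9)
            a = t2[t2.subset == "axis_within_window"].reset_index(drop=True)
            b = t2_ext[t2_ext.subset == "all"].reset_index(drop=True)
            np.testing.assert_allclose(a.r.values, b.r.values)

    def test_constant_ratio_flagged_not_fatal(self):
        recs = [record(sid=f"e{i}", mh=0.5, mv=0.5, ar=0.7 + 0.01 * i,
                       axis=float(i)) for i in range(6)]
        t2 = table2_correlations(recs)
        assert t2[(t2.variable == "area_ratio") & (t2.subset == "all")].r.isna().all()

    def test_too_few_erm_records(self):
        with pytest.raises(StatisticsError):
            table2_correlations([record(sid="a"), record(sid="b")])
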