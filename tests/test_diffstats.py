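"""Unit, oracle and property tests for the differential statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from circscape.diffstats import (
    DiffRecord,
    bh_adjust,
    classify_regulation,
    coupling_regression,
    dagostino_pearson,
    fold_change,
    fold_difference,
    global_shift_test,
    ma_table,
    threshold_filter,
    wilcoxon_signed_rank,
)


def enumeration_signed_rank_p(d):
    """Independent oracle: exact two-sided signed-rank p over all 2^n sign
    assignments of the observed |differences| (midranks, zeros dropped)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    w_all = np.array(w_all)
    lo = np.mean(w_all <= w_obs + 1e-9)
    hi = np.mean(w_all >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestFoldChange:
    def test_simple(self):
        fc, l2 = fold_change(2, 8)
        assert fc == 4 and l2 == 2

    def test_identity(self):
        fc, l2 = fold_change(7, 7)
        assert fc == 1 and l2 == 0

    def test_pseudocount(self):
        fc, _ = fold_change(0, 3, pseudocount=1)
        assert fc == 4

    def test_undefined_without_pseudocount(self):
        with pytest.raises(ValueError):
            fold_change(0, 0, pseudocount=0)


class TestClassifyRegulation:
    @pytest.mark.parametrize(
        "fc,expected",
        [(2.5, "up"), (2.0, "unchanged"), (0.4, "down"), (0.5, "unchanged"),
         (1.0, "unchanged"), (100.0, "up"), (0.01, "down")],
    )
    def test_strict_two_fold_rule(self, fc, expected):
        assert classify_regulation(np.log2(fc)) == expected

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            classify_regulation(1.0, threshold_fold=1.0)


class TestDagostinoPearson:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(11)
        k2, p = dagostino_pearson(rng.normal(size=1000))
        assert k2 >= 0
        assert p > 0.01

    def test_skewed_sample_rejected(self):
        rng = np.random.default_rng(12)
        _, p = dagostino_pearson(rng.exponential(size=1000))
        assert p < 1e-6

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            dagostino_pearson(np.arange(7))


class TestWilcoxonSignedRank:
    def test_all_positive_n5_exact(self):
        w, p, n = wilcoxon_signed_rank([0] * 5, [1, 2, 3, 4, 5])
        assert (w, n) == (15.0, 5)
        assert p == pytest.approx(0.0625)

    def test_degenerate_all_zero_differences(self):
        w, p, n = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert (w, p, n) == (0.0, 1.0, 0)

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        # mix of continuous and tied integer differences
        if seed % 2:
            d = rng.integers(-4, 5, size=n).astype(float)
        else:
            d = rng.normal(size=n)
        _, p, _ = wilcoxon_signed_rank(np.zeros(n), d)
        if np.all(d == 0):
            return
        assert p == pytest.approx(enumeration_signed_rank_p(d))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=14)
        _, p, _ = wilcoxon_signed_rank(np.zeros(14), d)
        ref = stats.wilcoxon(d, method="exact").pvalue
        assert p == pytest.approx(ref)

    def test_large_n_matches_scipy_normal_approx(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.2, 1, size=200)
        _, p, _ = wilcoxon_signed_rank(np.zeros(200), d)
        ref = stats.wilcoxon(d, method="approx", correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-9)


class TestGlobalShift:
    def test_identical_vectors_degenerate(self):
        r = global_shift_test(np.arange(10.0), np.arange(10.0))
        assert r.test_used == "degenerate"
        assert r.p_value == 1.0
        assert r.n_pairs_used == 0

    def test_forced_wilcoxon_small_n(self):
        r = global_shift_test([0] * 5, [1, 2, 3, 4, 5], test="wilcoxon")
        assert r.test_used == "wilcoxon"
        assert r.p_value == pytest.approx(0.0625)

    def test_gate_routes_skewed_data_to_wilcoxon(self):
        rng = np.random.default_rng(7)
        a = rng.exponential(size=200)
        b = a + rng.exponential(size=200)
        r = global_shift_test(a, b)
        assert r.test_used == "wilcoxon"
        assert any(p < 0.05 for p in r.normality_p.values())

    def test_gate_routes_normal_data_to_paired_t(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=500)
        b = a + rng.normal(0.05, 1, size=500)
        r = global_shift_test(a, b)
        if all(p >= 0.05 for p in r.normality_p.values()):
            assert r.test_used == "paired_t"
        ref = stats.ttest_rel(b, a).pvalue
        if r.test_used == "paired_t":
            assert r.p_value == pytest.approx(ref)


class TestCouplingRegression:
    def test_collinear(self):
        x = np.arange(10.0)
        res = coupling_regression(x, 2 * x)
        assert res.slope == pytest.approx(2)
        assert res.r_squared == pytest.approx(1)
        assert res.p_value < 1e-12

    def test_independent_normals_small_r2(self):
        rng = np.random.default_rng(9)
        res = coupling_regression(rng.normal(size=1000), rng.normal(size=1000))
        assert res.r_squared < 0.02

    def test_slope_invariant_to_y_shift(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        r1 = coupling_regression(x, y)
        r2 = coupling_regression(x, y + 100.0)
        assert r1.slope == pytest.approx(r2.slope)
        assert r2.intercept == pytest.approx(r1.intercept + 100.0)

    def test_f_equals_t_squared_and_p_matches_slope_t_test(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        res = coupling_regression(x, y)
        lin = stats.linregress(x, y)
        t = lin.slope / lin.stderr
        assert res.f_statistic == pytest.approx(t**2)
        assert res.p_value == pytest.approx(lin.pvalue)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            coupling_regression([1, 1, 1, 1], [1, 2, 3, 4])


class TestThresholdFilter:
    RECORDS = [
        DiffRecord("a", basemean=50, log2fc=1.0, p_value=0.01, adj_p=0.2),
        DiffRecord("b", basemean=50, log2fc=1.0, p_value=0.05, adj_p=0.01),  # p at bound
        DiffRecord("c", basemean=10, log2fc=1.0, p_value=0.01, adj_p=0.01),  # bm at bound
        DiffRecord("d", basemean=50, log2fc=0.5, p_value=0.01, adj_p=0.01),  # fc at bound
        DiffRecord("e", basemean=50, log2fc=-0.8, p_value=0.001, adj_p=0.04),
        DiffRecord("f", basemean=5, log2fc=2.0, p_value=0.2, adj_p=0.9),
    ]

    def test_brute_force_equivalence(self):
        got = {r.id for r in threshold_filter(self.RECORDS)}
        brute = {
            r.id
            for r in self.RECORDS
            if r.p_value < 0.05 and r.basemean > 10 and abs(r.log2fc) > 0.5
        }
        assert got == brute == {"a", "e"}

    def test_boundaries_are_strict(self):
        ids = {r.id for r in threshold_filter(self.RECORDS)}
        assert {"b", "c", "d"}.isdisjoint(ids)

    def test_adjusted_mode_without_bm(self):
        # without the basemean cut, record c (bm at the bound) comes back
        got = {r.id for r in threshold_filter(self.RECORDS, bm_min=None, use_adj=True)}
        assert got == {"b", "c", "e"}

    def test_missing_adj_p_raises(self):
        with pytest.raises(ValueError):
            threshold_filter([DiffRecord("x", 50, 1.0, 0.01)], use_adj=True)

    def test_empty_input(self):
        assert threshold_filter([]) == []


class TestBhAdjust:
    def test_hand_computation(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_independent_hand_oracle(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=20)
        # step-up by hand
        order = np.argsort(p)
        adj = np.empty(20)
        prev = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            i = 20 - rank_from_top  # 1-based rank
            val = min(prev, p[idx] * 20 / i)
            adj[idx] = val
            prev = val
        np.testing.assert_allclose(bh_adjust(p), adj)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_order_invariant(self, p):
        p = np.array(p)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestMaTable:
    def test_passthrough_and_classes(self):
        a = [10.0, 20.0, 5.0]
        m = [2.0, 0.0, -2.0]
        df = ma_table(a, m)
        np.testing.assert_allclose(df["A"], a)
        np.testing.assert_allclose(df["M"], m)
        assert list(df["regulation"]) == [
            classify_regulation(v) for v in m
        ]

    def test_empty(self):
        assert len(ma_table([], [])) == 0


def test_fold_difference_nearest_integer():
    assert fold_difference(1.89, 0.45) == 4
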