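"""Statistical procedures: tau, proportion tests, Fisher, BH, enrichment."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from m6atopo.stats import (bh_adjust, chi2_test, fisher_exact, geneset_enrichment,
                           odds_ratio, pearson_correlation, tau, two_proportion_ztest)


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration in exact rational arithmetic."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, r1)
    probs = {}
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        probs[k] = Fraction(math.comb(c1, k) * math.comb(n - c1, r1 - k), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestTau:
    def test_uniform_is_zero(self):
        expr = pd.DataFrame([[5.0] * 6], index=["g"])
        assert tau(expr).iloc[0] == 0.0

    def test_one_hot_is_one(self):
        expr = pd.DataFrame([[0, 0, 9.0, 0]], index=["g"])
        assert tau(expr).iloc[0] == 1.0

    def test_two_tissue_hand_value(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"])
        assert tau(expr).iloc[0] == pytest.approx(0.5)

    def test_all_zero_undefined(self):
        expr = pd.DataFrame([[0.0, 0.0, 0.0]], index=["g"])
        assert math.isnan(tau(expr).iloc[0])

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            tau(pd.DataFrame([[1.0, -1.0]]))

    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=10),
           st.floats(0.01, 100.0))
    @settings(derandomize=True, max_examples=50)
    def test_scale_invariance(self, xs, c):
        expr = pd.DataFrame([xs, [c * x for x in xs]])
        t = tau(expr)
        assert t.iloc[0] == pytest.approx(t.iloc[1], rel=1e-9)


class TestZTest:
    def test_equal_proportions(self):
        res = two_proportion_ztest(10, 50, 20, 100)
        assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_pooled_formula_oracle(self):
        res = two_proportion_ztest(20, 100, 10, 100)
        pool = 30 / 200
        se = math.sqrt(pool * (1 - pool) * (1 / 100 + 1 / 100))
        z = (0.2 - 0.1) / se
        assert res.statistic == pytest.approx(z, rel=1e-12)
        assert res.pvalue == pytest.approx(2 * sps.norm.sf(z), rel=1e-12)

    def test_antisymmetry(self):
        r1 = two_proportion_ztest(20, 100, 10, 100)
        r2 = two_proportion_ztest(10, 100, 20, 100)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_degenerate_pool(self):
        res = two_proportion_ztest(0, 10, 0, 20)
        assert (res.statistic, res.pvalue) == (0.0, 1.0)

    def test_z_squared_equals_chi2_on_2x2(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k1, k2 = rng.integers(1, 50, 2)
            n1, n2 = k1 + rng.integers(1, 50), k2 + rng.integers(1, 50)
            z = two_proportion_ztest(int(k1), int(n1), int(k2), int(n2)).statistic
            chi = chi2_test([[k1, n1 - k1], [k2, n2 - k2]]).statistic
            assert z ** 2 == pytest.approx(chi, abs=1e-9)


class TestChi2:
    def test_proportional_rows(self):
        res = chi2_test([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)
        assert res.df == 2

    def test_hand_expected_counts(self):
        # marginals 30/30, 30/30 -> every expected cell is 15
        expect = sum((o - 15) ** 2 / 15 for o in (10, 20, 20, 10))
        assert chi2_test([[10, 20], [20, 10]]).statistic == pytest.approx(expect)

    def test_column_permutation_invariance(self):
        a = chi2_test([[5, 9, 2], [7, 3, 11]])
        b = chi2_test([[2, 5, 9], [11, 7, 3]])
        assert a.statistic == pytest.approx(b.statistic)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chi2_test([[0, 5], [0, 7]])


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]).pvalue == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, 4)
            got = fisher_exact([[a, b], [c, d]]).pvalue
            assert got == pytest.approx(fisher_oracle(int(a), int(b), int(c), int(d)),
                                        abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 30, 4)
            got = fisher_exact([[a, b], [c, d]]).pvalue
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert got == pytest.approx(ref, abs=1e-9)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, 4))
            assert fisher_exact([[a, b], [c, d]]).pvalue == \
                   pytest.approx(fisher_exact([[a, c], [b, d]]).pvalue, abs=1e-12)


class TestOddsRatio:
    def test_arithmetic(self):
        assert odds_ratio([[2, 1], [1, 2]]) == (4.0, False)
        assert odds_ratio([[3, 3], [3, 3]]) == (1.0, False)

    def test_haldane_correction_flagged(self):
        orr, corrected = odds_ratio([[5, 0], [2, 7]])
        assert corrected
        assert orr == pytest.approx((5.5 * 7.5) / (0.5 * 2.5))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_formula_oracle(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
        res = pearson_correlation(x, y)
        assert res.statistic == pytest.approx(r, rel=1e-10)
        t = r * math.sqrt(8 / (1 - r * r))
        assert res.pvalue == pytest.approx(2 * sps.t.sf(abs(t), 8), rel=1e-9)

    def test_nan_pairs_excluded(self):
        x = np.array([1.0, 2, 3, np.nan, 5])
        y = np.array([2.0, 4, 6, 8, np.nan])
        assert pearson_correlation(x, y).statistic == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        res = pearson_correlation([1.0, 1, 1, 1], [1.0, 2, 3, 4])
        assert math.isnan(res.statistic)


class TestBH:
    def test_single_and_equal(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_stepup_arithmetic(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 100))
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), theirs, atol=1e-12)

    def test_never_decreases_and_order_restored(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        # adjusted values are monotone in the raw ordering
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_range_validation(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestEnrichment:
    def test_set_equal_to_group_is_top_hit(self):
        universe = {f"g{i}" for i in range(100)}
        group = {f"g{i}" for i in range(20)}
        sets = {"exact": set(group), "random": {f"g{i}" for i in range(50, 70)},
                "disjoint_from_universe": {"x1", "x2"}}
        res = geneset_enrichment(group, sets, universe)
        assert res.iloc[0]["set_id"] == "exact"
        assert res.iloc[0]["overlap"] == 20
        row = res.set_index("set_id").loc["disjoint_from_universe"]
        assert row["overlap"] == 0 and row["pvalue"] == 1.0

    def test_bh_applied_across_sets(self):
        rng = np.random.default_rng(7)
        universe = {f"g{i}" for i in range(200)}
        group = set(rng.choice(sorted(universe), 40, replace=False))
        sets = {f"s{j}": set(rng.choice(sorted(universe), 30, replace=False))
                for j in range(20)}
        res = geneset_enrichment(group, sets, universe)
        assert np.allclose(np.sort(res["adjusted_p"]),
                           np.sort(bh_adjust(res["pvalue"].to_numpy())))
        assert ((res["adjusted_p"] < 0.05) == res["significant"]).all()

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            geneset_enrichment({"a"}, {"s": {"a"}}, set())
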