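"""ECDFs and the two-sample shift tests against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirshift.matching import ControlMatchSet
from mirshift.shift import (
    cdf_shift_analysis,
    ecdf,
    ks_test,
    ranksum_test,
    t_test,
)


def enumerate_ranksum_p(x, y, alternative):
    """Full enumeration of the permutation null of the rank sum of x."""
    n_x, n = len(x), len(x) + len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n_x].sum()
    sums = [sum(c) for c in itertools.combinations(range(1, n + 1), n_x)]
    total = len(sums)
    p_less = sum(s <= w_obs for s in sums) / total
    p_greater = sum(s >= w_obs for s in sums) / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


class TestEcdf:
    def test_quantile_at_value(self):
        values, quantiles = ecdf([1, 2, 3])
        assert quantiles[list(values).index(2)] == pytest.approx(2 / 3)

    def test_all_equal_is_single_step_to_one(self):
        values, quantiles = ecdf([5.0, 5.0, 5.0])
        assert list(values) == [5.0]
        assert list(quantiles) == [1.0]

    def test_quantile_at_max_is_one_and_monotone(self):
        rng = np.random.default_rng(0)
        values, quantiles = ecdf(rng.normal(size=100))
        assert quantiles[-1] == 1.0
        assert (np.diff(quantiles) > 0).all()
        assert quantiles[0] >= 1 / 100

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            ecdf([])


class TestRanksum:
    def test_worked_one_sided_case(self):
        res = ranksum_test([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.p_value == pytest.approx(1 / 20)
        assert res.statistic == 6.0

    def test_worked_two_sided_case(self):
        res = ranksum_test([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.10)

    def test_opposite_tail_near_one(self):
        res = ranksum_test([1, 2, 3], [4, 5, 6], alternative="greater")
        assert res.p_value == pytest.approx(1.0)

    def test_identical_samples_p_near_one(self):
        res = ranksum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value > 0.9

    @pytest.mark.parametrize("alternative", ["two-sided", "less", "greater"])
    def test_exact_path_equals_full_enumeration(self, alternative):
        rng = np.random.default_rng(17)
        for n_x, n_y in [(1, 5), (2, 4), (3, 3), (4, 4), (5, 3)]:
            x = rng.normal(size=n_x)
            y = rng.normal(size=n_y)
            res = ranksum_test(x, y, alternative=alternative)
            assert res.p_value == pytest.approx(
                enumerate_ranksum_p(x, y, alternative), abs=1e-12
            )

    def test_exact_close_to_normal_approximation_at_ten_ten(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            exact = ranksum_test(x, y).p_value
            approx = ranksum_test(x, y, exact_max_n=0).p_value
            assert abs(exact - approx) < 0.01

    def test_agrees_with_scipy_mannwhitney_on_large_tied_data(self):
        rng = np.random.default_rng(29)
        x = rng.integers(0, 20, size=60).astype(float)
        y = rng.integers(0, 20, size=80).astype(float)
        res = ranksum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_invariant_under_common_monotone_transform(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=25)
        y = rng.normal(size=30) + 0.5
        a = ranksum_test(x, y)
        b = ranksum_test(np.exp(x), np.exp(y))
        assert a.p_value == b.p_value
        assert a.statistic == b.statistic


class TestKs:
    def test_disjoint_supports_give_d_one(self):
        res = ks_test([1, 2], [3, 4])
        assert res.statistic == pytest.approx(1.0)

    def test_identical_samples_give_d_zero(self):
        res = ks_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.statistic == 0.0

    def test_statistic_matches_brute_force_sup(self):
        rng = np.random.default_rng(37)
        x = rng.normal(size=40)
        y = rng.normal(size=55) + 0.3
        res = ks_test(x, y)
        grid = np.concatenate([x, y])
        d = max(
            abs((x <= v).mean() - (y <= v).mean()) for v in grid
        )
        assert res.statistic == pytest.approx(d, abs=1e-12)


class TestWelchT:
    def test_equal_samples_statistic_zero_p_one(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        res = t_test([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_zero_variance_offset_means_p_zero(self):
        res = t_test([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])
        assert res.p_value == 0.0
        assert res.statistic == -np.inf

    def test_matches_textbook_welch_formula(self):
        rng = np.random.default_rng(41)
        x = rng.normal(size=12)
        y = rng.normal(loc=0.7, scale=2.0, size=18)
        res = t_test(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_stat = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * sps.t.sf(abs(t_stat), df)
        assert res.statistic == pytest.approx(t_stat, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


class TestCdfShiftAnalysis:
    def _inputs(self, n=40, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(2 * n)]
        lfc = np.concatenate([rng.normal(-shift, 0.3, n), rng.normal(0, 0.3, n)])
        stats = pd.DataFrame({"lfc_wt_ko": lfc, "expressed": True}, index=genes)
        targets = genes[:n]
        pairs = pd.DataFrame({"target": targets, "control": genes[n:],
                              "distance": 0.0})
        return stats, {"targets": set(targets)}, {"targets": ControlMatchSet(pairs)}

    def test_one_result_per_set_and_test(self):
        results = cdf_shift_analysis(*self._inputs())
        assert sorted(r.test for r in results) == ["ks", "ranksum", "t"]
        assert all(r.set_name == "targets" for r in results)
        assert all(r.ecdf_set is not None for r in results)

    def test_planted_shift_detected_with_negative_median(self):
        results = cdf_shift_analysis(*self._inputs(n=200, shift=0.5, seed=1))
        ranksum = next(r for r in results if r.test == "ranksum")
        assert ranksum.p_value < 1e-6
        assert ranksum.median_shift < -0.3

    def test_small_set_skipped_with_warning(self):
        stats, sets, matches = self._inputs()
        sets["tiny"] = {"g0"}
        matches["tiny"] = matches["targets"]
        with pytest.warns(UserWarning, match="tiny"):
            results = cdf_shift_analysis(stats, sets, matches)
        assert {r.set_name for r in results} == {"targets"}

    def test_unexpressed_genes_excluded(self):
        stats, sets, matches = self._inputs()
        stats.loc[:, "expressed"] = False
        with pytest.warns(UserWarning):
            assert cdf_shift_analysis(stats, sets, matches) == []
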