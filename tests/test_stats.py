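from itertools import combinations, permutations

import numpy as np
import pytest
from scipy import stats as sps

from noiseplast.stats import (bh_fdr, bin_permutation_test, chi2_2x2_yates,
                              equal_size_bins, fisher_2x2,
                              group_location_tests, sliding_window, spearman)


# ---------------------------------------------------------------------------
# independent oracles

def exact_spearman_p(x, y):
    """Two-sided p by exhaustive permutation of y (n! tables)."""
    rho_obs, _, _ = spearman(x, y)
    rx = sps.rankdata(x)
    count = 0
    total = 0
    for perm in permutations(y):
        rho = np.corrcoef(rx, sps.rankdata(perm))[0, 1]
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def exact_ranksum_p(a, b):
    """Two-sided p over all C(n, |a|) group assignments (tie-free data)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    obs = ranks[:na].sum()
    e = na * (len(pooled) + 1) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), na):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - e) >= abs(obs - e) - 1e-12:
            count += 1
    return count / total


def exact_fisher_p(a, b, c, d):
    """Minimum-likelihood two-sided p by hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = sps.hypergeom(n, c1, r1)
    p_obs = rv.pmf(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return float(sum(rv.pmf(k) for k in range(lo, hi + 1)
                     if rv.pmf(k) <= p_obs * (1 + 1e-7)))


# ---------------------------------------------------------------------------
# binning

class TestEqualSizeBins:
    def test_even_split(self):
        bins = equal_size_bins(np.arange(10)[::-1], 5)
        # value-ordered: smallest two in bin 0
        assert bins.tolist() == [4, 4, 3, 3, 2, 2, 1, 1, 0, 0]

    def test_remainder_goes_to_first_bins(self):
        bins = equal_size_bins(np.arange(11), 5)
        sizes = np.bincount(bins)
        assert sizes.tolist() == [3, 2, 2, 2, 2]

    def test_ties_broken_by_input_order(self):
        bins = equal_size_bins([7, 7, 7, 7], 2)
        assert bins.tolist() == [0, 0, 1, 1]

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            equal_size_bins([1.0, 2.0], 3)

    def test_bin_index_increases_with_value(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(97)
        bins = equal_size_bins(v, 10)
        order = np.argsort(v, kind="stable")
        assert (np.diff(bins[order]) >= 0).all()
        assert np.ptp(np.bincount(bins)) <= 1


class TestBinPermutationTest:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        b, s, o = (rng.standard_normal(120) for _ in range(3))
        r1 = bin_permutation_test(b, s, o, n_bins=4, n_perm=200, seed=9)
        r2 = bin_permutation_test(b, s, o, n_bins=4, n_perm=200, seed=9)
        assert r1.bins.equals(r2.bins)

    def test_planted_signal_every_bin_significant(self):
        rng = np.random.default_rng(2)
        b = rng.standard_normal(200)
        s = rng.standard_normal(200)
        r = bin_permutation_test(b, s, s, n_bins=10, n_perm=500, seed=4)
        assert r.bins["significant"].all()
        assert (r.bins["observed_delta"]
                > r.bins["null_mean"] + 2 * r.bins["null_sd"]).all()

    def test_degenerate_bin_reported_missing(self):
        b = np.arange(40, dtype=float)
        s = np.zeros(40)
        o = np.arange(40, dtype=float)
        r = bin_permutation_test(b, s, o, n_bins=4, n_perm=50, seed=0)
        assert r.bins["degenerate"].all()
        assert r.bins["observed_delta"].isna().all()

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(3)
        b, s, o = (rng.standard_normal(60) for _ in range(3))
        o[::7] = np.nan
        r = bin_permutation_test(b, s, o, n_bins=3, n_perm=50, seed=0)
        assert r.bins["n"].sum() == np.isfinite(o).sum()


class TestSlidingWindow:
    def test_constant_response_flat_profile(self):
        r = sliding_window(np.arange(30.0), np.full(30, 2.5),
                           window_size=10, n_perm=50, seed=0)
        np.testing.assert_array_equal(r.window_mean, np.full(21, 2.5))
        np.testing.assert_array_equal(r.null_sd, np.zeros(21))

    def test_window_means_match_brute_force_exactly(self):
        rng = np.random.default_rng(5)
        ov = rng.standard_normal(250)
        rv = rng.standard_normal(250)
        r = sliding_window(ov, rv, window_size=50, n_perm=5, seed=0)
        srt = rv[np.argsort(ov, kind="stable")]
        brute = np.array([np.mean(srt[i:i + 50]) for i in range(201)])
        np.testing.assert_array_equal(r.window_mean, brute)

    def test_monotone_construction(self):
        ov = np.arange(200.0)
        rv = ov.copy()   # response = order rank
        r = sliding_window(ov, rv, window_size=40, n_perm=5, seed=0)
        assert r.window_mean[0] < r.window_mean[-1]
        assert (np.diff(r.window_mean) >= 0).all()

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            sliding_window([1.0, 2.0], [1.0, 2.0], window_size=5, n_perm=5,
                           seed=0)

    def test_shuffled_response_mostly_inside_envelope(self):
        rng = np.random.default_rng(11)
        ov = rng.standard_normal(300)
        rv = rng.permutation(rng.standard_normal(300))
        r = sliding_window(ov, rv, window_size=60, n_perm=300, seed=1)
        assert (~r.outside_envelope()).mean() >= 0.9


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        rho, _, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _, _ = spearman(x, -x ** 3)
        assert rho == pytest.approx(-1.0)

    def test_pairwise_deletion(self):
        x = [1.0, 2, 3, np.nan, 5, 6]
        y = [2.0, 1, 4, 5, np.nan, 8]
        rho, p, n = spearman(x, y)
        assert n == 4

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2, 3], [3.0, 2, 1])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_p_close_to_exact_enumeration_n6(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        _, p_t, _ = spearman(x, y)
        p_exact = exact_spearman_p(x, y)
        assert p_t == pytest.approx(p_exact, rel=0.35, abs=0.03)


class TestFisher:
    def test_printed_bipromoter_table(self):
        _, p = fisher_2x2(27, 39, 47, 189)
        assert p == pytest.approx(1.0e-3, rel=0.05)

    def test_no_association(self):
        _, p = fisher_2x2(5, 5, 5, 5)
        assert p == pytest.approx(1.0)

    def test_row_and_column_swap_symmetry(self):
        _, p = fisher_2x2(12, 5, 3, 9)
        for table in [(3, 9, 12, 5), (5, 12, 9, 3)]:
            _, p2 = fisher_2x2(*table)
            assert p2 == pytest.approx(p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)

    @pytest.mark.parametrize("table", [
        (1, 2, 3, 2), (4, 1, 1, 2), (2, 2, 2, 2), (0, 3, 4, 1), (3, 5, 2, 6),
    ])
    def test_matches_enumeration_oracle(self, table):
        _, p = fisher_2x2(*table)
        assert p == pytest.approx(exact_fisher_p(*table), rel=1e-6)


class TestChi2Yates:
    def test_proportional_table_not_significant(self):
        stat, p = chi2_2x2_yates(10, 20, 30, 60)
        assert stat == pytest.approx(0.0, abs=0.1)
        assert p > 0.7

    def test_correction_shrinks_statistic(self):
        for table in [(26, 487, 343, 1186), (8, 3, 2, 9), (20, 10, 5, 30)]:
            stat_c, _ = chi2_2x2_yates(*table)
            stat_u, _, _, _ = sps.chi2_contingency(
                [[table[0], table[1]], [table[2], table[3]]],
                correction=False)
            assert stat_c <= stat_u


class TestGroupLocationTests:
    def test_identical_samples(self):
        a = np.array([1.0, 2, 3, 4])
        ks_p, rs_p, ma, mb = group_location_tests(a, a)
        assert ks_p == pytest.approx(1.0)
        assert rs_p == pytest.approx(1.0)
        assert ma == mb

    def test_disjoint_supports_ks_statistic_one(self):
        a = np.arange(20.0)
        b = a + 100
        stat = sps.ks_2samp(a, b).statistic
        assert stat == 1.0
        ks_p, rs_p, _, _ = group_location_tests(a, b)
        assert ks_p < 1e-6 and rs_p < 1e-4

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ranksum_matches_enumeration_4v4(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(4)
        b = rng.standard_normal(4)
        _, rs_p, _, _ = group_location_tests(a, b)
        assert rs_p == pytest.approx(exact_ranksum_p(a, b), rel=1e-9)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_case(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(7)
        p = rng.random(50)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
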