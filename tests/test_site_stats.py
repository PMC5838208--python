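"""Site-level statistics against independent oracles and exact enumeration."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from methyltiers import site_stats
from methyltiers.beta_io import CASE, REF, BetaMatrix
from methyltiers.site_stats import (
    ContingencyTable,
    cohens_d,
    cramers_v,
    dice_index,
    hodges_lehmann,
    hodges_lehmann_rows,
    one_sample_test_vs_half,
    pooled_ecdf,
    rank_sum_test_rows,
    signed_rank_test_rows,
    storey_qvalues,
    two_sample_shift_test,
)

finite_beta = st.floats(min_value=0.001, max_value=0.999)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def hl_oracle(case, ref):
    return float(np.median([c - r for c in case for r in ref]))


def exact_mw_oracle(case, ref, side):
    """One-sided rank-sum p by full enumeration over all rank splits."""
    pooled = np.concatenate([case, ref])
    n = len(case)
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n].sum()
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        w = ranks[list(idx)].sum()
        total += 1
        if (side == "greater" and w >= w_obs - 1e-9) or (side == "less" and w <= w_obs + 1e-9):
            count += 1
    return count / total


def exact_signed_rank_oracle(values, side):
    """One-sided signed-rank p vs 0.5 by enumerating all 2^n sign patterns."""
    d = np.asarray(values, dtype=float) - 0.5
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if (side == "greater" and w >= w_obs - 1e-9) or (side == "less" and w <= w_obs + 1e-9):
            count += 1
    return count / 2**n


# ---------------------------------------------------------------------------
# Hodges-Lehmann
# ---------------------------------------------------------------------------

class TestHodgesLehmann:
    def test_hand_example(self):
        # pairwise differences {0.05, 0.10, 0.15, 0.20} -> median 0.125
        assert hodges_lehmann([0.6, 0.7], [0.5, 0.55]) == pytest.approx(0.125)

    def test_identical_singletons(self):
        assert hodges_lehmann([0.4], [0.4]) == 0.0

    @given(
        st.lists(finite_beta, min_size=1, max_size=8),
        st.lists(finite_beta, min_size=1, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_oracle_and_antisymmetry(self, x, y):
        hl = hodges_lehmann(x, y)
        assert hl == pytest.approx(hl_oracle(x, y))
        assert hodges_lehmann(y, x) == pytest.approx(-hl)

    def test_rowwise_agrees_with_scalar(self, rng):
        case = rng.random((50, 14))
        ref = rng.random((50, 5))
        ref[3, 2] = np.nan  # pairwise-complete handling
        rows = hodges_lehmann_rows(case, ref)
        for i in range(50):
            assert rows[i] == pytest.approx(hodges_lehmann(case[i], ref[i]))


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

class TestTwoSampleTest:
    def test_exact_small_example(self):
        # case {3,4} vs ref {1,2}: most extreme of C(4,2)=6 splits
        assert two_sample_shift_test([3, 4], [1, 2], 0, "greater") == pytest.approx(1 / 6)

    def test_no_separation_gives_large_p(self):
        x = [0.2, 0.4, 0.6]
        assert two_sample_shift_test(x, x, 0, "greater") >= 0.5
        assert two_sample_shift_test(x, x, 0, "less") >= 0.5

    def test_shift_zero_matches_scipy_exact(self, rng):
        for _ in range(20):
            case = rng.random(6)
            ref = rng.random(5)
            ours = two_sample_shift_test(case, ref, 0, "greater")
            ref_p = sps.mannwhitneyu(case, ref, alternative="greater", method="exact").pvalue
            assert ours == pytest.approx(ref_p)

    @pytest.mark.parametrize("n,m", [(3, 4), (5, 5), (8, 8), (5, 14)])
    def test_exact_p_equals_full_enumeration(self, n, m, rng):
        for _ in range(3):
            case = rng.random(n)
            ref = rng.random(m)
            if comb(n + m, n) > 20000:
                continue
            for side in ("greater", "less"):
                assert two_sample_shift_test(case, ref, 0, side) == pytest.approx(
                    exact_mw_oracle(case, ref, side)
                )

    def test_shifted_null_is_calibrated(self, rng):
        # at shift = the true offset, p should be ~uniform: check type-I error
        alpha = 0.025
        n_rep = 2000
        case = rng.random((n_rep, 14)) + 0.1
        ref = rng.random((n_rep, 5))
        p = rank_sum_test_rows(case, ref, shift=0.1, side="greater")
        frac = (p < alpha).mean()
        mc_se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert frac <= alpha + 2 * mc_se

    def test_rowwise_agrees_with_scalar_with_ties_and_nans(self, rng):
        case = rng.integers(0, 5, size=(40, 14)) / 4.0  # heavy ties
        ref = rng.integers(0, 5, size=(40, 5)) / 4.0
        case = case.astype(float)
        case[2, 1] = np.nan
        for side in ("greater", "less"):
            rows = rank_sum_test_rows(case, ref, 0.02, side)
            for i in range(40):
                assert rows[i] == pytest.approx(
                    two_sample_shift_test(case[i], ref[i], 0.02, side)
                )

    def test_empty_group_rejected(self):
        with pytest.raises(site_stats.DegenerateDataError):
            two_sample_shift_test([], [0.1], 0, "greater")


class TestOneSampleTest:
    def test_all_below_half_n5(self):
        p, degen = one_sample_test_vs_half([0.1, 0.2, 0.3, 0.4, 0.45], "less")
        assert p == pytest.approx(1 / 32)
        assert not degen

    def test_single_observation(self):
        p, _ = one_sample_test_vs_half([0.6], "greater")
        assert p == pytest.approx(0.5)

    def test_one_sided_p_values_sum_identity(self, rng):
        # p_less + p_greater = 1 + P(W = w_obs) on untied data
        v = rng.random(7)
        p_l, _ = one_sample_test_vs_half(v, "less")
        p_g, _ = one_sample_test_vs_half(v, "greater")
        assert p_l + p_g > 1.0
        assert p_l + p_g < 1.0 + 0.5  # point mass bounded

    def test_all_half_degenerate(self):
        p, degen = one_sample_test_vs_half([0.5, 0.5, 0.5], "less")
        assert p == 1.0 and degen

    @pytest.mark.parametrize("n", [2, 4, 6, 8])
    def test_exact_p_equals_sign_enumeration(self, n, rng):
        for _ in range(5):
            v = rng.random(n)
            for side in ("greater", "less"):
                p, _ = one_sample_test_vs_half(v, side)
                assert p == pytest.approx(exact_signed_rank_oracle(v, side))

    def test_rowwise_agrees_with_scalar(self, rng):
        mat = rng.random((30, 5))
        mat[4, 0] = 0.5  # zero difference path
        mat[7, 1] = np.nan
        for side in ("greater", "less"):
            rows = signed_rank_test_rows(mat, side)
            for i in range(30):
                assert rows[i] == pytest.approx(one_sample_test_vs_half(mat[i], side)[0])

    def test_status_calls(self):
        low = np.full(14, 0.1) + np.arange(14) * 1e-3
        high = 1 - low
        assert site_stats.methylation_status(low) == "low"
        assert site_stats.methylation_status(high) == "high"
        assert site_stats.methylation_status(np.linspace(0.3, 0.7, 14)) == "medium"

    def test_t_family_allows_small_group_calls(self):
        # the exact rank test cannot reject at n=5 (min p = 1/32 > 0.025)
        low5 = np.array([0.05, 0.08, 0.1, 0.12, 0.15])
        assert site_stats.methylation_status(low5) == "medium"
        assert site_stats.methylation_status(low5, family="t") == "low"


# ---------------------------------------------------------------------------
# pooled distribution summaries, effect sizes
# ---------------------------------------------------------------------------

def make_beta(values_ref, values_case):
    nr, nc = values_ref.shape[1], values_case.shape[1]
    ref_ids = [f"r{i}" for i in range(nr)]
    case_ids = [f"c{i}" for i in range(nc)]
    return BetaMatrix(
        [f"cg{i}" for i in range(values_ref.shape[0])],
        ref_ids + case_ids,
        np.concatenate([values_ref, values_case], axis=1),
        {**{s: REF for s in ref_ids}, **{s: CASE for s in case_ids}},
    )


class TestPooledSummaries:
    def test_two_point_ecdf(self):
        beta = make_beta(np.array([[0.2], [0.8]]), np.array([[0.5], [0.5]]))
        summ = pooled_ecdf(beta, REF)
        assert summ.ecdf(0.2) == pytest.approx(0.5)
        assert summ.ecdf(0.8) == pytest.approx(1.0)

    def test_ecdf_matches_sort_and_count(self, rng):
        vals = rng.random((25, 4))
        beta = make_beta(vals, rng.random((25, 3)))
        summ = pooled_ecdf(beta, REF)
        pooled = vals.ravel()
        for v in pooled:
            assert summ.ecdf(v) == pytest.approx((pooled <= v).mean())
        assert summ.n == pooled.size

    def test_cohens_d_hand_value(self):
        # means 2 vs 1, pooled sd 2/sqrt(3) -> d = sqrt(3)/2
        assert cohens_d([1, 1, 3, 3], [0, 0, 2, 2]) == pytest.approx(np.sqrt(3) / 2)

    def test_cohens_d_antisymmetric_and_zero(self, rng):
        x, y = rng.random(10), rng.random(12)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))
        assert cohens_d(x, x) == 0.0


class TestCramersV:
    def test_perfect_association(self):
        t = ContingencyTable(("a", "b"), ("x", "y"), np.array([[10, 0], [0, 10]]))
        v, chi2, p = cramers_v(t)
        assert v == pytest.approx(1.0)

    def test_permutation_invariance_and_range(self, rng):
        counts = rng.integers(1, 100, size=(3, 3))
        t = ContingencyTable(("a", "b", "c"), ("x", "y", "z"), counts)
        v, _, _ = cramers_v(t)
        assert 0 <= v <= 1
        perm = rng.permutation(3)
        t2 = ContingencyTable(("a", "b", "c"), ("x", "y", "z"), counts[perm][:, perm])
        assert cramers_v(t2)[0] == pytest.approx(v)

    def test_degenerate_margin_rejected(self):
        t = ContingencyTable(("a", "b"), ("x", "y"), np.array([[5, 5], [0, 0]]))
        with pytest.raises(site_stats.DegenerateDataError):
            cramers_v(t)


# ---------------------------------------------------------------------------
# Storey q-values and Dice
# ---------------------------------------------------------------------------

class TestStorey:
    def test_single_p(self):
        q, pi0 = storey_qvalues([0.02])
        assert q[0] <= 0.02 and pi0 <= 1.0

    def test_ties_get_equal_q(self):
        q, _ = storey_qvalues([0.3] * 10)
        assert np.allclose(q, q[0])

    def test_pi0_one_equals_benjamini_hochberg(self, rng):
        p = rng.random(500) ** 2
        q, _ = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, rtol=1e-12)

    def test_q_monotone_in_p_and_bounded(self, rng):
        p = np.concatenate([rng.random(400) * 0.01, rng.random(600)])
        q, pi0 = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= 0).all() and (q <= 1).all()
        assert 0 < pi0 <= 1

    def test_pi0_estimates_null_fraction(self, rng):
        # 70% uniform nulls + 30% strong signals
        p = np.concatenate([rng.random(7000), rng.random(3000) * 1e-4])
        _, pi0 = storey_qvalues(p)
        assert 0.6 < pi0 < 0.85

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])


class TestDice:
    def test_identical_and_disjoint(self):
        assert dice_index({"a", "b"}, {"a", "b"}) == 1.0
        assert dice_index({"a"}, {"b"}) == 0.0
        assert dice_index(set(), set()) == 0.0

    def test_published_site_overlap_magnitude(self):
        # 28,089- and 29,609-site detection sets sharing 18,367 sites
        a = {f"s{i}" for i in range(28089)}
        b = {f"s{i}" for i in range(28089 - 18367, 28089 - 18367 + 29609)}
        assert dice_index(a, b) == pytest.approx(2 * 18367 / (28089 + 29609))
        assert round(100 * dice_index(a, b)) == 64
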