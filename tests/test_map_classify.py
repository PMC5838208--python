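"""Maximum-probability boundaries, tier cutoffs and site classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from methyltiers.gmm1d import GaussianMixture1D
from methyltiers.map_classify import (
    ModelShapeError,
    TierCall,
    TierCutoffs,
    classify_sites,
    component_intersections,
    derive_tier_cutoffs,
    map_partition,
    status_contingency,
    tier_counts,
)
from methyltiers.reference import PUBLISHED_UP_CUTOFFS, hl_reference_mixture


class TestIntersections:
    def test_equal_sigma_equal_weight_midpoint(self):
        roots = component_intersections((0.0, 1.0, 0.5), (2.0, 1.0, 0.5))
        assert len(roots) == 1
        assert roots[0] == pytest.approx(1.0)

    def test_first_published_cutoff_from_component_pair(self):
        # the near-zero and the first broad positive component cross at ~0.0096
        roots = component_intersections((0.0019, 0.0051, 0.2148), (0.0128, 0.0189, 0.2645))
        upper = max(roots)
        assert upper == pytest.approx(0.0096, abs=0.0005)

    @given(
        st.floats(-1, 1), st.floats(0.01, 0.5), st.floats(0.1, 0.9),
        st.floats(-1, 1), st.floats(0.01, 0.5), st.floats(0.1, 0.9),
    )
    @settings(max_examples=150, deadline=None)
    def test_roots_have_zero_density_residual(self, m1, s1, w1, m2, s2, w2):
        if (m1, s1, w1) == (m2, s2, w2):
            return
        for x in component_intersections((m1, s1, w1), (m2, s2, w2)):
            d1 = w1 * norm.pdf(x, m1, s1)
            d2 = w2 * norm.pdf(x, m2, s2)
            assert abs(d1 - d2) < 1e-9

    def test_identical_components_rejected(self):
        with pytest.raises(ValueError):
            component_intersections((0.0, 1.0, 0.5), (0.0, 1.0, 0.5))


def random_mixture(rng, K):
    mu = np.sort(rng.uniform(-0.5, 0.5, K))
    sigma = rng.uniform(0.01, 0.2, K)
    w = rng.dirichlet(np.ones(K) * 2)
    w = np.maximum(w, 0.01)
    return GaussianMixture1D(mu, sigma, w / w.sum())


class TestMapPartition:
    def test_two_equal_components_midpoint(self):
        m = GaussianMixture1D([0.0, 2.0], [0.5, 0.5], [0.5, 0.5])
        bounds = map_partition(m)
        assert len(bounds) == 1
        assert bounds[0][0] == pytest.approx(1.0, abs=1e-6)

    def test_published_mixture_positive_boundaries(self):
        bounds = [b for b, _, _ in map_partition(hl_reference_mixture()) if b > 0]
        for got, expected in zip(bounds[:3], PUBLISHED_UP_CUTOFFS):
            assert got == pytest.approx(expected, abs=0.002)

    def test_boundaries_match_independent_grid_argmax(self, rng):
        # brute-force oracle: argmax over a fine independent grid changes
        # exactly at the returned boundaries
        for trial in range(25):
            m = random_mixture(rng, int(rng.integers(2, 9)))
            bounds = map_partition(m, grid_step=1e-4)
            ms = m.sorted_by_mean()
            lo = float((ms.mu - 6 * ms.sigma).min())
            hi = float((ms.mu + 6 * ms.sigma).max())
            x = np.linspace(lo, hi, 200_001)
            step = x[1] - x[0]
            am = np.argmax(ms.component_densities(x), axis=0)
            oracle = [0.5 * (x[i] + x[i + 1]) for i in np.nonzero(np.diff(am))[0]]
            assert len(oracle) == len(bounds)
            for got, exp in zip(sorted(b for b, _, _ in bounds), oracle):
                assert abs(got - exp) <= step + 1e-4

    def test_single_component_rejected(self):
        with pytest.raises(ModelShapeError):
            map_partition(GaussianMixture1D([0.0], [1.0], [1.0]))


class TestTierCutoffs:
    def test_published_cutoffs_reproduced(self):
        cutoffs = derive_tier_cutoffs(hl_reference_mixture())
        for got, expected in zip(cutoffs.up, PUBLISHED_UP_CUTOFFS):
            assert got == pytest.approx(expected, abs=0.002)
        assert cutoffs.provenance  # component pairs recorded

    def test_symmetric_mixture_gives_mirrored_down(self):
        mu = np.array([-0.4, -0.15, -0.05, -0.01, 0.01, 0.05, 0.15, 0.4])
        sigma = np.array([0.05, 0.03, 0.02, 0.005, 0.005, 0.02, 0.03, 0.05])
        w = np.full(8, 0.125)
        cutoffs = derive_tier_cutoffs(GaussianMixture1D(mu, sigma, w))
        assert cutoffs.down is not None
        np.testing.assert_allclose(cutoffs.down, [-b for b in cutoffs.up], atol=1e-6)

    def test_invariant_to_component_order(self, rng):
        m = hl_reference_mixture()
        perm = rng.permutation(m.K)
        m2 = GaussianMixture1D(m.mu[perm], m.sigma[perm], m.w[perm])
        np.testing.assert_allclose(derive_tier_cutoffs(m2).up, derive_tier_cutoffs(m).up)

    def test_too_coarse_model_rejected(self):
        m = GaussianMixture1D([0.0, 0.1], [0.01, 0.01], [0.5, 0.5])
        with pytest.raises(ModelShapeError):
            derive_tier_cutoffs(m)

    def test_cutoff_ordering_enforced(self):
        with pytest.raises(ValueError):
            TierCutoffs(up=(0.05, 0.02, 0.08))


def results_frame(rows):
    cols = [
        "site_id", "hl", "p_up", "p_down", "q_up", "q_down",
        "p_up_medium", "p_up_high", "p_up_extreme",
    ]
    return pd.DataFrame(rows, columns=cols)


CUT = TierCutoffs(up=PUBLISHED_UP_CUTOFFS)


class TestClassify:
    def test_insignificant_site_gets_none(self):
        df = results_frame([["s1", 0.2, 0.5, 0.5, 0.9, 0.9, 0.9, 0.9, 0.9]])
        calls = classify_sites(df, CUT)
        assert calls[0].direction == "none" and calls[0].tier == "none"

    def test_strong_site_reaches_extreme(self):
        df = results_frame([["s1", 0.10, 0.001, 0.999, 0.01, 1.0, 0.001, 0.001, 0.001]])
        assert classify_sites(df, CUT)[0].tier == "extreme"

    def test_medium_but_not_high(self):
        df = results_frame([["s1", 0.02, 0.001, 0.999, 0.01, 1.0, 0.001, 0.5, 0.9]])
        assert classify_sites(df, CUT)[0].tier == "medium"

    def test_hl_must_exceed_cutoff_too(self):
        # shifted test significant but point estimate below the boundary
        df = results_frame([["s1", 0.005, 0.001, 0.999, 0.01, 1.0, 0.001, 0.9, 0.9]])
        assert classify_sites(df, CUT)[0].tier == "significant"

    def test_hl_filter_rule(self):
        df = results_frame([["s1", 0.05, 0.001, 0.999, 0.01, 1.0, 0.9, 0.9, 0.9]])
        assert classify_sites(df, CUT, tier_rule="hl_filter")[0].tier == "high"

    def test_missing_shifted_column_rejected(self):
        df = results_frame([["s1", 0.1, 0.001, 0.9, 0.01, 1.0, 0.001, 0.001, 0.001]])
        with pytest.raises(KeyError):
            classify_sites(df.drop(columns=["p_up_high"]), CUT)

    def test_tier_sets_nest_and_monotone_in_hl(self):
        rows = []
        rng = np.random.default_rng(3)
        for i in range(300):
            hl = rng.uniform(-0.05, 0.15)
            p = rng.uniform(0, 0.05)
            rows.append([
                f"s{i}", hl, p, 1 - p, p, 1 - p,
                rng.uniform(0, 0.05), rng.uniform(0, 0.05), rng.uniform(0, 0.05),
            ])
        df = results_frame(rows)
        calls = classify_sites(df, CUT)
        counts = tier_counts(calls, "up")
        assert (
            counts["extreme_high"]
            <= counts["at_least_high"]
            <= counts["at_least_medium"]
            <= counts["significant"]
        )
        # raising HL (all else fixed) never lowers the tier
        order = {"none": 0, "significant": 1, "medium": 2, "high": 3, "extreme": 4}
        df2 = df.copy()
        df2["hl"] = df2["hl"] + 0.05
        calls2 = classify_sites(df2, CUT)
        for c1, c2 in zip(calls, calls2):
            if c1.direction == "up":
                assert order[c2.tier] >= order[c1.tier]


class TestDynamics:
    def test_enhancement_and_compensation_classes(self):
        ref_status = ["high", "low", "low", "medium", "high"]
        case_status = ["high", "low", "high", "medium", "low"]
        direction = ["up", "down", "up", "none", "down"]
        out = status_contingency(ref_status, case_status, direction)
        # high&up + low&down -> enhancement/diminution; low&up + high&down -> compensation
        assert out["enhancement_diminution"] == 2
        assert out["compensation"] == 2
        assert out["status_table"].counts.sum() == 5
        assert out["dynamics_table"].counts.sum() == 5

    def test_tier_call_validation(self):
        with pytest.raises(ValueError):
            TierCall("s1", "none", "medium")
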