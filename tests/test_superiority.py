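import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from betalift import (BetaParams, PairedSamples, ecdf, prob_ratio_exact,
                      prob_superior, prob_superior_exact, relative_improvement,
                      sample_pair)
from betalift.errors import ConfigError, DataError

from .conftest import POSTERIOR_EXPOSED, POSTERIOR_REFERENCE

# frozen exact values for the reference posterior pair, cross-validated
# below against independent quadrature / large-sample Monte Carlo
EXACT_SUPERIORITY = 0.8632552054869687
EXACT_RATIO_GE_1_5 = 0.19239468715099642

small_int = st.integers(min_value=1, max_value=200)


class TestSamplePair:
    def test_reproducible(self):
        s1 = sample_pair(BetaParams(2, 3), BetaParams(3, 2), 500, seed=42)
        s2 = sample_pair(BetaParams(2, 3), BetaParams(3, 2), 500, seed=42)
        assert np.array_equal(s1.arm_a, s2.arm_a)
        assert np.array_equal(s1.arm_b, s2.arm_b)

    def test_different_seed_differs(self):
        s1 = sample_pair(BetaParams(2, 3), BetaParams(3, 2), 500, seed=1)
        s2 = sample_pair(BetaParams(2, 3), BetaParams(3, 2), 500, seed=2)
        assert not np.array_equal(s1.arm_a, s2.arm_a)

    def test_marginal_means(self):
        s = sample_pair(POSTERIOR_EXPOSED, POSTERIOR_REFERENCE, 100_000, seed=3)
        for arr, dist in ((s.arm_a, POSTERIOR_EXPOSED),
                          (s.arm_b, POSTERIOR_REFERENCE)):
            se = math.sqrt(arr.var() / arr.size)
            assert abs(arr.mean() - dist.mean) < 3 * se

    def test_single_trial(self):
        s = sample_pair(BetaParams(1, 1), BetaParams(1, 1), 1, seed=0)
        assert 0 < s.arm_a[0] < 1 and 0 < s.arm_b[0] < 1

    def test_n_trials_domain(self):
        with pytest.raises(ConfigError):
            sample_pair(BetaParams(1, 1), BetaParams(1, 1), 0, seed=0)


class TestProbSuperior:
    def test_paper_pair(self):
        s = sample_pair(POSTERIOR_EXPOSED, POSTERIOR_REFERENCE, 100_000)
        res = prob_superior(s)
        assert round(res.prob_superior, 2) == 0.86
        assert abs(res.prob_superior - EXACT_SUPERIORITY) \
            < 3 * res.mc_standard_error

    def test_identical_distributions(self):
        s = sample_pair(BetaParams(5, 5), BetaParams(5, 5), 100_000, seed=9)
        res = prob_superior(s)
        assert abs(res.prob_superior - 0.5) < 3 * res.mc_standard_error + 1e-3

    def test_separated_supports(self):
        s = sample_pair(BetaParams(100, 1), BetaParams(1, 100), 10_000, seed=5)
        assert prob_superior(s).prob_superior > 0.999

    def test_ties_count_as_non_superior(self):
        x = np.full(10, 0.5)
        s = PairedSamples(x, x.copy(), 10, seed=0)
        assert prob_superior(s).prob_superior == 0.0

    def test_mc_standard_error(self):
        s = sample_pair(POSTERIOR_EXPOSED, POSTERIOR_REFERENCE, 10_000, seed=1)
        res = prob_superior(s)
        p = res.prob_superior
        assert res.mc_standard_error == pytest.approx(
            math.sqrt(p * (1 - p) / 10_000))


class TestProbSuperiorExact:
    def test_symmetry_uniform(self):
        assert prob_superior_exact(BetaParams(1, 1), BetaParams(1, 1)) == \
            pytest.approx(0.5, abs=1e-10)

    def test_closed_form_integral(self):
        # X ~ Beta(2,1) (CDF x^2), Y uniform: P(X > Y) = 2/3
        assert prob_superior_exact(BetaParams(2, 1), BetaParams(1, 1)) == \
            pytest.approx(2 / 3, abs=1e-10)

    def test_paper_pair_against_quadrature_oracle(self):
        # independent oracle: direct quadrature of pdf_a * CDF_b
        val, err = integrate.quad(
            lambda x: stats.beta.pdf(x, 17, 17) * stats.beta.cdf(x, 51, 78),
            0, 1, epsabs=1e-12)
        assert val == pytest.approx(EXACT_SUPERIORITY, abs=1e-9)
        exact = prob_superior_exact(POSTERIOR_EXPOSED, POSTERIOR_REFERENCE)
        assert exact == pytest.approx(EXACT_SUPERIORITY, abs=1e-8)
        assert round(exact, 2) == 0.86

    def test_sum_and_quadrature_paths_agree(self):
        # nudge one shape off the integers to force the quadrature path
        sum_path = prob_superior_exact(BetaParams(17, 17), BetaParams(51, 78))
        quad_path = prob_superior_exact(BetaParams(17 + 1e-9, 17),
                                        BetaParams(51 + 1e-9, 78))
        assert sum_path == pytest.approx(quad_path, abs=1e-6)

    @given(small_int, small_int, small_int, small_int)
    @settings(derandomize=True, deadline=None, max_examples=25)
    def test_complement_identity(self, a1, b1, a2, b2):
        da, db = BetaParams(a1, b1), BetaParams(a2, b2)
        total = prob_superior_exact(da, db) + prob_superior_exact(db, da)
        assert total == pytest.approx(1.0, abs=1e-8)

    @given(small_int, small_int, small_int, small_int)
    @settings(derandomize=True, deadline=None, max_examples=25)
    def test_mc_agrees_with_exact(self, a1, b1, a2, b2):
        da, db = BetaParams(a1, b1), BetaParams(a2, b2)
        exact = prob_superior_exact(da, db)
        n = 20_000
        mc = prob_superior(sample_pair(da, db, n, seed=12345)).prob_superior
        # 5/n floor covers the Poisson tail when exact*(1-exact) is tiny
        tol = 3 * math.sqrt(exact * (1 - exact) / n) + 5 / n
        assert abs(mc - exact) <= tol

    @given(small_int, small_int, small_int, small_int,
           st.integers(min_value=1, max_value=50))
    @settings(derandomize=True, deadline=None, max_examples=25)
    def test_stochastic_dominance_in_alpha(self, a1, b1, a2, b2, bump):
        base = prob_superior_exact(BetaParams(a1, b1), BetaParams(a2, b2))
        bumped = prob_superior_exact(BetaParams(a1 + bump, b1),
                                     BetaParams(a2, b2))
        assert bumped >= base - 1e-9

    def test_invalid_params(self):
        with pytest.raises(ConfigError):
            prob_superior_exact(BetaParams(1, 1), BetaParams(-1, 1))


@pytest.fixture(scope="module")
def paper_samples():
    return sample_pair(POSTERIOR_EXPOSED, POSTERIOR_REFERENCE, 100_000)


class TestRelativeImprovement:
    def test_paper_percentiles(self, paper_samples):
        summary = relative_improvement(paper_samples, numerator="a")
        # exact values are ~1.098 / 1.265 / 1.445; printed 1.10 / 1.26 / 1.44
        assert summary.percentiles[25.0] == pytest.approx(1.10, abs=0.01)
        assert summary.percentiles[50.0] == pytest.approx(1.265, abs=0.01)
        assert summary.percentiles[75.0] == pytest.approx(1.445, abs=0.01)

    def test_threshold_probability(self, paper_samples):
        summary = relative_improvement(paper_samples)
        p = summary.threshold_probs[1.5]
        se = math.sqrt(p * (1 - p) / summary.n_trials)
        assert abs(p - EXACT_RATIO_GE_1_5) < 3 * se

    def test_auto_numerator_picks_superior_arm(self, paper_samples):
        assert relative_improvement(paper_samples).numerator == "a"
        flipped = sample_pair(POSTERIOR_REFERENCE, POSTERIOR_EXPOSED,
                              50_000, seed=8)
        assert relative_improvement(flipped).numerator == "b"

    def test_identical_distributions_median_one(self):
        s = sample_pair(BetaParams(6, 6), BetaParams(6, 6), 100_000, seed=13)
        summary = relative_improvement(s, numerator="a")
        assert summary.percentiles[50.0] == pytest.approx(1.0, abs=0.02)

    def test_percentiles_monotone(self, paper_samples):
        summary = relative_improvement(
            paper_samples, percentile_grid=(5, 25, 50, 75, 95))
        vals = [summary.percentiles[q] for q in sorted(summary.percentiles)]
        assert vals == sorted(vals)

    def test_threshold_probs_non_increasing(self, paper_samples):
        summary = relative_improvement(
            paper_samples, thresholds=(1.0, 1.25, 1.5, 2.0))
        probs = [summary.threshold_probs[t]
                 for t in sorted(summary.threshold_probs)]
        assert all(p1 >= p2 for p1, p2 in zip(probs, probs[1:]))

    def test_bad_numerator(self, paper_samples):
        with pytest.raises(ConfigError):
            relative_improvement(paper_samples, numerator="c")


class TestEcdf:
    def test_enumeration(self):
        values, fractions = ecdf([3, 1, 2])
        assert np.array_equal(values, [1, 2, 3])
        assert np.allclose(fractions, [1 / 3, 2 / 3, 1.0])

    def test_constant_list(self):
        values, fractions = ecdf([4.0, 4.0, 4.0])
        assert np.array_equal(values, [4.0, 4.0, 4.0])
        assert fractions[-1] == 1.0

    def test_empty_errors(self):
        with pytest.raises(DataError):
            ecdf([])

    def test_median_self_consistency(self):
        s = sample_pair(POSTERIOR_EXPOSED, POSTERIOR_REFERENCE, 50_000, seed=2)
        summary = relative_improvement(s, numerator="a")
        med = summary.percentiles[50.0]
        frac_at_median = summary.ecdf_fractions[
            np.searchsorted(summary.ecdf_values, med, side="right") - 1]
        assert frac_at_median == pytest.approx(0.5, abs=0.01)


class TestProbRatioExact:
    def test_tiny_threshold_is_one(self):
        assert prob_ratio_exact(BetaParams(3, 4), BetaParams(4, 3), 1e-12) == \
            pytest.approx(1.0, abs=1e-9)

    def test_uniform_pair_threshold_one(self):
        assert prob_ratio_exact(BetaParams(1, 1), BetaParams(1, 1), 1.0) == \
            pytest.approx(0.5, abs=1e-9)

    def test_paper_pair_threshold(self):
        exact = prob_ratio_exact(POSTERIOR_EXPOSED, POSTERIOR_REFERENCE, 1.5)
        assert exact == pytest.approx(EXACT_RATIO_GE_1_5, abs=1e-6)
        # independent large-sample Monte Carlo oracle
        rng = np.random.default_rng(99)
        r = rng.beta(17, 17, 2_000_000) / rng.beta(51, 78, 2_000_000)
        mc = float(np.mean(r >= 1.5))
        assert abs(mc - exact) < 3 * math.sqrt(exact * (1 - exact) / 2e6)

    def test_matches_superiority_at_threshold_one(self):
        # P(X/Y >= 1) equals P(X > Y) for continuous variables
        assert prob_ratio_exact(POSTERIOR_EXPOSED, POSTERIOR_REFERENCE, 1.0) \
            == pytest.approx(EXACT_SUPERIORITY, abs=1e-6)

    def test_threshold_domain(self):
        with pytest.raises(ConfigError):
            prob_ratio_exact(BetaParams(1, 1), BetaParams(1, 1), 0.0)

    @given(small_int, small_int, small_int, small_int,
           st.floats(min_value=0.5, max_value=2.5))
    @settings(derandomize=True, deadline=None, max_examples=15)
    def test_mc_agrees_with_exact(self, a1, b1, a2, b2, t):
        da, db = BetaParams(a1, b1), BetaParams(a2, b2)
        exact = prob_ratio_exact(da, db, t)
        s = sample_pair(da, db, 20_000, seed=54321)
        mc = float(np.mean(s.arm_a / s.arm_b >= t))
        tol = 3 * math.sqrt(exact * (1 - exact) / 20_000) + 5 / 20_000
        assert abs(mc - exact) <= tol
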