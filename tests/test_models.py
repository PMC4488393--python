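"""Unit tests for the exact survey-total distributions and samplers."""

import itertools

import numpy as np
import pytest
from scipy.stats import binom

from clusterlqas import (
    ClusteringSpec,
    DesignTargets,
    TotalPMF,
    betabinomial_pmf,
    binomial_risks,
    binomial_scaled_pmf,
    cluster_pmf,
    convolve_iid,
    failure_rule_to_success,
    hund_effective,
    model_risks,
    sample_total,
    sample_totals,
    total_pmf,
)

from _reference import SEED


class TestTotalPMF:
    def test_normalization_enforced(self):
        with pytest.raises(ValueError):
            TotalPMF(np.array([0.5, 0.4]))

    def test_cdf_sf_complementary(self):
        pmf = TotalPMF(binom.pmf(np.arange(11), 10, 0.3))
        for d in range(-1, 12):
            assert pmf.cdf(d) + pmf.sf(d) == pytest.approx(1.0)

    def test_moments_match_binomial(self):
        pmf = TotalPMF(binom.pmf(np.arange(21), 20, 0.4))
        assert pmf.mean() == pytest.approx(8.0)
        assert pmf.var() == pytest.approx(20 * 0.4 * 0.6)


class TestBinomialRisks:
    def test_definition(self):
        a, b = binomial_risks(40, 33, 0.75, 0.90)
        assert a == pytest.approx(float(binom.cdf(33, 40, 0.90)))
        assert b == pytest.approx(float(binom.sf(33, 40, 0.75)))

    def test_rule_out_of_range(self):
        with pytest.raises(ValueError):
            binomial_risks(10, 11, 0.5, 0.7)


class TestClusterPMFs:
    def test_betabinomial_normalizes_and_has_right_mean(self):
        pmf = betabinomial_pmf(10, 0.7, 0.1)
        assert pmf.sum() == pytest.approx(1.0)
        assert np.arange(11) @ pmf == pytest.approx(7.0)

    def test_betabinomial_variance_inflated_by_rho(self):
        # Var = m p (1-p) (1 + (m-1) rho)
        m, p, rho = 10, 0.7, 0.1
        pmf = betabinomial_pmf(m, p, rho)
        x = np.arange(m + 1)
        var = (x - 7.0) ** 2 @ pmf
        assert var == pytest.approx(m * p * (1 - p) * (1 + (m - 1) * rho))

    def test_betabinomial_rho_limits(self):
        np.testing.assert_allclose(
            betabinomial_pmf(5, 0.4, 0.0), binom.pmf(np.arange(6), 5, 0.4)
        )
        two_point = betabinomial_pmf(5, 0.4, 1.0)
        assert two_point[0] == pytest.approx(0.6)
        assert two_point[5] == pytest.approx(0.4)
        assert two_point[1:5].sum() == pytest.approx(0.0)

    def test_binomial_scaled_normalizes_and_has_right_mean(self):
        pmf = binomial_scaled_pmf(10, 0.7, 21)
        assert pmf.sum() == pytest.approx(1.0)
        assert np.arange(11) @ pmf == pytest.approx(7.0)

    def test_binomial_scaled_eta_one_is_two_point(self):
        # eta=1: cluster coverage is 0 or 1, so counts pile at 0 and m
        pmf = binomial_scaled_pmf(6, 0.3, 1)
        assert pmf[0] == pytest.approx(0.7)
        assert pmf[6] == pytest.approx(0.3)

    def test_binomial_scaled_variance_close_to_target(self):
        # With eta = p(1-p)/sigma^2 the latent SD is close to sigma, so the
        # count variance is close to the beta-binomial one at matching rho.
        m, p, sigma = 10, 0.7, 0.1
        spec = ClusteringSpec.from_sigma(sigma)
        pmf = binomial_scaled_pmf(m, p, spec.eta_at(p))
        x = np.arange(m + 1)
        var = (x - x @ pmf) ** 2 @ pmf
        target = m * p * (1 - p) * (1 + (m - 1) * spec.rho_at(p))
        assert var == pytest.approx(target, rel=0.02)

    def test_cluster_pmf_dispatch(self):
        spec = ClusteringSpec.from_rho(0.1)
        np.testing.assert_allclose(
            cluster_pmf("hedt", 10, 0.7, spec), betabinomial_pmf(10, 0.7, 0.1)
        )
        np.testing.assert_allclose(
            cluster_pmf("srs", 10, 0.7, spec), binom.pmf(np.arange(11), 10, 0.7)
        )
        with pytest.raises(ValueError):
            cluster_pmf("hund", 10, 0.7, spec)


class TestConvolution:
    def test_matches_exhaustive_enumeration_k3_m2(self):
        # Brute force: enumerate all 27 outcome triples of three iid
        # clusters of size 2 and accumulate total probabilities.
        base = betabinomial_pmf(2, 0.6, 0.2)
        expected = np.zeros(7)
        for combo in itertools.product(range(3), repeat=3):
            expected[sum(combo)] += np.prod([base[c] for c in combo])
        got = convolve_iid(base, 3)
        np.testing.assert_allclose(got.probs, expected, atol=1e-14)

    def test_binomial_clusters_convolve_to_binomial(self):
        got = convolve_iid(binom.pmf(np.arange(11), 10, 0.3), 5)
        np.testing.assert_allclose(
            got.probs, binom.pmf(np.arange(51), 50, 0.3), atol=1e-12
        )

    def test_k_validation(self):
        with pytest.raises(ValueError):
            convolve_iid(np.array([0.5, 0.5]), 0)

    def test_total_pmf_support(self):
        spec = ClusteringSpec.from_sigma(0.1)
        pmf = total_pmf("pezzoli", 6, 10, 0.7, spec)
        assert pmf.n == 60
        assert pmf.probs.sum() == pytest.approx(1.0)


class TestHundEffective:
    def test_published_effective_counts(self):
        # n=80, d=66, m=10, rho=.11: D=1.99 -> (40, 33)
        n_star, d_star, D = hund_effective(80, 66, 10, 0.11)
        assert (n_star, d_star) == (40, 33)
        assert D == pytest.approx(1.99)

    def test_rho_zero_identity(self):
        assert hund_effective(60, 38, 10, 0.0) == (60, 38, 1.0)


class TestFailureRule:
    def test_conversion(self):
        # 33x6 nutrition design: 13 allowed failures out of 198
        assert failure_rule_to_success(198, 13) == 184

    def test_round_trip(self):
        n = 60
        for d_fail in (0, 13, 59):
            d = failure_rule_to_success(n, d_fail)
            assert n - d - 1 == d_fail

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            failure_rule_to_success(10, 10)


class TestModelRisks:
    TARGETS = DesignTargets(0.75, 0.90)

    def test_srs_matches_binomial(self):
        assert model_risks("srs", 4, 10, 33, self.TARGETS) == pytest.approx(
            binomial_risks(40, 33, 0.75, 0.90)
        )

    def test_exact_models_match_pmf_tails(self):
        spec = ClusteringSpec.from_rho(0.1)
        for method in ("hedt", "pezzoli"):
            a, b = model_risks(method, 6, 10, 45, self.TARGETS, spec)
            assert a == pytest.approx(total_pmf(method, 6, 10, 0.90, spec).cdf(45))
            assert b == pytest.approx(total_pmf(method, 6, 10, 0.75, spec).sf(45))

    def test_hund_resolves_clustering_per_threshold(self):
        # sigma fixed: different rho (hence different rounding) at p_l, p_u
        spec = ClusteringSpec.from_sigma(0.1)
        a, b = model_risks("hund", 8, 10, 66, self.TARGETS, spec)
        n_u, d_u, _ = hund_effective(80, 66, 10, spec.rho_at(0.90))
        n_l, d_l, _ = hund_effective(80, 66, 10, spec.rho_at(0.75))
        assert a == pytest.approx(float(binom.cdf(d_u, n_u, 0.90)))
        assert b == pytest.approx(float(binom.sf(d_l, n_l, 0.75)))

    def test_hund_failure_scale_rounds_the_case_threshold(self):
        # 33x6 design, 13-failure rule, rho=.1: D=1.5, effective n=132,
        # effective case threshold round(13/1.5)=9.
        spec = ClusteringSpec.from_rho(0.1)
        targets = DesignTargets(0.90, 0.95)
        d = failure_rule_to_success(198, 13)
        a, b = model_risks("hund", 33, 6, d, targets, spec, rule_scale="failure")
        assert a == pytest.approx(float(binom.sf(9, 132, 0.05)))
        assert b == pytest.approx(float(binom.cdf(9, 132, 0.10)))

    def test_clustering_required(self):
        with pytest.raises(ValueError):
            model_risks("hedt", 6, 10, 40, self.TARGETS)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            model_risks("bogus", 6, 10, 40, self.TARGETS)


class TestSamplers:
    def test_deterministic_given_seed(self):
        spec = ClusteringSpec.from_sigma(0.1)
        a = sample_totals("hedt", 6, 10, 0.7, spec, 50, np.random.default_rng(SEED))
        b = sample_totals("hedt", 6, 10, 0.7, spec, 50, np.random.default_rng(SEED))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("method", ["srs", "hedt", "pezzoli", "hund"])
    def test_draws_in_support_with_plausible_mean(self, method):
        spec = ClusteringSpec.from_rho(0.1)
        k, m, p = 6, 10, 0.7
        draws = sample_totals(method, k, m, p, spec, 4000, np.random.default_rng(SEED))
        assert draws.min() >= 0 and draws.max() <= k * m
        if method == "hund":
            # rescaled effective draws have mean D * round(n/D) * p, which
            # differs from n*p by the rounding of the effective size
            from clusterlqas import design_effect, round_half_away

            D = design_effect(m, spec.rho_at(p))
            expected = D * round_half_away(k * m / D) * p
        else:
            expected = k * m * p
        se = np.sqrt(draws.var(ddof=1) / draws.size)
        assert abs(draws.mean() - expected) < 5 * max(se, 0.1)

    def test_latent_coverage_detail(self):
        spec = ClusteringSpec.from_sigma(0.1)
        sample = sample_total("pezzoli", 6, 10, 0.7, spec, SEED, return_clusters=True)
        assert sample.counts.shape == (6,)
        assert sample.latent_coverages.shape == (6,)
        # binomial-scaled coverages live on the eta-point lattice
        eta = spec.eta_at(0.7)
        np.testing.assert_allclose(
            np.round(sample.latent_coverages * eta),
            sample.latent_coverages * eta,
            atol=1e-12,
        )
        assert sample.total == sample.counts.sum()

    def test_cluster_detail_undefined_for_hund(self):
        spec = ClusteringSpec.from_rho(0.1)
        with pytest.raises(ValueError):
            sample_total("hund", 6, 10, 0.7, spec, SEED, return_clusters=True)
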