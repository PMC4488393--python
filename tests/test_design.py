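"""Unit tests for the decision-rule and sample-size searches."""

import numpy as np
import pytest
from scipy.stats import binom

from clusterlqas import (
    ClusteringSpec,
    DesignTargets,
    InfeasibleDesignError,
    TotalPMF,
    binomial_risks,
    cost_optimal_design,
    find_cluster_design,
    find_cluster_design_fixed_k,
    find_feasible_d,
    find_srs_design,
    hund_design,
    model_risks,
    pezzoli_design,
    total_pmf,
)

from _reference import COUPLETS, SEED, SRS_DESIGNS

T5570 = DesignTargets(*COUPLETS["55-70"])
T7590 = DesignTargets(*COUPLETS["75-90"])
T9095 = DesignTargets(*COUPLETS["90-95"])


class TestFindFeasibleD:
    def test_matches_brute_force(self):
        pmf_l = TotalPMF(binom.pmf(np.arange(41), 40, 0.75))
        pmf_u = TotalPMF(binom.pmf(np.arange(41), 40, 0.90))
        rules = find_feasible_d(pmf_l, pmf_u, T7590)
        feasible = [
            d
            for d in range(41)
            if pmf_u.cdf(d) <= 0.1 and pmf_l.sf(d) <= 0.1
        ]
        assert rules.d_min == min(feasible)
        assert rules.d_max == max(feasible)

    def test_none_when_infeasible(self):
        pmf_l = TotalPMF(binom.pmf(np.arange(11), 10, 0.75))
        pmf_u = TotalPMF(binom.pmf(np.arange(11), 10, 0.90))
        assert find_feasible_d(pmf_l, pmf_u, T7590) is None

    def test_mismatched_supports_rejected(self):
        pmf_a = TotalPMF(binom.pmf(np.arange(11), 10, 0.5))
        pmf_b = TotalPMF(binom.pmf(np.arange(12), 11, 0.5))
        with pytest.raises(ValueError):
            find_feasible_d(pmf_a, pmf_b, T7590)


class TestSRSSearch:
    @pytest.mark.parametrize("couplet", sorted(SRS_DESIGNS))
    def test_minimality(self, couplet):
        n, d, _, _ = SRS_DESIGNS[couplet]
        targets = DesignTargets(*COUPLETS[couplet])
        design = find_srs_design(targets)
        assert (design.n, design.d) == (n, d)
        # no smaller n admits any feasible rule
        for smaller in range(max(1, n - 3), n):
            alphas = binom.cdf(np.arange(smaller + 1), smaller, targets.p_u)
            betas = binom.sf(np.arange(smaller + 1), smaller, targets.p_l)
            assert not np.any((alphas <= 0.1) & (betas <= 0.1))

    def test_infeasible_cap_raises(self):
        with pytest.raises(InfeasibleDesignError):
            find_srs_design(DesignTargets(0.50, 0.51), n_max=100)


class TestClusterSearch:
    def test_reported_risks_are_self_consistent(self):
        spec = ClusteringSpec.from_rho(0.1)
        for method in ("hedt", "pezzoli", "hund"):
            design = find_cluster_design(method, T7590, spec, 10)
            a, b = model_risks(method, design.k, design.m, design.d, T7590, spec)
            assert design.alpha_hat == pytest.approx(a, abs=1e-12)
            assert design.beta_hat == pytest.approx(b, abs=1e-12)
            assert a <= 0.1 and b <= 0.1

    def test_minimality_in_k_for_exact_models(self):
        spec = ClusteringSpec.from_rho(0.1)
        for method in ("hedt", "pezzoli"):
            design = find_cluster_design(method, T7590, spec, 10)
            pmf_l = total_pmf(method, design.k - 1, 10, T7590.p_l, spec)
            pmf_u = total_pmf(method, design.k - 1, 10, T7590.p_u, spec)
            assert find_feasible_d(pmf_l, pmf_u, T7590) is None

    def test_clustering_used_records_both_thresholds(self):
        spec = ClusteringSpec.from_sigma(0.1)
        design = find_cluster_design("hedt", T7590, spec, 10)
        used = design.clustering_used
        assert used["rho_l"] == pytest.approx(spec.rho_at(0.75))
        assert used["rho_u"] == pytest.approx(spec.rho_at(0.90))

    def test_record_shape(self):
        spec = ClusteringSpec.from_rho(0.1)
        rec = find_cluster_design("hedt", T7590, spec, 10).to_record()
        assert rec["n"] == rec["k"] * rec["m"]
        for key in ("method", "n", "d", "k", "m", "alpha", "beta"):
            assert key in rec

    def test_cap_raises(self):
        spec = ClusteringSpec.from_rho(0.3)
        with pytest.raises(InfeasibleDesignError):
            find_cluster_design("hedt", T9095, spec, 10, k_max=5)


class TestHundDesign:
    def test_effective_rule_back_transforms_consistently(self):
        # With rho fixed, the effective binomial search mirrors the SRS
        # search; the returned d maps back onto the minimal effective rule.
        spec = ClusteringSpec.from_rho(0.1)
        design = hund_design(T7590, spec, 10)
        assert (design.n, design.d) == (90, 74)
        d_star = design.clustering_used["d_star"]
        D_u = design.clustering_used["D_u"]
        assert round(d_star * D_u) == design.d
        assert design.alpha_hat <= 0.1 and design.beta_hat <= 0.1

    def test_back_transform_ties_to_even(self):
        # 90-95 couplet, rho=.1, m=10: d* = 175 and D = 1.9 give
        # 175 * 1.9 = 332.5, reported as 332 (ties to even).
        spec = ClusteringSpec.from_rho(0.1)
        design = hund_design(T9095, spec, 10)
        assert (design.n, design.d) == (360, 332)
        assert design.clustering_used["d_star"] == 175

    def test_feasible_interval_contains_reported_rule(self):
        spec = ClusteringSpec.from_sigma(0.1)
        design = hund_design(T5570, spec, 10)
        assert design.feasible.d_min <= design.d <= design.feasible.d_max


class TestFixedKSearch:
    def test_grows_m_until_feasible(self):
        spec = ClusteringSpec.from_sigma(0.1)
        design = find_cluster_design_fixed_k("hedt", T7590, spec, 6)
        assert design.k == 6
        assert design.alpha_hat <= 0.1 and design.beta_hat <= 0.1
        # published envelope for this couplet at fixed k=6: n in [72, 150]
        assert 72 <= design.n <= 150

    def test_heavy_clustering_infeasible_at_any_m(self):
        # For the 90-95 couplet at sigma=.1 the design effect outgrows
        # the information added per subject: no m works at k=6.
        spec = ClusteringSpec.from_sigma(0.1)
        with pytest.raises(InfeasibleDesignError):
            find_cluster_design_fixed_k("hedt", T9095, spec, 6, m_max=120)


class TestPezzoliSimulationMode:
    def test_simulated_search_close_to_exact(self):
        spec = ClusteringSpec.from_sigma(0.1)
        exact = pezzoli_design(T7590, spec, 10, mode="exact")
        sim = pezzoli_design(
            T7590, spec, 10, mode="simulate", n_sims=10_000, seed=SEED
        )
        # the 75-90 couplet has a wide feasibility margin: the seeded
        # simulated search lands on the same (n, d)
        assert (sim.n, sim.d) == (exact.n, exact.d)
        assert sim.warnings  # simulation provenance recorded

    def test_bad_mode_rejected(self):
        spec = ClusteringSpec.from_sigma(0.1)
        with pytest.raises(ValueError):
            pezzoli_design(T7590, spec, 10, mode="guess")


class TestCostOptimal:
    def test_picks_cheapest_geometry(self):
        spec = ClusteringSpec.from_rho(0.1)
        grid = [5, 10, 20]
        best = cost_optimal_design("hedt", T7590, spec, 100.0, 1.0, grid)
        costs = {}
        for m in grid:
            cand = find_cluster_design("hedt", T7590, spec, m)
            costs[m] = cand.k * 100.0 + cand.n * 1.0
        assert best.k * 100.0 + best.n * 1.0 == min(costs.values())

    def test_cluster_cost_pushes_toward_bigger_clusters(self):
        spec = ClusteringSpec.from_rho(0.05)
        cheap_clusters = cost_optimal_design(
            "hedt", T7590, spec, 1.0, 1.0, [5, 10, 15, 20]
        )
        dear_clusters = cost_optimal_design(
            "hedt", T7590, spec, 1000.0, 1.0, [5, 10, 15, 20]
        )
        assert dear_clusters.m >= cheap_clusters.m

    def test_all_infeasible_raises(self):
        spec = ClusteringSpec.from_sigma(0.1)
        with pytest.raises(InfeasibleDesignError):
            cost_optimal_design("hedt", T9095, spec, 1.0, 1.0, [200], k_max=3)
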