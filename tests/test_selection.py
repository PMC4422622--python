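import numpy as np
import pytest

from _oracles import brute_force_loglik
from conftest import make_tree
from mitosel.codonmodel import (CodonParams, OmegaDistribution,
                                equal_codon_freqs, gy94_rate_matrix)
from mitosel.selection import (MODEL_REGISTRY, aic, codon_site_loglik,
                               fit_codon_model, model_scan, omega_summary,
                               positive_proportion, resolve_model,
                               selection_threshold)
from mitosel.simulate import SimulationConfig, simulate_codon_alignment, cetacean_like_tree


class TestAic:
    def test_formula(self):
        assert aic(-100.0, 4) == 208.0

    def test_fewer_parameters_win_on_equal_lnl(self):
        assert aic(-100.0, 4) < aic(-100.0, 5)

    def test_ranking_invariant_to_common_lnl_shift(self):
        delta = aic(-100.0, 4) - aic(-120.0, 6)
        delta_shifted = aic(-93.0, 4) - aic(-113.0, 6)
        assert np.isclose(delta, delta_shifted)


class TestRegistry:
    def test_discrete3_reports_five_parameters(self):
        assert resolve_model("discrete3").n_reported_params == 5

    def test_hyphy_aliases_resolve(self):
        assert resolve_model("MODEL 3 (Discrete)").model_id == "discrete3"
        assert resolve_model("MODEL 8 (Beta & w)").model_id == "beta_w"
        assert resolve_model("MODEL 15 (Beta & 1)").model_id == "beta_1"

    def test_unknown_model_is_an_error(self):
        with pytest.raises(KeyError, match="discrete3"):
            resolve_model("MODEL 99")

    def test_every_model_builds_a_valid_distribution(self):
        for m in MODEL_REGISTRY.values():
            comps = m.components(np.asarray(m.theta_init), K=4)
            w = np.concatenate([c.weights for c in comps])
            assert all(c.omegas.min() >= 0 for c in comps)
            assert len(comps) == m.n_components


class TestSummaries:
    def test_omega_summary_arithmetic(self):
        d = OmegaDistribution([0.1, 1.0, 2.0], [0.5, 0.3, 0.2])
        mean, var = omega_summary(d)
        assert np.isclose(mean, 0.75) and np.isclose(var, 0.5425)

    @pytest.mark.parametrize("omegas,weights,expected", [
        ([0.2, 0.7, 2.2], [0.5, 0.3, 0.2], 2.2),
        ([0.1, 0.5, 0.9], [0.3, 0.3, 0.4], 1.0),
        ([0.5], [1.0], 1.0),
    ])
    def test_selection_threshold_rule(self, omegas, weights, expected):
        assert selection_threshold(OmegaDistribution(omegas, weights)) == expected


class _FakeFit:
    def __init__(self, pos):
        self.positive_posterior = np.asarray(pos)


class TestPositiveProportion:
    def test_counts_sites_above_half(self):
        fit = _FakeFit([0.9, 0.9, 0.1] + [0.0] * 7)
        assert positive_proportion(fit) == 0.2

    def test_exactly_half_does_not_count(self):
        assert positive_proportion(_FakeFit([0.5] * 4)) == 0.0

    def test_masked_sites_excluded(self):
        assert positive_proportion(_FakeFit([np.nan, 0.9])) == 1.0


class TestCodonSiteLoglik:
    def test_matches_exhaustive_enumeration(self, four_taxon_tree,
                                            four_taxon_codon, mito_code):
        """Codon pruning equals brute-force summation over internal states."""
        params = CodonParams(2.5, equal_codon_freqs(mito_code), "F_equal")
        dist = OmegaDistribution([0.2, 1.5], [0.7, 0.3])
        lnL, lcl = codon_site_loglik(four_taxon_tree, four_taxon_codon,
                                     params, dist)
        Qs = [gy94_rate_matrix(params, w, mito_code, normalize="neutral")
              for w in dist.omegas]
        expected = sum(
            brute_force_loglik(four_taxon_tree,
                               dict(zip(four_taxon_codon.taxa, col)),
                               Qs, dist.weights, params.pi)
            for col in four_taxon_codon.codons.T)
        assert np.isclose(lnL, expected, rtol=1e-8)

    def test_mixture_collapse_equals_single_ratio(self, four_taxon_tree,
                                                  four_taxon_codon, mito_code):
        params = CodonParams(2.5, equal_codon_freqs(mito_code), "F_equal")
        collapsed = OmegaDistribution([0.4, 0.4, 0.4], [0.2, 0.3, 0.5])
        single = OmegaDistribution([0.4], [1.0])
        l1, _ = codon_site_loglik(four_taxon_tree, four_taxon_codon, params,
                                  collapsed)
        l2, _ = codon_site_loglik(four_taxon_tree, four_taxon_codon, params,
                                  single)
        assert np.isclose(l1, l2, rtol=1e-12)

    def test_site_permutation_invariance(self, four_taxon_tree,
                                         four_taxon_codon, mito_code):
        params = CodonParams(2.5, equal_codon_freqs(mito_code), "F_equal")
        dist = OmegaDistribution([0.3, 2.0], [0.8, 0.2])
        l1, _ = codon_site_loglik(four_taxon_tree, four_taxon_codon, params,
                                  dist)
        shuffled = four_taxon_codon.subset_sites(np.array([2, 0, 1]))
        l2, _ = codon_site_loglik(four_taxon_tree, shuffled, params, dist)
        assert np.isclose(l1, l2)

    def test_flat_likelihood_posteriors_equal_prior(self, mito_code):
        """Constant columns on a near-zero tree fit every class equally,
        so the NEB posteriors collapse to the prior weights."""
        from conftest import toy_codon_alignment
        tree = make_tree("((A:1e-9,B:1e-9):1e-9,(C:1e-9,D:1e-9):1e-9);")
        aln = toy_codon_alignment(mito_code,
                                  {t: "ATGACCGGA" for t in "ABCD"})
        params = CodonParams(2.0, equal_codon_freqs(mito_code), "F_equal")
        dist = OmegaDistribution([0.2, 1.0, 3.0], [0.5, 0.3, 0.2])
        _, lcl = codon_site_loglik(tree, aln, params, dist)
        post = np.exp(lcl) * dist.weights
        post /= post.sum(axis=1, keepdims=True)
        assert np.allclose(post, dist.weights, atol=1e-6)


@pytest.fixture(scope="module")
def study_tree():
    return cetacean_like_tree(seed=0)[0]


class TestFitCodonModel:
    def test_m0_recovers_generating_omega(self, study_tree):
        """One-ratio fit on 29 taxa x 1000 codons simulated at omega 0.2."""
        cfg = SimulationConfig(tree=study_tree, n_sites=1000, seed=21,
                               omega_dist=OmegaDistribution([0.2], [1.0]))
        aln, _ = simulate_codon_alignment(cfg)
        fit = fit_codon_model(study_tree, aln, "M0", n_starts=1, seed=1)
        omega = fit.omega_distribution.omegas[0]
        assert 0.15 <= omega <= 0.25
        assert np.isclose(fit.site_posteriors[0].sum(), 1.0)

    def test_nested_models_do_not_lose_likelihood(self, study_tree):
        cfg = SimulationConfig(tree=study_tree, n_sites=300, seed=8,
                               omega_dist=OmegaDistribution([0.2, 1.0],
                                                            [0.7, 0.3]))
        aln, _ = simulate_codon_alignment(cfg)
        m0 = fit_codon_model(study_tree, aln, "M0", n_starts=1, seed=1)
        m3 = fit_codon_model(study_tree, aln, "discrete3", n_starts=1, seed=1)
        assert m3.log_likelihood >= m0.log_likelihood - 1e-4

    def test_posterior_rows_sum_to_one(self, study_tree):
        cfg = SimulationConfig(tree=study_tree, n_sites=200, seed=9,
                               omega_dist=OmegaDistribution([0.2, 2.0],
                                                            [0.8, 0.2]))
        aln, _ = simulate_codon_alignment(cfg)
        fit = fit_codon_model(study_tree, aln, "discrete3", n_starts=1, seed=1)
        sums = fit.site_posteriors.sum(axis=1)
        assert np.allclose(sums[np.isfinite(sums)], 1.0)


class TestModelScan:
    def test_single_model_registry(self, study_tree):
        cfg = SimulationConfig(tree=study_tree, n_sites=150, seed=2,
                               omega_dist=OmegaDistribution([0.3], [1.0]))
        aln, _ = simulate_codon_alignment(cfg)
        fits = model_scan(study_tree, aln, registry=["M0"], n_starts=1, seed=1)
        assert len(fits) == 1 and fits[0].model.model_id == "M0"

    def test_positive_selection_data_outranks_one_ratio(self, study_tree):
        dist = OmegaDistribution([0.1, 0.8, 3.0], [0.6, 0.25, 0.15])
        cfg = SimulationConfig(tree=study_tree, n_sites=400, seed=13,
                               omega_dist=dist)
        aln, _ = simulate_codon_alignment(cfg)
        fits = model_scan(study_tree, aln, registry=["M0", "discrete3"],
                          n_starts=1, seed=1)
        assert fits[0].model.model_id == "discrete3"
        assert fits[0].selection_threshold > 1.0
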