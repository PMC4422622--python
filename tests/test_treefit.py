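import numpy as np
import pytest

from _oracles import brute_force_loglik
from conftest import make_tree
from mitosel.alignments import NucAlignment
from mitosel.nucmodel import (NucSubstModel, discrete_gamma_rates,
                              gtr_rate_matrix)
from mitosel.simulate import simulate_nucleotide_alignment
from mitosel.treefit import (_bipartitions, bic_select,
                             bootstrap_support, ml_pairwise_distances,
                             nj_tree, optimize_tree, tree_log_likelihood)


@pytest.fixture
def gamma_model():
    return NucSubstModel(np.array([1.0, 2.0, 1.0, 1.0, 3.0, 1.0]),
                         np.array([0.3, 0.2, 0.25, 0.25]),
                         gamma_shape=0.5, n_rate_categories=3)


class TestTreeLogLikelihood:
    def test_two_sequence_closed_form(self):
        """lnL of one site on a single edge is ln(pi_i * P_ij(t))."""
        tree = make_tree("(A:0.2,B:0.1);")
        aln = NucAlignment.from_sequences(["A", "B"], ["A", "C"])
        model = NucSubstModel.jc()
        Q = gtr_rate_matrix(model)
        from scipy.linalg import expm
        P = expm(Q * 0.3)  # total path length A->B
        expected = np.log(0.25 * P[0, 1])
        assert np.isclose(tree_log_likelihood(tree, aln, model), expected)

    def test_matches_exhaustive_enumeration(self, four_taxon_tree,
                                            four_taxon_nuc, gamma_model):
        lnL = tree_log_likelihood(four_taxon_tree, four_taxon_nuc, gamma_model)
        Q = gtr_rate_matrix(gamma_model)
        rates, weights = discrete_gamma_rates(0.5, 3)
        expected = sum(
            brute_force_loglik(four_taxon_tree,
                               dict(zip(four_taxon_nuc.taxa, col)),
                               [Q * r for r in rates], weights,
                               gamma_model.base_freqs)
            for col in four_taxon_nuc.data.T)
        assert np.isclose(lnL, expected, rtol=1e-10)

    def test_ambiguous_state_marginalizes(self, four_taxon_tree, gamma_model):
        aln = NucAlignment.from_sequences(["A", "B", "C", "D"],
                                          ["AN", "AC", "AG", "AT"])
        lnL = tree_log_likelihood(four_taxon_tree, aln, gamma_model)
        Q = gtr_rate_matrix(gamma_model)
        rates, weights = discrete_gamma_rates(0.5, 3)
        expected = sum(
            brute_force_loglik(four_taxon_tree,
                               dict(zip(aln.taxa, col)),
                               [Q * r for r in rates], weights,
                               gamma_model.base_freqs)
            for col in aln.data.T)
        assert np.isclose(lnL, expected, rtol=1e-10)

    def test_duplicating_columns_doubles_lnl(self, four_taxon_tree,
                                             four_taxon_nuc, gamma_model):
        doubled = NucAlignment(four_taxon_nuc.taxa,
                               np.hstack([four_taxon_nuc.data] * 2))
        assert np.isclose(
            tree_log_likelihood(four_taxon_tree, doubled, gamma_model),
            2 * tree_log_likelihood(four_taxon_tree, four_taxon_nuc,
                                    gamma_model))

    def test_invariant_to_rerooting(self, four_taxon_nuc, gamma_model):
        """Same unrooted metric, different rootings: identical lnL."""
        t1 = make_tree("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07);")
        t2 = make_tree("(A:0.1,B:0.2,(C:0.3,D:0.15):0.12);")
        l1 = tree_log_likelihood(t1, four_taxon_nuc, gamma_model)
        l2 = tree_log_likelihood(t2, four_taxon_nuc, gamma_model)
        assert np.isclose(l1, l2, rtol=1e-10)


class TestNeighborJoining:
    def test_additive_metric_reproduced_exactly(self):
        # additive distances on ((A,B),(C,D)) with internal edge 0.3
        tree = make_tree("((A:0.1,B:0.2):0.3,(C:0.4,D:0.5):0.0);")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(t.label for t in tree.taxon_namespace)
        D = np.zeros((4, 4))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i != j:
                    t1 = tree.taxon_namespace.get_taxon(a)
                    t2 = tree.taxon_namespace.get_taxon(b)
                    D[i, j] = pdm.patristic_distance(t1, t2)
        nj = nj_tree(D, taxa)
        pdm2 = nj.phylogenetic_distance_matrix()
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    d = pdm2.patristic_distance(
                        nj.taxon_namespace.get_taxon(a),
                        nj.taxon_namespace.get_taxon(b))
                    assert np.isclose(d, D[i, j], atol=1e-8)

    def test_two_taxa_degenerate(self):
        tree = nj_tree(np.array([[0.0, 0.4], [0.4, 0.0]]), ["A", "B"])
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"A", "B"}

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["A", "B"])


class TestOptimizeTree:
    def test_recovers_known_topology_and_is_monotone(self):
        truth = make_tree("((A:0.15,B:0.12):0.08,((C:0.1,D:0.18):0.09,"
                          "(E:0.12,F:0.1):0.07):0.05,G:0.2);")
        model = NucSubstModel(np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0]),
                              np.array([0.3, 0.2, 0.2, 0.3]), gamma_shape=0.8)
        aln = simulate_nucleotide_alignment(truth, model, 3000, seed=5)
        start = nj_tree(ml_pairwise_distances(aln), aln.taxa)
        fit = optimize_tree(start, aln, model="GTR+G", do_nni=True)
        assert _bipartitions(fit.tree) == _bipartitions(truth)
        # refit from the optimum barely moves (fixed point)
        fit2 = optimize_tree(fit.tree, aln, model="GTR+G", do_nni=False,
                             max_iterations=3)
        assert fit2.log_likelihood >= fit.log_likelihood - 1e-3


class TestBicSelect:
    def test_formula_and_tie_break(self):
        # BIC = k ln n - 2 lnL computed in-line for a trivial candidate set
        tree = make_tree("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
        aln = NucAlignment.from_sequences(
            ["A", "B", "C", "D"],
            ["ACGTACGTACGTACGTACGT"] * 2 + ["ACGTACGAACGTACGAACGT"] * 2)
        best, table = bic_select(aln, tree, ("JC", "JC+G"))
        by_name = {r[0]: r for r in table}
        for name, lnL, k, bic in table:
            assert np.isclose(bic, k * np.log(aln.n_sites) - 2 * lnL)
        # +G adds a parameter; with near-identical lnL, JC must win
        if np.isclose(by_name["JC"][1], by_name["JC+G"][1], atol=0.5):
            assert best == "JC"

    def test_selects_generating_family_with_strong_signal(self):
        truth = make_tree("((A:0.2,B:0.25):0.08,(C:0.2,D:0.3):0.08,"
                          "(E:0.22,F:0.28):0.06);")
        model = NucSubstModel(np.array([0.3, 6.0, 2.0, 0.2, 9.0, 1.0]),
                              np.array([0.38, 0.3, 0.08, 0.24]),
                              gamma_shape=0.3)
        aln = simulate_nucleotide_alignment(truth, model, 5000, seed=11)
        best, _ = bic_select(aln, truth, ("JC", "HKY", "HKY+G", "GTR", "GTR+G"))
        assert best == "GTR+G"


class TestBootstrap:
    def _setup(self):
        truth = make_tree("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1,E:0.3);")
        model = NucSubstModel.jc().with_(gamma_shape=None)
        aln = simulate_nucleotide_alignment(truth, model, 2000, seed=3)
        start = nj_tree(ml_pairwise_distances(aln), aln.taxa)
        fit = optimize_tree(start, aln, model="JC", do_nni=True,
                            max_iterations=4)
        return fit.tree, aln

    def test_same_seed_is_reproducible_and_b1_is_binary(self):
        tree, aln = self._setup()
        s1 = bootstrap_support(tree, aln, "JC", B=3, seed=42)
        s2 = bootstrap_support(tree, aln, "JC", B=3, seed=42)
        assert s1 == s2
        s3 = bootstrap_support(tree, aln, "JC", B=1, seed=7)
        assert set(s3.values()) <= {0.0, 100.0}

    def test_overwhelming_signal_gives_full_support(self):
        truth = make_tree("((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2,E:0.4);")
        model = NucSubstModel.jc()
        aln = simulate_nucleotide_alignment(truth, model, 20000, seed=9)
        start = nj_tree(ml_pairwise_distances(aln), aln.taxa)
        fit = optimize_tree(start, aln, model="JC", do_nni=True,
                            max_iterations=4)
        support = bootstrap_support(fit.tree, aln, "JC", B=10, seed=1)
        assert all(v == 100.0 for v in support.values())
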