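import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import exhaustive_fitch
from conftest import make_tree, toy_codon_alignment
from mitosel.alignments import HabitatAnnotation
from mitosel.convergence import (RESIDUE_PROPERTIES, annotate_substitution,
                                 codon_site_report, count_min_origins,
                                 fixed_difference_genes, site_group_patterns)
from mitosel.synthetic_cetacea import (SITE297_CODONS, cetacea_habitat,
                                       cetacea_tree, site297_alignment,
                                       site297_states)


class TestResidueChemistry:
    def test_embedded_scale_values(self):
        """Kyte-Doolittle: Ala 1.8, Thr -0.7; all 20 residues present."""
        assert RESIDUE_PROPERTIES["A"][0] == 1.8
        assert RESIDUE_PROPERTIES["T"][0] == -0.7
        assert len(RESIDUE_PROPERTIES) == 20

    def test_thr_to_ala_annotation(self):
        ann = annotate_substitution("T", "A")
        assert ann.hydropathy_from == -0.7 and ann.hydropathy_to == 1.8
        assert np.isclose(ann.hydropathy_delta, 2.5)
        assert ann.polarity_from == "polar" and ann.polarity_to == "non-polar"
        assert ann.weight_to < ann.weight_from
        assert ann.polarity_change

    def test_identity_substitution_is_all_zero(self):
        ann = annotate_substitution("T", "T")
        assert ann.hydropathy_delta == 0.0 and not ann.polarity_change

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            annotate_substitution("T", "Z")


def _two_group_alignment(mito_code, marine, riverine):
    seqs = {f"m{i}": s for i, s in enumerate(marine)}
    seqs.update({f"r{i}": s for i, s in enumerate(riverine)})
    hab = HabitatAnnotation({t: ("marine" if t.startswith("m") else "riverine")
                             for t in seqs})
    return toy_codon_alignment(mito_code, seqs), hab


class TestSiteGroupPatterns:
    def test_fixed_difference_detected(self, mito_code):
        aln, hab = _two_group_alignment(mito_code, ["ACC", "ACC"],
                                        ["GCC", "GCC"])
        (p,) = site_group_patterns(aln, hab)
        assert p.differential and p.fixed

    def test_identical_groups_have_no_flags(self, mito_code):
        aln, hab = _two_group_alignment(mito_code, ["ACC"], ["ACC"])
        (p,) = site_group_patterns(aln, hab)
        assert not p.differential and not p.fixed

    def test_polymorphic_group_is_not_fixed(self, mito_code):
        """One riverine taxon retaining the marine codon breaks fixation."""
        aln, hab = _two_group_alignment(mito_code, ["ACC", "ACC"],
                                        ["GCC", "ACC"])
        (p,) = site_group_patterns(aln, hab)
        assert p.differential and not p.fixed

    def test_ambiguous_codons_do_not_break_fixation(self, mito_code):
        aln, hab = _two_group_alignment(mito_code, ["ACC", "NNN"],
                                        ["GCC", "GCC"])
        (p,) = site_group_patterns(aln, hab)
        assert p.fixed

    @given(st.lists(st.sampled_from(["ACC", "GCC", "GCT", "ATA"]),
                    min_size=2, max_size=4),
           st.lists(st.sampled_from(["ACC", "GCC", "GCT", "ATA"]),
                    min_size=2, max_size=4))
    @settings(max_examples=40, deadline=None)
    def test_fixed_implies_differential(self, marine, riverine):
        from mitosel.codes import load_genetic_code
        code = load_genetic_code("vertebrate_mitochondrial")
        aln, hab = _two_group_alignment(code, marine, riverine)
        (p,) = site_group_patterns(aln, hab)
        if p.fixed:
            assert p.differential

    def test_fixed_difference_genes_filters_and_sorts(self, mito_code):
        fixed_aln, hab = _two_group_alignment(mito_code, ["ACC"], ["GCC"])
        syn_aln, _ = _two_group_alignment(mito_code, ["GCC"], ["GCT"])
        genes = fixed_difference_genes({
            "zeta": site_group_patterns(fixed_aln, hab),
            "alpha": site_group_patterns(syn_aln, hab),
        })
        assert genes == [("zeta", [1])]


class TestCodonSiteReport:
    def test_reproduces_study_codon_table(self):
        """The published site-297 codon/residue rows for the key taxa."""
        aln = site297_alignment()
        rows = {r["taxon"]: r for r in codon_site_report(aln, cetacea_habitat(), 1)}
        assert rows["Sotalia_fluviatilis"]["codon"] == "GCC"
        assert rows["Sotalia_fluviatilis"]["residue"] == "A"
        assert rows["Sotalia_guianensis"]["codon"] == "ACC"
        assert rows["Sotalia_guianensis"]["residue"] == "T"
        assert rows["Inia_geoffrensis"]["codon"] == "GCT"
        assert rows["Inia_geoffrensis"]["residue"] == "A"
        assert rows["Sotalia_fluviatilis"]["habitat"] == "riverine"
        assert rows["Sotalia_guianensis"]["habitat"] == "marine"

    def test_out_of_range_site_is_an_error(self):
        with pytest.raises(ValueError):
            codon_site_report(site297_alignment(), cetacea_habitat(), 2)


class TestCountMinOrigins:
    def test_single_target_tip_is_one_gain(self):
        tree = make_tree("((a:1,b:1):1,((c:1,d:1):1,((e:1,f:1):1,"
                         "(g:1,h:1):1):1):1);")
        states = dict.fromkeys("abcdefgh", "T")
        states["e"] = "A"
        rep = count_min_origins(tree, states, "A", ("fixed", "T"))
        assert rep.min_origins == 1 and rep.fitch_length == 1

    def test_balanced_tree_two_separated_targets(self):
        tree = make_tree("((a:1,b:1):1,(c:1,d:1):1);")
        states = {"a": "A", "b": "T", "c": "A", "d": "T"}
        rep = count_min_origins(tree, states, "A", ("fixed", "T"))
        length, gains = exhaustive_fitch(tree, states, "A", root_state="T")
        assert rep.fitch_length == length == 2
        assert rep.min_origins == gains == 2

    def test_matches_exhaustive_enumeration_on_random_labelings(self):
        tree = make_tree("(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,"
                         "(g:1,h:1):1):1);")
        rng = np.random.default_rng(5)
        for _ in range(25):
            states = {t: rng.choice(["A", "T", "V"]) for t in "abcdefgh"}
            for policy, root in ((("fixed", "T"), "T"), ("unconstrained", None)):
                rep = count_min_origins(tree, states, "A", policy)
                length, gains = exhaustive_fitch(tree, states, "A",
                                                 root_state=root)
                assert rep.fitch_length == length
                assert rep.min_origins == gains

    def test_adding_a_target_tip_never_decreases_origins(self):
        tree = make_tree("(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,"
                         "(g:1,h:1):1):1);")
        base = dict.fromkeys("abcdefgh", "T")
        base.update({"a": "A", "e": "A"})
        rep0 = count_min_origins(tree, base, "A", ("fixed", "T"))
        for extra in "cdgh":
            more = dict(base)
            more[extra] = "A"
            rep1 = count_min_origins(tree, more, "A", ("fixed", "T"))
            assert rep1.min_origins >= rep0.min_origins
            # exact check against the oracle
            length, gains = exhaustive_fitch(tree, more, "A", root_state="T")
            assert rep1.min_origins == gains

    def test_outgroup_policy_uses_tip_state(self):
        tree = make_tree("((a:1,b:1):1,(c:1,d:1):1);")
        states = {"a": "A", "b": "A", "c": "A", "d": "T"}
        rep = count_min_origins(tree, states, "A", ("outgroup", "d"))
        assert rep.min_origins >= 1

    def test_unknown_tip_rejected(self):
        tree = make_tree("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError, match="missing|without"):
            count_min_origins(tree, {"a": "A"}, "A", "unconstrained")


class TestCetaceaWorkedExample:
    def test_alanine_evolved_at_least_four_times(self):
        """Fitch origin count on the cetacean tree with the site-297 states."""
        rep = count_min_origins(cetacea_tree(), site297_states(), "A",
                                ("fixed", "T"))
        assert rep.min_origins >= 4

    def test_residue_counts_match_the_study_tallies(self):
        states = site297_states()
        tallies = {r: sum(1 for s in states.values() if s == r)
                   for r in "TVA"}
        assert tallies == {"T": 22, "V": 2, "A": 7}
        assert len(SITE297_CODONS) == 31
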