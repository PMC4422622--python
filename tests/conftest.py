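import dendropy
import pytest

from mitosel.alignments import CodonAlignment, NucAlignment
from mitosel.codes import load_genetic_code


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


@pytest.fixture(scope="session")
def mito_code():
    return load_genetic_code("vertebrate_mitochondrial")


@pytest.fixture(scope="session")
def standard_code():
    return load_genetic_code("standard")


@pytest.fixture
def four_taxon_tree():
    return make_tree("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07);")


@pytest.fixture
def four_taxon_nuc():
    return NucAlignment.from_sequences(
        ["A", "B", "C", "D"],
        ["ACGTACGTAC", "ACGTACGAAC", "ACTTACGTAC", "GCGTACGTAC"])


def toy_codon_alignment(code, taxa_seqs: dict[str, str],
                        gene: str = "toy") -> CodonAlignment:
    from mitosel.alignments import build_codon_alignment
    taxa = list(taxa_seqs)
    aln = build_codon_alignment(
        NucAlignment.from_sequences(taxa, [taxa_seqs[t] for t in taxa]),
        code, 0)
    aln.gene = gene
    return aln


@pytest.fixture
def four_taxon_codon(mito_code):
    # 3 codon columns, no stops under the mitochondrial code
    return toy_codon_alignment(mito_code, {
        "A": "ATGACCGGA",
        "B": "ATGACAGGA",
        "C": "ATGGCCGGT",
        "D": "ATAACCGGA",
    })
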