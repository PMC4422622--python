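"""Genetic code tables for codon-level analyses.

All selection math in this package runs on the *sense* codons of a named
genetic code.  Mitochondrial protein-coding genes use the vertebrate
mitochondrial code (TGA = Trp, ATA = Met, AGA/AGG = stop; 60 sense codons),
nuclear genes the standard code (61 sense codons).  Tables are taken from
Biopython's NCBI codon tables and frozen into an immutable
:class:`GeneticCode` with a fixed, documented sense-codon order
(lexicographic over A < C < G < T) so that rate-matrix state indices are
stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
#: Placeholder residue for codons containing N or gap characters.
UNKNOWN_RESIDUE = "X"
#: Internal marker for a codon column that cannot be resolved to a sense codon.
AMBIGUOUS = "NNN"

_SUPPORTED = {
    "standard": "Standard",
    "vertebrate_mitochondrial": "Vertebrate Mitochondrial",
}


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table.

    ``codon_to_aa`` maps every triplet over {A,C,G,T} to a one-letter
    residue, with ``"*"`` for stops.  ``sense_codons`` is the stop-free
    subset in lexicographic order; its positions define the state indices
    used by codon rate matrices and alignments.
    """

    name: str
    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...]
    index: dict[str, int] = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == "*"

    def translate(self, codon: str) -> str:
        return translate_codon(codon, self)

    #: residue (one-letter) for each sense codon, aligned with state indices
    def sense_residues(self) -> tuple[str, ...]:
        return tuple(self.codon_to_aa[c] for c in self.sense_codons)


def load_genetic_code(name: str) -> GeneticCode:
    """Return a validated :class:`GeneticCode` by short name.

    Supported names: ``standard`` and ``vertebrate_mitochondrial``.
    """
    if name not in _SUPPORTED:
        raise ValueError(
            f"unknown genetic code {name!r}; supported codes: "
            + ", ".join(sorted(_SUPPORTED))
        )
    return _load(name)


@lru_cache(maxsize=None)
def _load(name: str) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_name[_SUPPORTED[name]]
    codon_to_aa: dict[str, str] = {}
    for codon_tuple in product(NUCLEOTIDES, repeat=3):
        codon = "".join(codon_tuple)
        if codon in table.stop_codons:
            codon_to_aa[codon] = "*"
        else:
            codon_to_aa[codon] = table.forward_table[codon]
    sense = tuple(c for c in sorted(codon_to_aa) if codon_to_aa[c] != "*")
    if len(codon_to_aa) != 64:
        raise AssertionError("genetic code table is not complete")
    return GeneticCode(
        name=name,
        codon_to_aa=codon_to_aa,
        sense_codons=sense,
        index={c: i for i, c in enumerate(sense)},
    )


def translate_codon(codon: str, code: GeneticCode) -> str:
    """Translate a single codon; ambiguous codons give :data:`UNKNOWN_RESIDUE`.

    Raises on stop codons, identifying the offending triplet: in-frame stops
    are data errors upstream, never valid alignment states.
    """
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    if any(ch not in NUCLEOTIDES for ch in codon):
        return UNKNOWN_RESIDUE
    aa = code.codon_to_aa[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} under the {code.name} code")
    return aa
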