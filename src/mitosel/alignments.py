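"""Alignment containers and the surrounding plumbing.

Two in-memory containers are used throughout:

* :class:`NucAlignment` — taxa x nucleotide columns, integer-coded
  (A,C,G,T -> 0..3; anything else, including N and gaps, -> -1).
* :class:`CodonAlignment` — taxa x codon columns, integer-coded by the
  sense-codon index of a :class:`~mitosel.codes.GeneticCode`
  (-1 marks an ambiguous codon: any triplet touching an N or a gap).

A per-column boolean ``mask`` on the codon alignment records which sites are
usable; masked columns are excluded from every likelihood and every site
report.  The masking policies mirror the two ways partially sequenced genes
are commonly handled: drop a column outright when any taxon is ambiguous
(``ignore_site``) or keep it and let ambiguous states contribute a flat
partial likelihood (``ambiguous_ok``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .codes import AMBIGUOUS, NUCLEOTIDES, GeneticCode, load_genetic_code

logger = logging.getLogger(__name__)

_NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

MASK_POLICIES = ("ignore_site", "ambiguous_ok")


def encode_nucleotides(seq: str) -> np.ndarray:
    arr = np.full(len(seq), -1, dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        arr[i] = _NT_INDEX.get(ch, -1)
    return arr


def decode_nucleotides(row: np.ndarray) -> str:
    return "".join(NUCLEOTIDES[i] if i >= 0 else "N" for i in row)


@dataclass
class NucAlignment:
    """Equal-length nucleotide sequences, integer coded."""

    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_sites) int8, -1 = ambiguous

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("data must be (n_taxa, n_sites)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_sequences(cls, taxa: list[str], seqs: list[str]) -> "NucAlignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences differ in length: {sorted(lengths)}")
        return cls(list(taxa), np.stack([encode_nucleotides(s) for s in seqs]))

    @classmethod
    def read_fasta(cls, path) -> "NucAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences([r.id for r in records], [str(r.seq) for r in records])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon, row in zip(self.taxa, self.data):
                fh.write(f">{taxon}\n{decode_nucleotides(row)}\n")

    def sequence(self, taxon: str) -> str:
        return decode_nucleotides(self.data[self.taxa.index(taxon)])


@dataclass
class CodonAlignment:
    """Taxa x codon columns under a named genetic code.

    ``codons[i, j]`` is the sense-codon state index of taxon i at codon
    site j, or -1 when the underlying triplet is ambiguous.  ``mask[j]`` is
    True when site j participates in likelihoods and reports.
    """

    taxa: list[str]
    codons: np.ndarray  # (n_taxa, n_sites) int16
    code: GeneticCode
    gene: str = ""
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=np.int16)
        if self.mask is None:
            self.mask = np.ones(self.codons.shape[1], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codons must be (n_taxa, n_sites)")
        if self.mask.shape != (self.codons.shape[1],):
            raise ValueError("mask length must equal the number of codon sites")
        if self.codons.size and self.codons.max() >= self.code.n_states:
            raise ValueError("codon state index out of range for the genetic code")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    @property
    def n_unmasked(self) -> int:
        return int(self.mask.sum())

    def codon_str(self, taxon: str, site: int) -> str:
        """Codon triplet of ``taxon`` at 0-based ``site`` (``NNN`` if ambiguous)."""
        state = self.codons[self.taxa.index(taxon), site]
        return AMBIGUOUS if state < 0 else self.code.sense_codons[state]

    def residue(self, taxon: str, site: int) -> str:
        state = self.codons[self.taxa.index(taxon), site]
        return "X" if state < 0 else self.code.sense_residues()[state]

    def to_nucleotide(self) -> NucAlignment:
        """Expand codon states back to a nucleotide alignment (ambiguous -> NNN)."""
        seqs = []
        for row in self.codons:
            seqs.append(
                "".join(AMBIGUOUS if s < 0 else self.code.sense_codons[s] for s in row)
            )
        return NucAlignment.from_sequences(list(self.taxa), seqs)

    def write_fasta(self, path) -> None:
        self.to_nucleotide().write_fasta(path)

    @classmethod
    def read_fasta(cls, path, code: GeneticCode | str = "vertebrate_mitochondrial",
                   gene: str = "", frame: int = 0) -> "CodonAlignment":
        if isinstance(code, str):
            code = load_genetic_code(code)
        aln = build_codon_alignment(NucAlignment.read_fasta(path), code, frame)
        return replace(aln, gene=gene or aln.gene)

    def subset_sites(self, sites: np.ndarray) -> "CodonAlignment":
        sites = np.asarray(sites)
        return replace(self, codons=self.codons[:, sites], mask=self.mask[sites])


def build_codon_alignment(
    nucleotide_alignment: NucAlignment,
    code: GeneticCode,
    reading_frame: int = 0,
    gene: str = "",
) -> CodonAlignment:
    """Fold an in-frame nucleotide alignment into codon columns.

    Triplets containing any non-ACGT character become ambiguous (-1); a
    trailing incomplete codon is dropped with a warning (incomplete stop
    codons at mitochondrial CDS 3' ends are normal, not errors).  An
    internal in-frame stop is a hard error naming the taxon and column.
    """
    if reading_frame not in (0, 1, 2):
        raise ValueError("reading frame must be 0, 1 or 2")
    data = nucleotide_alignment.data[:, reading_frame:]
    n_drop = data.shape[1] % 3
    if n_drop:
        logger.warning("dropping %d trailing nucleotide(s) (incomplete codon)", n_drop)
        data = data[:, : data.shape[1] - n_drop]
    n_taxa, n_nt = data.shape
    n_sites = n_nt // 3
    trip = data.reshape(n_taxa, n_sites, 3)
    ambiguous = (trip < 0).any(axis=2)
    # map resolved triplets through the code table
    flat_idx = trip[..., 0] * 16 + trip[..., 1] * 4 + trip[..., 2]
    lookup = np.full(64, -2, dtype=np.int16)  # -2 = stop sentinel
    for codon, aa in code.codon_to_aa.items():
        k = _NT_INDEX[codon[0]] * 16 + _NT_INDEX[codon[1]] * 4 + _NT_INDEX[codon[2]]
        if aa != "*":
            lookup[k] = code.index[codon]
    states = np.where(ambiguous, -1, lookup[np.clip(flat_idx, 0, 63)])
    stops = (states == -2) & ~ambiguous
    if stops.any():
        i, j = np.argwhere(stops)[0]
        codon = "".join(NUCLEOTIDES[b] for b in trip[i, j])
        raise ValueError(
            f"in-frame stop codon {codon} in taxon {nucleotide_alignment.taxa[i]!r} "
            f"at codon column {j + 1} under the {code.name} code"
        )
    return CodonAlignment(
        taxa=list(nucleotide_alignment.taxa),
        codons=states.astype(np.int16),
        code=code,
        gene=gene,
    )


def mask_missing(alignment: CodonAlignment, policy: str = "ignore_site") -> CodonAlignment:
    """Apply a missing-data policy, returning a new alignment.

    ``ignore_site`` masks every column where any taxon is ambiguous;
    ``ambiguous_ok`` keeps columns (ambiguous states are uninformative in the
    likelihood) but still masks columns that are ambiguous in *all* taxa.
    Masking is monotone: existing masked columns stay masked.
    """
    if policy not in MASK_POLICIES:
        raise ValueError(f"policy must be one of {MASK_POLICIES}")
    any_amb = (alignment.codons < 0).any(axis=0)
    all_amb = (alignment.codons < 0).all(axis=0)
    drop = any_amb if policy == "ignore_site" else all_amb
    new_mask = alignment.mask & ~drop
    n_new = int((alignment.mask & drop).sum())
    if n_new:
        logger.info("masked %d column(s) under policy %s", n_new, policy)
    return replace(alignment, mask=new_mask)


@dataclass(frozen=True)
class GeneRecord:
    """One CDS in GenBank-style 1-based inclusive plus-strand coordinates."""

    gene: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def extract_gene(genome_sequence: str, record: GeneRecord) -> str:
    """Slice a CDS out of a genome; minus-strand genes are reverse-complemented."""
    if record.end > len(genome_sequence):
        raise ValueError(
            f"gene {record.gene}: coordinates {record.start}..{record.end} exceed "
            f"sequence length {len(genome_sequence)}"
        )
    sub = genome_sequence[record.start - 1 : record.end]
    return str(Seq(sub).reverse_complement()) if record.strand == "-" else sub


def trim_to_frame(seq: str) -> str:
    """Trim an incomplete 3' codon (mitochondrial CDSs often end in T/TA)."""
    return seq[: len(seq) - len(seq) % 3]


def read_gene_table(path) -> list[GeneRecord]:
    """TSV with columns gene, start, end, strand (header optional)."""
    records = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] in ("", "gene"):
                continue
            records.append(
                GeneRecord(parts[0], int(parts[1]), int(parts[2]),
                           parts[3] if len(parts) > 3 else "+")
            )
    return records


@dataclass(frozen=True)
class HabitatAnnotation:
    """Taxon -> habitat map driving the marine/riverine comparisons."""

    labels: dict[str, str]

    LABELS = ("marine", "riverine")

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - set(self.LABELS)
        if bad:
            raise ValueError(f"unknown habitat label(s): {sorted(bad)}")

    def habitat(self, taxon: str) -> str:
        if taxon not in self.labels:
            raise KeyError(f"taxon {taxon!r} has no habitat label")
        return self.labels[taxon]

    def group(self, label: str) -> list[str]:
        return [t for t, h in self.labels.items() if h == label]

    def check_covers(self, taxa) -> None:
        missing = [t for t in taxa if t not in self.labels]
        if missing:
            raise ValueError(f"taxa without habitat label: {missing}")


def read_habitat_table(path) -> HabitatAnnotation:
    """TSV with columns taxon, habitat (header optional)."""
    labels = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or parts[0] in ("", "taxon"):
                continue
            labels[parts[0]] = parts[1]
    return HabitatAnnotation(labels)


def write_habitat_table(annotation: HabitatAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\thabitat\n")
        for taxon, habitat in annotation.labels.items():
            fh.write(f"{taxon}\t{habitat}\n")


def concatenate_genes(alignments):
    """Concatenate per-gene alignments into a supermatrix + partition map.

    Accepts :class:`NucAlignment` or :class:`CodonAlignment` entries (codon
    alignments are expanded to nucleotides).  Taxa are intersected; taxa
    missing from any gene are dropped and logged.  Returns
    ``(NucAlignment, partitions)`` with ``partitions`` a list of
    ``(gene, start, end)`` in 1-based inclusive nucleotide coordinates.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    nuc = []
    names = []
    for k, aln in enumerate(alignments):
        if isinstance(aln, CodonAlignment):
            names.append(aln.gene or f"gene{k + 1}")
            nuc.append(aln.to_nucleotide())
        else:
            names.append(f"gene{k + 1}")
            nuc.append(aln)
    shared = set(nuc[0].taxa)
    for aln in nuc[1:]:
        shared &= set(aln.taxa)
    if not shared:
        raise ValueError("no taxa shared across all genes")
    dropped = sorted(set().union(*(a.taxa for a in nuc)) - shared)
    if dropped:
        logger.info("dropping taxa absent from some genes: %s", dropped)
    taxa = [t for t in nuc[0].taxa if t in shared]
    blocks, partitions, offset = [], [], 0
    for name, aln in zip(names, nuc):
        rows = np.stack([aln.data[aln.taxa.index(t)] for t in taxa])
        blocks.append(rows)
        partitions.append((name, offset + 1, offset + rows.shape[1]))
        offset += rows.shape[1]
    return NucAlignment(taxa, np.concatenate(blocks, axis=1)), partitions
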