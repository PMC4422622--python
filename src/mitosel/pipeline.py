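"""End-to-end orchestration: tree stage, per-gene selection scan, convergence
report, with deterministic TSV outputs and a provenance record.

The stages mirror the analysis design of mitogenome selection studies: a
concatenated nucleotide ML tree whose topology is frozen for everything
downstream; a per-gene codon site-model scan ranked by AIC, with
empirical-Bayes candidate sites; and, for each candidate, a habitat
breakdown, parsimony origin count and residue-chemistry annotation.

Numbers in the summary table are fixed at two decimals (full precision goes
to a companion file); the decimal separator is always ".".
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .alignments import (CodonAlignment, HabitatAnnotation, concatenate_genes,
                         mask_missing)
from .convergence import (annotate_substitution, codon_site_report,
                          count_min_origins, site_group_patterns)
from .selection import CodonFitResult, model_scan
from .treefit import (TreeFitResult, bootstrap_support, ml_pairwise_distances,
                      nj_tree, optimize_tree)

logger = logging.getLogger(__name__)

#: Table-style summary columns
REPORT_COLUMNS = ("Gene", "Best Model", "Number of parameters", "Global dN/dS",
                  "variance dN/dS", "Proportion of sites with dN/dS>1 (P>0.5)",
                  "dN/dS positive selection threshold", "Notes")


@dataclass
class RunConfig:
    alignments: dict[str, CodonAlignment]
    habitat: HabitatAnnotation
    tree: dendropy.Tree | None = None       # supplied -> tree stage passes through
    registry: tuple[str, ...] = ("M0", "selection", "discrete3", "beta_1")
    masking_policy: str = "ambiguous_ok"
    tree_model: str = "GTR+G"
    tree_nni: bool = True
    bootstrap_replicates: int = 0
    seed: int = 1
    n_starts: int = 2
    missing_note_threshold: float = 0.2     # masked fraction triggering the note
    candidate_threshold: float = 0.5
    ancestral_policy: str = "marine_majority"
    output_dir: Path | None = None

    def record(self) -> dict:
        d = dataclasses.asdict(self)
        d["alignments"] = {g: f"{a.n_taxa} taxa x {a.n_sites} codons"
                           for g, a in self.alignments.items()}
        d["habitat"] = {k: v for k, v in self.habitat.labels.items()}
        d["tree"] = None if self.tree is None else "supplied"
        d["output_dir"] = str(self.output_dir) if self.output_dir else None
        d["version"] = __version__
        return d


@dataclass
class ScanReport:
    rows: list[dict]
    fits: dict[str, CodonFitResult]
    candidates: dict[str, list[tuple[int, float]]]

    def to_frame(self, precision: int | None = 2) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=list(REPORT_COLUMNS))
        if precision is not None:
            for col in REPORT_COLUMNS[3:7]:
                df[col] = df[col].map(lambda v: f"{v:.{precision}f}")
        return df


def run_tree(config: RunConfig) -> TreeFitResult:
    """Concatenate genes, estimate (or pass through) the ML tree, bootstrap."""
    super_aln, partitions = concatenate_genes(list(config.alignments.values()))
    if super_aln.n_taxa < 4:
        raise ValueError("tree stage needs at least 4 taxa")
    if config.tree is not None:
        fit = TreeFitResult(tree=config.tree.clone(depth=1), model=None,
                            log_likelihood=np.nan, model_name="supplied")
    else:
        start = nj_tree(ml_pairwise_distances(super_aln), super_aln.taxa)
        fit = optimize_tree(start, super_aln, model=config.tree_model,
                            do_nni=config.tree_nni)
    if config.bootstrap_replicates > 0 and config.tree is None:
        fit.support = bootstrap_support(fit.tree, super_aln, config.tree_model,
                                        config.bootstrap_replicates,
                                        seed=config.seed,
                                        do_nni=config.tree_nni)
        fit.bootstrap_replicates = config.bootstrap_replicates
        fit.seed = config.seed
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(fit.newick_with_support() + "\n")
        with open(out / "partitions.tsv", "w") as fh:
            fh.write("gene\tstart\tend\n")
            for gene, s, e in partitions:
                fh.write(f"{gene}\t{s}\t{e}\n")
    return fit


def _notes(fit: CodonFitResult, masked_fraction: float,
           threshold: float, candidates) -> str:
    notes = []
    if masked_fraction > threshold:
        notes.append("Large missing data")
    if fit.selection_threshold == 1.0:
        notes.append("No positive selection in the model")
    elif candidates:
        notes.append("Positively selected sites detected")
    notes.extend(fit.notes)
    return "; ".join(notes)


def run_selection_scan(config: RunConfig, tree: dendropy.Tree) -> ScanReport:
    """Per-gene AIC model scan with Table-style summary rows."""
    if not config.alignments:
        raise ValueError("no genes to scan")
    rows, fits, candidates = [], {}, {}
    for gene, aln in config.alignments.items():
        aln = mask_missing(aln, config.masking_policy)
        masked_fraction = 1.0 - aln.n_unmasked / aln.n_sites
        try:
            ranked = model_scan(tree, aln, registry=list(config.registry),
                                n_starts=config.n_starts, seed=config.seed)
        except Exception:
            logger.exception("scan failed for gene %s", gene)
            rows.append(dict(zip(REPORT_COLUMNS,
                                 (gene, "FAILED", 0, np.nan, np.nan, np.nan,
                                  np.nan, "fit failure"))))
            continue
        best = ranked[0]
        fits[gene] = best
        cands = best.candidate_sites(config.candidate_threshold)
        candidates[gene] = cands
        rows.append(dict(zip(REPORT_COLUMNS, (
            gene, best.model.name, best.model.n_reported_params,
            best.global_omega, best.omega_variance, best.positive_proportion,
            best.selection_threshold,
            _notes(best, masked_fraction, config.missing_note_threshold, cands),
        ))))
    report = ScanReport(rows, fits, candidates)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_frame(2).to_csv(out / "report.tsv", sep="\t", index=False)
        report.to_frame(None).to_csv(out / "report_full.tsv", sep="\t",
                                     index=False)
        for gene, fit in fits.items():
            _write_site_table(fit, out / f"sites_{gene}.tsv")
    return report


def _write_site_table(fit: CodonFitResult, path) -> None:
    K = fit.site_posteriors.shape[1]
    cols = {"site": np.arange(1, fit.site_posteriors.shape[0] + 1)}
    for k in range(K):
        cols[f"P(class{k + 1}|site)"] = fit.site_posteriors[:, k]
    cols["P(positive|site)"] = fit.positive_posterior
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class ConvergenceEntry:
    gene: str
    site: int
    posterior: float
    pattern: object
    table: list[dict]
    origin: object
    annotation: object | None


def run_convergence(config: RunConfig, scan_report: ScanReport,
                    tree: dendropy.Tree) -> list[ConvergenceEntry]:
    """Habitat breakdown + origin counts for every candidate site."""
    config.habitat.check_covers(
        next(iter(config.alignments.values())).taxa)
    entries: list[ConvergenceEntry] = []
    for gene, cands in scan_report.candidates.items():
        aln = mask_missing(config.alignments[gene], config.masking_policy)
        patterns = {p.site: p for p in site_group_patterns(aln, config.habitat)}
        for site, posterior in cands:
            if site not in patterns:
                continue
            pattern = patterns[site]
            table = codon_site_report(aln, config.habitat, site)
            riverine = pattern.residues.get("riverine", {})
            marine = pattern.residues.get("marine", {})
            target = max(riverine, key=riverine.get) if riverine else None
            origin = annotation = None
            if target is not None and marine:
                ancestral = max(marine, key=marine.get)
                tip_states = {r["taxon"]: r["residue"] for r in table}
                policy = (("fixed", ancestral)
                          if config.ancestral_policy == "marine_majority"
                          else "unconstrained")
                origin = count_min_origins(tree, tip_states, target, policy)
                if target != ancestral:
                    annotation = annotate_substitution(ancestral, target)
            entries.append(ConvergenceEntry(gene, site, posterior, pattern,
                                            table, origin, annotation))
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for e in entries:
            df = pd.DataFrame(e.table)
            df.to_csv(out / f"convergence_{e.gene}_{e.site}.tsv", sep="\t",
                      index=False)
    return entries


def run_all(config: RunConfig):
    """tree -> scan -> convergence; writes a provenance record at the end."""
    tree_fit = run_tree(config)
    scan = run_selection_scan(config, tree_fit.tree)
    entries = run_convergence(config, scan, tree_fit.tree)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "provenance.json").write_text(
            json.dumps(config.record(), indent=2, default=str) + "\n")
    return tree_fit, scan, entries
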