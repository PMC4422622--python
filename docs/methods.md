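# Methods

`mitosel` implements a three-stage analysis of selective pressure on
mitochondrial protein-coding genes: (i) a maximum-likelihood nucleotide
phylogeny from a concatenated gene supermatrix, whose topology is frozen for
everything downstream; (ii) per-gene codon site-model fits ranked by AIC,
with naive empirical-Bayes (NEB) identification of positively selected
codons; (iii) a habitat-aware convergence analysis that maps fixed
amino-acid differences between marine and riverine taxa, counts independent
origins of a derived residue by parsimony, and annotates substitutions with
residue chemistry.  A codon-evolution simulator generates data with exactly
the structure the inference assumes, so every stage is testable without
external downloads.

## Codon substitution model

The substitution process on the 60 sense codons of the vertebrate
mitochondrial code (61 for the standard code) is Goldman–Yang (GY94) style:
for codons *i → j* differing at exactly one nucleotide,

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

zero for multi-nucleotide changes.  `kappa` is the transition/transversion
rate ratio (bounds 0.01–100, estimated by ML, shared across site classes);
`omega` = dN/dS (bounds 0–50); `pi` the codon equilibrium frequencies.
Frequency schemes: `F3x4` (positional nucleotide counts, the default),
`F_equal`, and `F61` (empirical codon counts); frequencies are plug-in
estimates with a 0.5 pseudocount, not ML parameters.  The process is
time-reversible; transition matrices come from one symmetric
eigendecomposition per omega category.

**Normalization.**  A single rate matrix is conventionally scaled to one
expected substitution per codon (`gy94_rate_matrix(..., normalize="self")`).
Inside site-class mixtures and the simulator, every category's generator is
instead divided by the total rate the same (kappa, pi) process would have at
omega = 1 (`normalize="neutral"`).  Relative rates across classes are then
preserved — a class at omega 3 genuinely evolves faster than one at 0.2 —
which carries a large part of the class signal; per-class self-normalization
would discard it.  A free global branch-length scale absorbs the choice of
constant, so fitted likelihoods are invariant to it but class assignments
are not.

## Site-class models

dN/dS varies across codons according to a finite mixture, literal or
induced by discretizing parametric laws at the conditional means of K
equiprobable slices (K = 8 per continuous component; the discrete model uses
three literal categories).  The registry:

| id              | omega distribution                              | reported params |
|-----------------|--------------------------------------------------|----|
| `M0`            | one ratio                                        | 1  |
| `neutral`       | {0, 1}, free weight                              | 1  |
| `selection`     | {w0 in [0,1], 1, w2 >= 1}, free weights          | 4  |
| `discrete3`     | three free categories, free weights (M3-like)    | 5  |
| `freqs`         | fixed grid {0, 1/3, 2/3, 1, 3}, free weights     | 4  |
| `beta`          | Beta(p, q)                                       | 2  |
| `beta_w`        | Beta(p, q) + point w >= 1, free weight           | 4  |
| `beta_1`        | Beta(p, q) + point 1, free weight                | 3  |
| `beta_gamma1`   | Beta(p, q) + (1 + Gamma(a, b)), free weight      | 5  |
| `gamma_mod_beta`| product Beta(p, q) x Gamma(a, b), 4x4 slices     | 4  |

"Reported params" counts only the omega-distribution side, the convention of
published summary tables; AIC uses the full free-parameter count (kappa +
branch scale + continuous omega parameters + free component weights).  Both
are recorded on every fit.  HyPhy-menu aliases ("MODEL 3 (Discrete)", …)
resolve to these ids; `gamma_mod_beta` is our documented reading of an
ambiguous menu name (the product law), and unmapped names raise.

**Fitting.**  Branch lengths are taken from the supplied tree up to one
global scale factor estimated by ML — the standard protocol when a
nucleotide-stage topology is fixed upstream; under `M0` a full per-branch
optimization is additionally available.  All continuous parameters are
log-transformed (mixture weights via softmax logits) and optimized jointly
with bounded L-BFGS-B; per-category site log-likelihood columns are memoized
by (kappa, scale, omega), so the finite-difference step on one omega only
recomputes that category's pruning pass.  Convergence at delta-lnL below
1e-6.  The multi-start schedule is deterministic-first: (1) registry
defaults with equal weights, (2, 3) "sparse positive" starts putting weight
~0.05 / ~0.0025 on a strong positive class (omega 4 / 8) — a rare selected
component is a narrow likelihood valley that equal-weight starts routinely
miss — then seeded random jitters.  AIC ties break toward fewer parameters.

**Posteriors and summaries.**  NEB: P(class k | site) = p_k L_k / sum_m p_m
L_m at the MLEs; masked sites are NaN.  Summaries follow the conventions of
Table-style gene reports: global dN/dS (mixture mean) and its variance; the
positive-selection threshold (smallest category strictly above 1, or
exactly 1.00 when the model has no positive class); the proportion of sites
whose posterior mass on classes with omega > 1 exceeds 0.5 (strict); and
the prior weight of the positive class.  Candidate sites are those with
positive posterior above 0.5, ranked descending.

**Detector choice.**  For site-level detection experiments the
`selection` model (w2 bounded at >= 1) is the reference detector.  On data
without positive selection the bulk omega MLE of an unconstrained model
scatters around 1 and lands above it half the time, at which point a strict
"omega > 1" class rule would label every site positive; the boundary
constraint makes the no-selection case collapse to threshold 1.00 and zero
positive posteriors.  This mirrors the field's use of explicitly
positive-selection-capable models for site identification, with AIC ranking
across the registry for gene-level conclusions.

## Nucleotide stage

GTR exchangeabilities (order AC, AG, AT, CG, CT; GT fixed at 1) with
empirical base frequencies and Yang-style discrete-gamma rate variation
(K = 4 categories at conditional means, weighted mean 1).  The likelihood is
Felsenstein pruning with per-pattern log scaling and site-pattern
compression; ambiguous bases contribute a flat partial likelihood.  The
search starts from neighbor joining on JC-corrected ML distances and
alternates per-branch Brent optimization (cached up/down edge messages;
Jacobi-style rounds accepted only when the exact lnL improves, keeping the
trace monotone), bounded quasi-Newton updates of exchangeabilities and the
gamma shape, and NNI sweeps accepted only on improvement.  BIC
(k ln n − 2 lnL, ties toward fewer parameters) selects among JC, HKY, GTR,
each with or without gamma.  The nonparametric bootstrap resamples
nucleotide columns of the supermatrix, re-searches each replicate from its
own NJ start, and reports the percentage of replicates containing each
original bipartition.

## Convergence analysis

A site is *differential* when the residue sets of the two habitat groups
differ, and a *fixed difference* when both groups are monomorphic for
different residues; ambiguous codons are dropped from the group multisets
rather than breaking fixation (fixation is about observed states, and
mitogenome Ns concentrate in low-coverage blocks).  Independent origins of
a derived residue are counted by unweighted (Fitch-style) parsimony over
the full residue alphabet observed at the site: a lexicographic dynamic
program minimizes total changes first and, among all most-parsimonious
reconstructions, the number of edges changing from a non-target to the
target state.  The root state can be pinned (`("fixed", state)`), taken
from a designated tip (`("outgroup", taxon)`), or left free; the pipeline
defaults to the majority residue of the marine group, the marine-ancestral
argument.  The residue chemistry table is embedded: Kyte–Doolittle
hydropathy (Ala +1.8, Thr −0.7), average free-amino-acid masses, and a
binary polar/non-polar classification (charged and amide/hydroxyl residues
polar; note Cys is classed polar here, a convention some scales invert).

## Simulator

Sequences evolve site-by-site along the tree by exact per-edge sampling
from the transition matrix (spectral decomposition, cached per branch
length) — not Gillespie jumps.  Per site a class is drawn from the omega
distribution; the root codon from pi.  Defaults emulate mitochondrial
protein-coding data: kappa = 4; codon frequencies from an F3x4-style
product law with A/C-rich, G-poor positional biases; purifying background
mixtures with mean omega below 0.5.  `plant_convergent_site` forces carrier
taxa to one shared synonymous codon of the target residue (convergent
lineages in practice fix the same derived codon or a close synonym);
`inject_missing` overlays contiguous N blocks, emulating low-coverage
regions.  Everything is reproducible from one integer seed.

Two tree-depth regimes are used deliberately.  The parameter-recovery
battery draws branch lengths U(0.02, 0.24) codon substitutions (total tree
length ~7): separating purifying classes at omega 0.2 vs 0.7 needs that
much divergence — at half this depth the two classes are weakly
identifiable and their MLEs visibly biased, which is a property of the
design, not the optimizer (verified by pinned-start polishing).  The
end-to-end study scenario instead scales depth by 0.3 (total ~2, the
shallow divergence of a real cetacean mitogenome set): there, a convergent
site's four-to-five changes rank among the fastest sites, which is exactly
what makes such sites detectable in real data.  The scenario's selected
gene carries a genuine positive class (omega 0.05/0.45/2.0 at weights
0.6/0.3/0.1, i.e. ~10% positive sites) that anchors the detector, and the
planted site's background codon sits one nonsynonymous step from the
carriers' codon — the Thr/Ala configuration.  A single convergent site in
an otherwise purifying gene is often *not* detectable at the MLE (the
sparse positive class collapses); the scenario is built so that the
analysis has the power the design intends to demonstrate.

**What the simulator does not model:** indels and alignment error,
strand-asymmetric mutation, context effects (CpG), synonymous rate
variation, recombination, sequencing error beyond clean N blocks.  Passing
tests therefore demonstrate correctness of the inference machinery under
its own assumptions, not robustness to these violations.

## Numerical choices and degenerate inputs

Float64 throughout; per-pattern, per-category log scaling in the pruning
recursions; likelihood floors at 1e-300 before logs.  Pattern compression
happens once per alignment.  Branch lengths are bounded to [1e-8, 50];
negative NJ branch lengths are clipped to zero.  All-masked alignments,
stop codons in frame, taxa missing habitat labels, and out-of-range
coordinates raise immediately with the offending taxon/column named.
Optimizer failures flag the fit rather than abort a scan; a failed gene row
is marked and the scan continues.  Reports print two decimals (full
precision in a companion file) with "." as the decimal separator.

## Problem sizes

Default experiment sizes are desk-scale on one CPU: 29 taxa x 2000 codons
for recovery fits (~15 s per three-class fit after pattern compression),
500 codons for detection runs, 350 codons x 2–4 genes for pipeline
scenarios, 1000–5000 nt for tree-stage checks with bootstrap replicates in
the tens.  These sizes give the statistical power the corresponding checks
need while keeping the full suite fast.

## Known limitations

NEB rather than BEB: posterior uncertainty in the mixture parameters is
ignored, so posteriors can be overconfident near boundary fits.  F3x4 and
F61 are plug-in frequency estimates and F3x4's product form is only an
approximation of a stop-codon-truncated stationary law, which inflates
omega-hat by a few percent on small neutral datasets.  Branch-site and
branch models, synonymous rate variation, and likelihood-ratio testing are
out of scope; AIC is the only model-ranking criterion.  The Fitch counter
treats all residue changes as unit cost; it reports one gain-minimal
most-parsimonious reconstruction, not all of them.
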