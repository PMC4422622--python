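"""Estimate an ML nucleotide tree with model choice and bootstrap support.

GTR+Gamma maximum likelihood with an NJ start and NNI search; BIC picks
the substitution model; nonparametric bootstrap measures split support.
"""

import dendropy

from mitosel import NucSubstModel, bic_select, bootstrap_support
from mitosel.simulate import simulate_nucleotide_alignment
from mitosel.treefit import ml_pairwise_distances, nj_tree, optimize_tree

truth = dendropy.Tree.get(
    data="((A:0.2,B:0.25):0.08,(C:0.2,D:0.3):0.08,(E:0.22,F:0.28):0.06);",
    schema="newick", preserve_underscores=True)
import numpy as np
model = NucSubstModel(np.array([0.3, 6.0, 2.0, 0.2, 9.0, 1.0]),
                      np.array([0.38, 0.30, 0.08, 0.24]), gamma_shape=0.3)
aln = simulate_nucleotide_alignment(truth, model, 4000, seed=11)

best, table = bic_select(aln, truth, ("JC", "HKY+G", "GTR", "GTR+G"))
print("BIC model choice (smaller is better):")
for name, lnL, k, bic in table:
    print(f"  {name:7s} lnL={lnL:10.2f}  k={k}  BIC={bic:10.2f}")
print(f"selected: {best}")

start = nj_tree(ml_pairwise_distances(aln), aln.taxa)
fit = optimize_tree(start, aln, model=best, do_nni=True)
support = bootstrap_support(fit.tree, aln, best, B=20, seed=3)
print(f"\nML tree lnL = {fit.log_likelihood:.2f}")
print("bootstrap support per internal split (%, 20 replicates):")
for split, pct in support.items():
    print(f"  {sorted(split)}: {pct:.0f}")
print(fit.newick_with_support())
# With 4000 sites of strongly structured data every true split should be
# recovered with support at or near 100%.
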