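"""Fit codon site models to one simulated gene and rank them by AIC.

dN/dS (omega) measures the nonsynonymous/synonymous rate ratio; a model
whose omega distribution includes a class above 1 can flag individual
codons as positively selected via their empirical-Bayes posteriors.
"""


from mitosel import OmegaDistribution, model_scan
from mitosel.simulate import SimulationConfig, cetacean_like_tree, simulate_codon_alignment

tree, _ = cetacean_like_tree(seed=0)
truth = OmegaDistribution([0.1, 0.8, 3.0], [0.6, 0.25, 0.15])
cfg = SimulationConfig(tree=tree, n_sites=400, seed=42, omega_dist=truth)
aln, _ = simulate_codon_alignment(cfg)

fits = model_scan(tree, aln, registry=["M0", "neutral", "selection",
                                       "discrete3"], n_starts=2, seed=1)
print(f"{'model':12s} {'lnL':>12s} {'AIC':>12s} {'mean w':>8s} {'w+':>6s}")
for f in fits:
    print(f"{f.model.model_id:12s} {f.log_likelihood:12.2f} {f.aic:12.2f} "
          f"{f.global_omega:8.3f} {f.selection_threshold:6.2f}")

best = fits[0]
n_flagged = sum(1 for _, p in best.candidate_sites() if p > 0.95)
print(f"\nbest model: {best.model.name}; "
      f"{n_flagged} site(s) with positive-class posterior > 0.95")
# The generating mixture has 15% of sites at omega 3, so site-variable
# models should decisively outrank the one-ratio fit, and 'w+' (the omega
# of the positive-selection class) should land near 3.
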