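"""Maximum-likelihood nucleotide phylogenies: GTR+Gamma fits, BIC model
choice, NNI topology search and nonparametric bootstrap.

The search strategy mirrors desk-scale ML tree programs: a neighbor-joining
start tree on JC-corrected ML pairwise distances, then coordinate ascent
alternating per-branch Brent optimization, bounded quasi-Newton updates of
the substitution parameters, and (optionally) nearest-neighbor-interchange
sweeps accepted only on likelihood improvement.  Base frequencies are the
empirical counts (counted as free parameters in BIC/AIC, as usual).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize

from .alignments import NucAlignment
from .likelihood import (TreeIndex, compress_patterns, mixture_loglik,
                         category_site_logliks, optimize_branch_lengths)
from .nucmodel import (NucSubstModel, empirical_base_freqs, model_eigensystems)

logger = logging.getLogger(__name__)

#: nucleotide model families selectable in bic_select
MODEL_FAMILIES = ("JC", "JC+G", "HKY", "HKY+G", "GTR", "GTR+G")


@dataclass
class TreeFitResult:
    tree: dendropy.Tree
    model: NucSubstModel
    log_likelihood: float
    bic: float | None = None
    support: dict | None = None          # bipartition bitmask -> percent
    bootstrap_replicates: int = 0
    seed: int | None = None
    converged: bool = True
    n_iterations: int = 0
    model_name: str = "GTR+G"

    def newick_with_support(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

def ml_pairwise_distances(alignment: NucAlignment) -> np.ndarray:
    """JC69 maximum-likelihood pairwise distances (closed form)."""
    n = alignment.n_taxa
    D = np.zeros((n, n))
    data = alignment.data
    for i in range(n):
        for j in range(i + 1, n):
            ok = (data[i] >= 0) & (data[j] >= 0)
            m = ok.sum()
            p = (data[i][ok] != data[j][ok]).sum() / m if m else 0.0
            p = min(p, 0.7499)  # keep the JC correction finite
            D[i, j] = D[j, i] = max(-0.75 * np.log(1.0 - 4.0 * p / 3.0), 0.0)
    return D


def nj_tree(distance_matrix: np.ndarray, taxa: list[str]) -> dendropy.Tree:
    """Neighbor-joining tree (scikit-bio backend) as a dendropy tree."""
    D = np.asarray(distance_matrix, float)
    if D.shape[0] != len(taxa) or not np.allclose(D, D.T) or (np.diag(D) != 0).any():
        raise ValueError("need a symmetric zero-diagonal matrix matching taxa")
    if len(taxa) < 3:
        logger.warning("fewer than 3 taxa: returning a degenerate tree")
        if len(taxa) == 2:
            nwk = f"({taxa[0]}:{D[0, 1]:.8f},{taxa[1]}:0.0);"
        else:
            nwk = f"({taxa[0]}:0.0);"
        return dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj
    sk_tree = skbio_nj(SkbioDM(D, ids=taxa))
    tree = dendropy.Tree.get(data=str(sk_tree), schema="newick", preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0  # NJ can emit small negatives
    return tree


# ---------------------------------------------------------------------------
# likelihood plumbing
# ---------------------------------------------------------------------------

def _sync_lengths_to_tree(tree: dendropy.Tree, tidx: TreeIndex) -> None:
    for i, nd in enumerate(tree.postorder_node_iter()):
        if i < tidx.n_nodes - 1:
            nd.edge.length = float(tidx.edge_len[i])


def tree_log_likelihood(tree: dendropy.Tree, alignment: NucAlignment,
                        model: NucSubstModel) -> float:
    """Pruning log-likelihood under the (possibly gamma-mixed) model."""
    tidx = TreeIndex(tree, alignment.taxa)
    patterns, weights, _ = compress_patterns(alignment.data)
    eigs, mix_w = model_eigensystems(model)
    lcl = category_site_logliks(tidx, patterns, eigs)
    return mixture_loglik(lcl, mix_w, weights)


class _Family:
    """Free-parameter packing for one nucleotide model family."""

    def __init__(self, name: str, freqs: np.ndarray):
        if name not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {name!r}")
        self.name = name
        self.base = name.replace("+G", "")
        self.gamma = name.endswith("+G")
        self.freqs = np.full(4, 0.25) if self.base == "JC" else freqs
        self.n_exch = {"JC": 0, "HKY": 1, "GTR": 5}[self.base]

    @property
    def n_free(self) -> int:
        # exchangeabilities + (freqs unless JC) + alpha
        return self.n_exch + (0 if self.base == "JC" else 3) + (1 if self.gamma else 0)

    def init_theta(self) -> np.ndarray:
        return np.zeros(self.n_exch + (1 if self.gamma else 0))

    def build(self, theta: np.ndarray) -> NucSubstModel:
        ex = np.ones(6)
        if self.base == "HKY":
            kappa = np.exp(theta[0])
            ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        elif self.base == "GTR":
            ex[:5] = np.exp(theta[:5])
        alpha = float(np.exp(theta[-1])) if self.gamma else None
        return NucSubstModel(ex, self.freqs, gamma_shape=alpha)


def _optimize_model_params(tidx, patterns, pat_w, family: _Family,
                           theta0: np.ndarray):
    if len(theta0) == 0:
        model = family.build(theta0)
        eigs, mix_w = model_eigensystems(model)
        lnL = mixture_loglik(category_site_logliks(tidx, patterns, eigs),
                             mix_w, pat_w)
        return theta0, model, lnL

    def neg(theta):
        eigs, mix_w = model_eigensystems(family.build(theta))
        return -mixture_loglik(category_site_logliks(tidx, patterns, eigs),
                               mix_w, pat_w)

    bounds = [(-6.0, 6.0)] * len(theta0)
    res = minimize(neg, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200, "ftol": 1e-10})
    model = family.build(res.x)
    return res.x, model, -res.fun


def _nni_neighbors(tree: dendropy.Tree):
    """Yield (v, child, sibling) triples describing possible NNI swaps."""
    for v in tree.preorder_internal_node_iter(exclude_seed_node=True):
        u = v.parent_node
        sibs = [s for s in u.child_nodes() if s is not v]
        kids = v.child_nodes()
        if not sibs or len(kids) < 2:
            continue
        yield v, kids[0], sibs[0]
        yield v, kids[1], sibs[0]


def _apply_nni(v, child, sib) -> None:
    u = v.parent_node
    u.remove_child(sib)
    v.remove_child(child)
    u.add_child(child)
    v.add_child(sib)


def optimize_tree(
    start_tree: dendropy.Tree,
    alignment: NucAlignment,
    model: NucSubstModel | str = "GTR+G",
    do_nni: bool = True,
    max_iterations: int = 10,
    tol: float = 1e-6,
) -> TreeFitResult:
    """Fit branch lengths, substitution parameters and (optionally) topology.

    ``model`` may be a family name from :data:`MODEL_FAMILIES` (parameters
    estimated) or a fixed :class:`NucSubstModel` (only branch lengths and
    topology estimated).  The reported lnL trace is monotone non-decreasing.
    """
    tree = start_tree.clone(depth=1)
    tree.resolve_polytomies(limit=3)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and (
                edge.length is None or edge.length <= 0):
            edge.length = 0.05
    patterns, pat_w, _ = compress_patterns(alignment.data)
    freqs = empirical_base_freqs(alignment.data)

    fixed_model = isinstance(model, NucSubstModel)
    if fixed_model:
        family, theta = None, np.zeros(0)
        current = model
        model_name = "fixed"
    else:
        family = _Family(model, freqs)
        theta = family.init_theta()
        current = family.build(theta)
        model_name = family.name

    lnL = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        tidx = TreeIndex(tree, alignment.taxa)
        eigs, mix_w = model_eigensystems(current)
        _, lnL_b, _ = optimize_branch_lengths(tidx, patterns, pat_w, eigs, mix_w)
        _sync_lengths_to_tree(tree, tidx)
        new_lnL = lnL_b
        if not fixed_model:
            theta, current, new_lnL = _optimize_model_params(
                tidx, patterns, pat_w, family, theta)
        if do_nni:
            new_lnL, tree = _nni_sweep(tree, alignment.taxa, patterns, pat_w,
                                       current, new_lnL)
        if new_lnL < lnL - 1e-9:
            logger.warning("lnL decreased (%.6f -> %.6f); keeping best", lnL, new_lnL)
            break
        if new_lnL - lnL < tol:
            lnL = max(lnL, new_lnL)
            converged = True
            break
        lnL = new_lnL
    if not converged:
        logger.warning("tree optimization hit the iteration cap; best-so-far returned")
    return TreeFitResult(tree=tree, model=current, log_likelihood=lnL,
                         converged=converged, n_iterations=it,
                         model_name=model_name)


def _nni_sweep(tree, taxa, patterns, pat_w, model, lnL):
    eigs, mix_w = model_eigensystems(model)
    improved = True
    while improved:
        improved = False
        # regenerate the neighbor list after any accepted swap: earlier
        # (node, child, sibling) triples go stale once the topology changes
        for v, child, sib in list(_nni_neighbors(tree)):
            _apply_nni(v, child, sib)
            tidx = TreeIndex(tree, taxa)
            _, cand, _ = optimize_branch_lengths(tidx, patterns, pat_w, eigs,
                                                 mix_w, max_rounds=2)
            if cand > lnL + 1e-8:
                _sync_lengths_to_tree(tree, tidx)
                lnL = cand
                improved = True
                break
            _apply_nni(v, sib, child)  # revert
        if improved:
            tidx = TreeIndex(tree, taxa)
            _, lnL, _ = optimize_branch_lengths(tidx, patterns, pat_w, eigs, mix_w)
            _sync_lengths_to_tree(tree, tidx)
    return lnL, tree


def bic_select(alignment: NucAlignment, tree: dendropy.Tree,
               candidate_models=MODEL_FAMILIES):
    """Fit each candidate family on the fixed topology and rank by BIC.

    BIC = k ln(n_sites) - 2 lnL; ties break toward fewer parameters.
    Returns ``(best_name, table)`` with ``table`` rows of
    (name, lnL, k, BIC).
    """
    n = alignment.n_sites
    table = []
    for name in candidate_models:
        fit = optimize_tree(tree, alignment, model=name, do_nni=False,
                            max_iterations=6)
        k = _Family(name, empirical_base_freqs(alignment.data)).n_free
        bic = k * np.log(n) - 2.0 * fit.log_likelihood
        table.append((name, fit.log_likelihood, k, bic))
    table.sort(key=lambda r: (round(r[3], 9), r[2]))
    return table[0][0], table


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial bipartitions as frozensets of tip labels (smaller side)."""
    all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for nd in tree.preorder_internal_node_iter(exclude_seed_node=True):
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if 1 < len(side) < len(all_taxa) - 1:
            other = all_taxa - side
            out.add(side if len(side) <= len(other) else other)
    return out


def bootstrap_support(tree: dendropy.Tree, alignment: NucAlignment,
                      model: NucSubstModel | str, B: int, seed: int,
                      do_nni: bool = True) -> dict[frozenset, float]:
    """Nonparametric bootstrap: column resampling, full re-search per replicate.

    Returns percent support for each nontrivial bipartition of ``tree`` and
    writes the values onto the internal node labels of ``tree``.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    ref = _bipartitions(tree)
    counts = {bp: 0 for bp in ref}
    for _ in range(B):
        cols = rng.integers(0, alignment.n_sites, alignment.n_sites)
        rep = NucAlignment(alignment.taxa, alignment.data[:, cols])
        start = nj_tree(ml_pairwise_distances(rep), rep.taxa)
        fit = optimize_tree(start, rep, model=model, do_nni=do_nni,
                            max_iterations=4)
        rep_bps = _bipartitions(fit.tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    support = {bp: 100.0 * c / B for bp, c in counts.items()}
    for nd in tree.preorder_internal_node_iter(exclude_seed_node=True):
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        key = side if len(side) <= len(all_taxa - side) else all_taxa - side
        if key in support:
            nd.label = f"{support[key]:.0f}"
    return support
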