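"""Felsenstein pruning engine shared by the nucleotide and codon stages.

The engine is model-agnostic: it consumes a tree flattened to postorder
arrays (:class:`TreeIndex`), integer tip states per site pattern, and one
spectral decomposition (:class:`ReversibleEigen`) per mixture category.
Because every substitution process used here is time-reversible
(off-diagonal rates ``q_ij = r_ij * pi_j`` with symmetric ``r``), transition
matrices come from a single symmetric eigendecomposition per category:
``P(t) = D^{-1/2} U exp(L t) U' D^{1/2}`` with ``D = diag(pi)``.

Ambiguous tip states (-1) contribute a flat partial likelihood of one for
every state.  Per-pattern log scaling keeps partial likelihoods in range on
deep trees.  Site patterns are compressed before any likelihood work.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

MIN_BRANCH = 1e-8
MAX_BRANCH = 50.0


@dataclass(frozen=True)
class ReversibleEigen:
    """Spectral decomposition of a reversible generator, P(t) = U exp(L t) V."""

    U: np.ndarray       # (S, S)
    V: np.ndarray       # (S, S), V = U^{-1}
    eigvals: np.ndarray  # (S,), all <= 0 up to rounding
    pi: np.ndarray      # (S,) stationary distribution

    @classmethod
    def from_rates(cls, Q: np.ndarray, pi: np.ndarray) -> "ReversibleEigen":
        d = np.sqrt(pi)
        A = (Q * d[:, None]) / d[None, :]
        A = 0.5 * (A + A.T)  # enforce symmetry against rounding
        w, S = np.linalg.eigh(A)
        return cls(U=S / d[:, None], V=S.T * d[None, :], eigvals=w, pi=pi)

    def transition(self, t: float) -> np.ndarray:
        """P(t) for a single branch length (rows sum to 1)."""
        P = (self.U * np.exp(self.eigvals * t)) @ self.V
        return np.clip(P, 0.0, None)

    def transition_batch(self, ts: np.ndarray) -> np.ndarray:
        """P(t) for every branch length in ``ts`` -> (len(ts), S, S)."""
        E = np.exp(np.outer(ts, self.eigvals))  # (B, S)
        P = (self.U[None, :, :] * E[:, None, :]) @ self.V
        return np.clip(P, 0.0, None)


class TreeIndex:
    """A dendropy tree flattened to postorder arrays over a fixed taxon list.

    Node 0..n-1 in postorder (root last).  ``edge_len[i]`` is the length of
    the edge above node i (0 for the root); ``children[i]`` the child node
    ids; ``leaf_taxon[i]`` the index into ``taxa`` for leaves, -1 otherwise.
    Multifurcations (including an unrooted trifurcating root) are handled.
    """

    def __init__(self, tree: dendropy.Tree, taxa: list[str]):
        taxon_pos = {t: i for i, t in enumerate(taxa)}
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self._node_id = {id(nd): i for i, nd in enumerate(nodes)}
        self.children: list[list[int]] = []
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.edge_len = np.zeros(self.n_nodes)
        self.leaf_taxon = np.full(self.n_nodes, -1, dtype=int)
        seen = set()
        for i, nd in enumerate(nodes):
            kids = [self._node_id[id(c)] for c in nd.child_nodes()]
            self.children.append(kids)
            for k in kids:
                self.parent[k] = i
            if nd.edge.length is not None:
                self.edge_len[i] = max(float(nd.edge.length), 0.0)
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon else None
                if label not in taxon_pos:
                    raise ValueError(f"tree tip {label!r} not among alignment taxa")
                if label in seen:
                    raise ValueError(f"duplicate tree tip {label!r}")
                seen.add(label)
                self.leaf_taxon[i] = taxon_pos[label]
        missing = set(taxa) - seen
        if missing:
            raise ValueError(f"taxa absent from tree: {sorted(missing)}")
        self.root = self.n_nodes - 1
        self.postorder = [i for i in range(self.n_nodes) if self.children[i]]
        self.taxa = list(taxa)

    def copy_lengths(self) -> np.ndarray:
        return self.edge_len.copy()


def compress_patterns(states: np.ndarray, mask: np.ndarray | None = None):
    """Collapse identical site columns.

    Returns ``(patterns, weights, site_to_pattern)`` where ``patterns`` is
    (n_taxa, n_patterns), ``weights`` the column multiplicities and
    ``site_to_pattern`` maps each *unmasked* site (in original order) to its
    pattern index; masked sites map to -1.
    """
    n_sites = states.shape[1]
    if mask is None:
        mask = np.ones(n_sites, dtype=bool)
    cols = states[:, mask]
    if cols.shape[1] == 0:
        raise ValueError("all columns are masked")
    patterns, inverse, counts = np.unique(
        cols, axis=1, return_inverse=True, return_counts=True
    )
    site_to_pattern = np.full(n_sites, -1, dtype=int)
    site_to_pattern[np.flatnonzero(mask)] = inverse
    return patterns, counts.astype(float), site_to_pattern


def _tip_message(P: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Message from a leaf child: (K, n_pat, S); ambiguous -> ones."""
    # P: (K, S, S); states: (n_pat,)
    msg = P[:, :, np.clip(states, 0, None)].transpose(0, 2, 1).copy()
    if (states < 0).any():
        msg[:, states < 0, :] = 1.0
    return msg


def _build_P(eigs, lengths: np.ndarray) -> np.ndarray:
    """(K, n_nodes, S, S) transition matrices for the edge above each node."""
    return np.stack([e.transition_batch(lengths) for e in eigs])


def category_site_logliks(
    tidx: TreeIndex,
    patterns: np.ndarray,
    eigs: list[ReversibleEigen],
    lengths: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pattern, per-category log-likelihoods -> (n_patterns, K)."""
    K = len(eigs)
    lengths = tidx.edge_len if lengths is None else lengths
    P = _build_P(eigs, lengths)
    part, logscale = _postorder_partials(tidx, patterns, P, store=False)
    pi = eigs[0].pi
    lik = np.einsum("kps,s->kp", part, pi)
    return (np.log(np.clip(lik, 1e-300, None)) + logscale).T  # (n_pat, K)


def mixture_loglik(site_cat_logliks: np.ndarray, weights: np.ndarray,
                   pattern_weights: np.ndarray) -> float:
    """Total lnL of a mixture: sum_pat w_pat * log sum_k p_k L_pat,k."""
    lse = logsumexp(site_cat_logliks + np.log(weights)[None, :], axis=1)
    return float(np.dot(pattern_weights, lse))


def _postorder_partials(tidx, patterns, P, store=True):
    """Postorder partial likelihoods.

    Returns root ``(part, logscale)``; when ``store`` is True also keeps
    every internal node's arrays (needed for the branch-length machinery),
    returned as dicts.
    """
    K = P.shape[0]
    n_pat = patterns.shape[1]
    S = P.shape[2]
    parts: dict[int, np.ndarray] = {}
    scales: dict[int, np.ndarray] = {}
    for node in tidx.postorder:
        part = np.ones((K, n_pat, S))
        scale = np.zeros((K, n_pat))
        for child in tidx.children[node]:
            tax = tidx.leaf_taxon[child]
            if tax >= 0:
                part *= _tip_message(P[:, child], patterns[tax])
            else:
                part *= parts[child] @ P[:, child].transpose(0, 2, 1)
                scale += scales[child]
                if not store:
                    del parts[child], scales[child]
        m = part.max(axis=2)
        m[m == 0.0] = 1.0
        part /= m[:, :, None]
        scale += np.log(m)
        parts[node] = part
        scales[node] = scale
    root = tidx.root
    if store:
        return parts, scales
    return parts[root], scales[root]


def tree_mixture_loglik(tidx, patterns, pattern_weights, eigs, weights,
                        lengths=None) -> float:
    lcl = category_site_logliks(tidx, patterns, eigs, lengths)
    return mixture_loglik(lcl, np.asarray(weights, float), pattern_weights)


# ---------------------------------------------------------------------------
# Branch-length optimization on cached edge messages
# ---------------------------------------------------------------------------

def _edge_vectors(tidx, patterns, P, eigs):
    """Up/down vectors for every non-root node's edge.

    For edge (parent u, child v): ``down[v]`` is the partial likelihood of
    the subtree below v (states of v), ``up[v]`` the likelihood of the rest
    of the tree including the root prior (states of u), so that
    lnL = log sum_ij up[v]_i P_v(t)_ij down[v]_j  (plus scales).
    """
    K, _, n_pat, S = P.shape[0], None, patterns.shape[1], P.shape[2]
    parts, scales = _postorder_partials(tidx, patterns, P, store=True)
    pi = eigs[0].pi
    down, down_scale, msg, msg_scale = {}, {}, {}, {}
    for v in range(tidx.n_nodes - 1):  # all non-root nodes
        tax = tidx.leaf_taxon[v]
        if tax >= 0:
            onehot = np.zeros((n_pat, S))
            amb = patterns[tax] < 0
            onehot[np.arange(n_pat), np.clip(patterns[tax], 0, None)] = 1.0
            onehot[amb] = 1.0
            down[v] = np.broadcast_to(onehot, (K, n_pat, S)).copy()
            down_scale[v] = np.zeros((K, n_pat))
        else:
            down[v] = parts[v]
            down_scale[v] = scales[v]
        msg[v] = down[v] @ P[:, v].transpose(0, 2, 1)
        msg_scale[v] = down_scale[v]
    up, up_scale = {}, {}
    order = [n for n in range(tidx.n_nodes - 1)]
    # preorder: parents before children
    for v in sorted(order, key=lambda n: -n):
        u = tidx.parent[v]
        sib_prod = np.ones((K, n_pat, S))
        sib_scale = np.zeros((K, n_pat))
        for s in tidx.children[u]:
            if s != v:
                sib_prod = sib_prod * msg[s]
                sib_scale += msg_scale[s]
        if u == tidx.root:
            base = pi[None, None, :] * sib_prod
            base_scale = sib_scale
        else:
            upmsg = up[u] @ P[:, u]
            base = upmsg * sib_prod
            base_scale = up_scale[u] + sib_scale
        m = base.max(axis=2)
        m[m == 0.0] = 1.0
        up[v] = base / m[:, :, None]
        up_scale[v] = base_scale + np.log(m)
    return down, down_scale, up, up_scale


def optimize_branch_lengths(
    tidx: TreeIndex,
    patterns: np.ndarray,
    pattern_weights: np.ndarray,
    eigs: list[ReversibleEigen],
    mix_weights: np.ndarray,
    max_rounds: int = 8,
    tol: float = 1e-6,
):
    """Optimize all branch lengths by rounds of per-edge Brent searches.

    Each round caches up/down vectors once and optimizes every edge against
    those (Jacobi-style); a round is accepted only if the exact lnL improves,
    so the reported lnL sequence is monotone non-decreasing.  Returns
    ``(lengths, lnL, n_rounds)`` and leaves ``tidx.edge_len`` updated.
    """
    mix_weights = np.asarray(mix_weights, float)
    lengths = tidx.copy_lengths()
    lnL = tree_mixture_loglik(tidx, patterns, pattern_weights, eigs,
                              mix_weights, lengths)
    for rnd in range(max_rounds):
        P = _build_P(eigs, lengths)
        down, down_scale, up, up_scale = _edge_vectors(tidx, patterns, P, eigs)
        new_lengths = lengths.copy()
        logw = np.log(mix_weights)
        for v in range(tidx.n_nodes - 1):
            uvec, dvec = up[v], down[v]
            const_scale = up_scale[v] + down_scale[v]

            def edge_neg_lnL(t, uvec=uvec, dvec=dvec, const_scale=const_scale):
                tot = np.empty((len(eigs), uvec.shape[1]))
                for k, e in enumerate(eigs):
                    Pk = e.transition(t)
                    tot[k] = np.einsum("ps,ps->p", uvec[k] @ Pk, dvec[k])
                ll = np.log(np.clip(tot, 1e-300, None)) + const_scale
                return -float(np.dot(pattern_weights,
                                     logsumexp(ll + logw[:, None], axis=0)))

            res = minimize_scalar(edge_neg_lnL, bounds=(MIN_BRANCH, MAX_BRANCH),
                                  method="bounded",
                                  options={"xatol": 1e-7})
            new_lengths[v] = res.x
        new_lnL = tree_mixture_loglik(tidx, patterns, pattern_weights, eigs,
                                      mix_weights, new_lengths)
        if new_lnL > lnL + tol:
            lengths, lnL = new_lengths, new_lnL
        else:
            if new_lnL > lnL:
                lengths, lnL = new_lengths, new_lnL
            break
    tidx.edge_len = lengths
    return lengths, lnL, rnd + 1
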