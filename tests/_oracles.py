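"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive: likelihoods by exhaustive summation
over internal-node state assignments (scipy expm for transition matrices),
parsimony by exhaustive enumeration of internal labelings.  None of it
shares code with the pruning/DP implementations it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.linalg import expm


def _collect(tree):
    """Rooted structure: lists of (node, parent, edge_length), postorder."""
    nodes = list(tree.postorder_node_iter())
    ids = {id(n): i for i, n in enumerate(nodes)}
    edges = []
    for n in nodes:
        if n.parent_node is not None:
            edges.append((ids[id(n)], ids[id(n.parent_node)],
                          float(n.edge.length or 0.0)))
    leaves = {ids[id(n)]: n.taxon.label for n in nodes if n.is_leaf()}
    internals = [ids[id(n)] for n in nodes if not n.is_leaf()]
    return len(nodes), edges, leaves, internals


def brute_force_loglik(tree, tip_states: dict[str, int], Qs, weights,
                       pi) -> float:
    """ln sum_k w_k L_k for ONE site by enumeration over internal states.

    ``Qs`` is one generator per mixture category; ``tip_states`` maps taxon
    label to a state index (-1 = ambiguous, any state allowed).
    """
    n_nodes, edges, leaves, internals = _collect(tree)
    S = Qs[0].shape[0]
    root = n_nodes - 1
    amb = [i for i, label in leaves.items() if tip_states[label] < 0]
    free = internals + amb  # nodes to enumerate over
    total = 0.0
    for Q, w in zip(Qs, weights):
        P = {(c, p): expm(Q * t) for c, p, t in edges}
        like = 0.0
        for assign in product(range(S), repeat=len(free)):
            state = dict(zip(free, assign))
            for i, label in leaves.items():
                if tip_states[label] >= 0:
                    state[i] = tip_states[label]
            term = pi[state[root]]
            for c, p, t in edges:
                term *= P[(c, p)][state[p], state[c]]
            like += term
        total += w * like
    return float(np.log(total))


def brute_force_site_likelihood(tree, tip_states, Q, pi) -> float:
    """Single-category site likelihood by enumeration (no mixture)."""
    n_nodes, edges, leaves, internals = _collect(tree)
    S = Q.shape[0]
    root = n_nodes - 1
    P = {(c, p): expm(Q * t) for c, p, t in edges}
    like = 0.0
    for assign in product(range(S), repeat=len(internals)):
        state = dict(zip(internals, assign))
        ok = True
        for i, label in leaves.items():
            if tip_states[label] < 0:
                ok = False
            state[i] = tip_states[label]
        if not ok:
            raise NotImplementedError("ambiguous tips not supported here")
        term = pi[state[root]]
        for c, p, t in edges:
            term *= P[(c, p)][state[p], state[c]]
        like += term
    return like


def exhaustive_fitch(tree, tip_states: dict[str, str], target: str,
                     root_state: str | None = None):
    """(min changes, min gains among minimum-change labelings) by brute force."""
    n_nodes, edges, leaves, internals = _collect(tree)
    states = sorted(set(tip_states.values()) | {target}
                    | ({root_state} if root_state else set()))
    root = n_nodes - 1
    best = (10 ** 9, 10 ** 9)
    for assign in product(states, repeat=len(internals)):
        lab = dict(zip(internals, assign))
        for i, label in leaves.items():
            lab[i] = tip_states[label]
        if root_state is not None and lab[root] != root_state:
            continue
        changes = sum(1 for c, p, _ in edges if lab[c] != lab[p])
        gains = sum(1 for c, p, _ in edges
                    if lab[c] == target and lab[p] != target)
        best = min(best, (changes, gains))
    return best
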