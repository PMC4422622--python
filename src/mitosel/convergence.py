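"""Habitat-aware convergence analysis of amino-acid sites.

Given a codon alignment and marine/riverine labels this module (i) tabulates
per-site residue and codon states by habitat group, flagging *differential*
sites (group residue sets differ) and *fixed* differences (each group
monomorphic, for different residues; ambiguous codons are excluded from the
group multisets rather than breaking fixation), (ii) counts the minimum
number of independent gains of a derived residue on a tree by Fitch
(unweighted) parsimony — among all most-parsimonious reconstructions the one
with the fewest non-target -> target changes — and (iii) annotates
substitutions with residue chemistry (Kyte–Doolittle hydropathy, average
residue mass, binary polarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignments import CodonAlignment, HabitatAnnotation
from .codes import AMBIGUOUS

# Kyte & Doolittle hydropathy index (kcal/mol-style), average molecular
# weight of the free amino acid (Da), binary polarity class.
RESIDUE_PROPERTIES: dict[str, tuple[float, float, str]] = {
    "A": (1.8, 89.09, "non-polar"),
    "R": (-4.5, 174.20, "polar"),
    "N": (-3.5, 132.12, "polar"),
    "D": (-3.5, 133.10, "polar"),
    "C": (2.5, 121.16, "polar"),
    "Q": (-3.5, 146.15, "polar"),
    "E": (-3.5, 147.13, "polar"),
    "G": (-0.4, 75.07, "non-polar"),
    "H": (-3.2, 155.15, "polar"),
    "I": (4.5, 131.17, "non-polar"),
    "L": (3.8, 131.17, "non-polar"),
    "K": (-3.9, 146.19, "polar"),
    "M": (1.9, 149.21, "non-polar"),
    "F": (2.8, 165.19, "non-polar"),
    "P": (-1.6, 115.13, "non-polar"),
    "S": (-0.8, 105.09, "polar"),
    "T": (-0.7, 119.12, "polar"),
    "W": (-0.9, 204.23, "non-polar"),
    "Y": (-1.3, 181.19, "polar"),
    "V": (4.2, 117.15, "non-polar"),
}


def hydropathy(residue: str) -> float:
    return _props(residue)[0]


def _props(residue: str) -> tuple[float, float, str]:
    if residue not in RESIDUE_PROPERTIES:
        raise KeyError(f"unknown residue {residue!r}")
    return RESIDUE_PROPERTIES[residue]


@dataclass(frozen=True)
class SubstitutionAnnotation:
    from_residue: str
    to_residue: str
    hydropathy_from: float
    hydropathy_to: float
    hydropathy_delta: float
    polarity_from: str
    polarity_to: str
    weight_from: float
    weight_to: float

    @property
    def polarity_change(self) -> bool:
        return self.polarity_from != self.polarity_to


def annotate_substitution(from_residue: str, to_residue: str,
                          table=None) -> SubstitutionAnnotation:
    """Chemistry delta of a residue substitution (e.g. Thr -> Ala)."""
    table = RESIDUE_PROPERTIES if table is None else table
    for r in (from_residue, to_residue):
        if r not in table:
            raise KeyError(f"unknown residue {r!r}")
    h1, w1, p1 = table[from_residue]
    h2, w2, p2 = table[to_residue]
    return SubstitutionAnnotation(from_residue, to_residue, h1, h2, h2 - h1,
                                  p1, p2, w1, w2)


# ---------------------------------------------------------------------------
# group patterns
# ---------------------------------------------------------------------------

@dataclass
class SiteGroupPattern:
    """Residue/codon states of one codon site split by habitat group."""

    site: int                                   # 1-based codon position
    residues: dict[str, dict[str, int]]         # group -> residue -> count
    codons: dict[str, dict[str, int]]           # group -> codon -> count
    differential: bool
    fixed: bool


def site_group_patterns(codon_alignment: CodonAlignment,
                        habitat_annotation: HabitatAnnotation
                        ) -> list[SiteGroupPattern]:
    """One pattern per unmasked site; ambiguous codons are left out of the
    group multisets.  ``fixed`` requires both groups non-empty, monomorphic
    and for different residues (so fixed implies differential)."""
    habitat_annotation.check_covers(codon_alignment.taxa)
    groups = {label: [t for t in codon_alignment.taxa
                      if habitat_annotation.habitat(t) == label]
              for label in HabitatAnnotation.LABELS}
    residues = codon_alignment.code.sense_residues()
    codons = codon_alignment.code.sense_codons
    taxon_row = {t: i for i, t in enumerate(codon_alignment.taxa)}
    out = []
    for j in range(codon_alignment.n_sites):
        if not codon_alignment.mask[j]:
            continue
        res_by, cod_by = {}, {}
        for label, members in groups.items():
            rc: dict[str, int] = {}
            cc: dict[str, int] = {}
            for t in members:
                s = codon_alignment.codons[taxon_row[t], j]
                if s < 0:
                    continue
                rc[residues[s]] = rc.get(residues[s], 0) + 1
                cc[codons[s]] = cc.get(codons[s], 0) + 1
            res_by[label] = rc
            cod_by[label] = cc
        sets = [set(res_by[lab]) for lab in HabitatAnnotation.LABELS]
        differential = sets[0] != sets[1]
        fixed = (all(len(s) == 1 for s in sets) and sets[0].isdisjoint(sets[1]))
        out.append(SiteGroupPattern(j + 1, res_by, cod_by, differential, fixed))
    return out


def fixed_difference_genes(per_gene_patterns: dict[str, list[SiteGroupPattern]]
                           ) -> list[tuple[str, list[int]]]:
    """Genes carrying at least one fixed differential site, sorted by name."""
    out = []
    for gene in sorted(per_gene_patterns):
        sites = [p.site for p in per_gene_patterns[gene] if p.fixed]
        if sites:
            out.append((gene, sites))
    return out


def codon_site_report(codon_alignment: CodonAlignment,
                      habitat_annotation: HabitatAnnotation,
                      site: int) -> list[dict]:
    """Per-taxon table (taxon, habitat, codon, residue) at a 1-based site."""
    if not 1 <= site <= codon_alignment.n_sites:
        raise ValueError(f"site {site} out of range 1..{codon_alignment.n_sites}")
    j = site - 1
    if not codon_alignment.mask[j]:
        raise ValueError(f"site {site} is masked")
    rows = []
    for t in codon_alignment.taxa:
        codon = codon_alignment.codon_str(t, j)
        rows.append({
            "taxon": t,
            "habitat": habitat_annotation.habitat(t),
            "codon": codon,
            "residue": codon_alignment.residue(t, j) if codon != AMBIGUOUS else "X",
        })
    return rows


# ---------------------------------------------------------------------------
# Fitch parsimony origin counting
# ---------------------------------------------------------------------------

@dataclass
class OriginReport:
    target_residue: str
    fitch_length: int        # minimum total changes
    min_origins: int         # minimum non-target -> target gains among MP trees
    gain_edges: list[tuple[str, ...]] = field(default_factory=list)
    # each entry: tip labels below the edge where a gain is placed (one MP pick)


def count_min_origins(tree: dendropy.Tree, tip_states: dict[str, str],
                      target_residue: str,
                      ancestral_policy: str | tuple = "unconstrained"
                      ) -> OriginReport:
    """Minimum independent gains of ``target_residue`` under Fitch parsimony.

    ``ancestral_policy`` is ``"unconstrained"``, ``("fixed", state)`` or
    ``("outgroup", taxon)`` (root state pinned to that tip's state).  The
    count is the fewest edges with a non-target parent and target child over
    all reconstructions attaining the parsimony minimum (lexicographic DP:
    changes first, gains second).
    """
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = set(tip_states) - leaves
    if unknown:
        raise ValueError(f"tip(s) not in tree: {sorted(unknown)}")
    missing = leaves - set(tip_states)
    if missing:
        raise ValueError(f"tip(s) without state: {sorted(missing)}")
    extra = set()
    if ancestral_policy != "unconstrained":
        kind, value = ancestral_policy
        if kind == "fixed":
            extra.add(value)
        elif kind == "outgroup":
            if value not in tip_states:
                raise ValueError(f"outgroup taxon {value!r} has no state")
            extra.add(tip_states[value])
        else:
            raise ValueError(f"unknown ancestral policy {ancestral_policy!r}")
    states = sorted(set(tip_states.values()) | {target_residue} | extra)
    idx = {s: i for i, s in enumerate(states)}
    S = len(states)
    t_i = idx[target_residue]
    BIG = 10 ** 6

    cost: dict[int, np.ndarray] = {}
    gains: dict[int, np.ndarray] = {}
    choice: dict[int, list] = {}
    nodes = list(tree.postorder_node_iter())
    node_id = {id(n): i for i, n in enumerate(nodes)}
    for n in nodes:
        i = node_id[id(n)]
        if n.is_leaf():
            c = np.full(S, BIG)
            c[idx[tip_states[n.taxon.label]]] = 0
            cost[i] = c
            gains[i] = np.zeros(S, dtype=int)
            choice[i] = []
            continue
        c = np.zeros(S, dtype=int)
        g = np.zeros(S, dtype=int)
        picks = []
        for child in n.child_nodes():
            ci = node_id[id(child)]
            # edge (state s at n) -> (state s' at child)
            edge_cost = cost[ci][None, :] + (1 - np.eye(S, dtype=int))
            edge_gain = gains[ci][None, :] + (
                (np.arange(S)[:, None] != t_i) & (np.arange(S)[None, :] == t_i)
            ).astype(int)
            # lexicographic (cost, gains) minimum per parent state
            combined = edge_cost * (BIG // 2) + edge_gain
            best = combined.argmin(axis=1)
            c += edge_cost[np.arange(S), best]
            g += edge_gain[np.arange(S), best]
            picks.append((ci, best))
        cost[i] = c
        gains[i] = g
        choice[i] = picks

    root = node_id[id(tree.seed_node)]
    if ancestral_policy == "unconstrained":
        allowed = np.arange(S)
    else:
        root_state = next(iter(extra))
        allowed = np.array([idx[root_state]])
    combined = cost[root][allowed] * (BIG // 2) + gains[root][allowed]
    pick = allowed[combined.argmin()]
    length = int(cost[root][pick])
    n_gains = int(gains[root][pick])

    # backtrack one most-parsimonious, gain-minimal reconstruction
    gain_edges = []
    stack = [(root, pick)]
    tips_below = {}
    for n in nodes:
        i = node_id[id(n)]
        tips_below[i] = (tuple(sorted(l.taxon.label for l in n.leaf_iter()))
                         if not n.is_leaf() else (n.taxon.label,))
    while stack:
        i, s = stack.pop()
        for ci, best in choice.get(i, []):
            s_child = int(best[s])
            if s != t_i and s_child == t_i:
                gain_edges.append(tips_below[ci])
            stack.append((ci, s_child))
    return OriginReport(target_residue, length, n_gains, gain_edges)
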