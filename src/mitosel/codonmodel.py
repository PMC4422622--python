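"""Goldman–Yang codon substitution processes and site-class ω distributions.

The GY94-style generator acts on the sense codons of a genetic code.  For a
pair of codons differing at exactly one nucleotide position the rate is

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

and zero for multi-nucleotide changes.  ``kappa`` is the
transition/transversion rate ratio, ``omega`` = dN/dS, ``pi`` the codon
equilibrium frequencies (equal, F3x4 from positional nucleotide counts, or
F61 empirical).  The generator is reversible; see
:func:`gy94_rate_matrix` for the two normalization conventions (per-matrix
unit rate for single fits, shared neutral-reference rate inside site-class
mixtures), with branch lengths in expected codon substitutions either way.

Site-to-site variation in ω is a finite mixture (:class:`OmegaDistribution`),
either literal categories or discretizations of parametric laws (beta on
(0,1), gamma, shifted gamma) at the conditional means of K equiprobable
slices — the same construction as the discrete-gamma rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import betainc, gammainc
from scipy.stats import beta as beta_dist
from scipy.stats import gamma as gamma_dist

from .codes import GeneticCode, load_genetic_code
from .likelihood import ReversibleEigen

FREQUENCY_SCHEMES = ("F_equal", "F3x4", "F61")

KAPPA_BOUNDS = (0.01, 100.0)
OMEGA_BOUNDS = (0.0, 50.0)


# ---------------------------------------------------------------------------
# codon-pair structure (cached per code)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _pair_structure(code_name: str):
    """Boolean matrices over sense-codon pairs: single-nt change, transition,
    nonsynonymous, and the index of the target nucleotide per pair."""
    code = load_genetic_code(code_name)
    codons = code.sense_codons
    aas = code.sense_residues()
    S = len(codons)
    single = np.zeros((S, S), dtype=bool)
    transition = np.zeros((S, S), dtype=bool)
    nonsyn = np.zeros((S, S), dtype=bool)
    ts_pairs = {frozenset("AG"), frozenset("CT")}
    for i in range(S):
        for j in range(S):
            if i == j:
                continue
            diffs = [p for p in range(3) if codons[i][p] != codons[j][p]]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            p = diffs[0]
            transition[i, j] = frozenset((codons[i][p], codons[j][p])) in ts_pairs
            nonsyn[i, j] = aas[i] != aas[j]
    return single, transition, nonsyn


@dataclass(frozen=True)
class CodonParams:
    """Substitution-process side of a codon model: kappa and codon frequencies."""

    kappa: float
    pi: np.ndarray               # (S,) over sense codons, sums to 1
    frequency_scheme: str = "F3x4"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi", np.asarray(self.pi, float))
        if not KAPPA_BOUNDS[0] <= self.kappa <= KAPPA_BOUNDS[1]:
            raise ValueError(f"kappa must be in {KAPPA_BOUNDS}")
        if self.frequency_scheme not in FREQUENCY_SCHEMES:
            raise ValueError(f"frequency scheme must be one of {FREQUENCY_SCHEMES}")
        if (self.pi <= 0).any() or not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("codon frequencies must be positive and sum to 1")


def equal_codon_freqs(code: GeneticCode) -> np.ndarray:
    return np.full(code.n_states, 1.0 / code.n_states)


def f3x4_codon_freqs(alignment, pseudocount: float = 0.5) -> np.ndarray:
    """F3x4: positional nucleotide frequencies multiplied per codon, then
    renormalized over the sense codons of the alignment's code."""
    code = alignment.code
    counts = np.full((3, 4), pseudocount)
    nt_index = {c: i for i, c in enumerate("ACGT")}
    states = alignment.codons[:, alignment.mask]
    for s in states[states >= 0]:
        codon = code.sense_codons[s]
        for p in range(3):
            counts[p, nt_index[codon[p]]] += 1
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([
        pos_freqs[0, nt_index[c[0]]] * pos_freqs[1, nt_index[c[1]]]
        * pos_freqs[2, nt_index[c[2]]]
        for c in code.sense_codons
    ])
    return pi / pi.sum()


def f61_codon_freqs(alignment, pseudocount: float = 0.5) -> np.ndarray:
    """Empirical sense-codon frequencies (F61/F60 depending on the code)."""
    code = alignment.code
    counts = np.full(code.n_states, pseudocount)
    states = alignment.codons[:, alignment.mask]
    np.add.at(counts, states[states >= 0], 1.0)
    return counts / counts.sum()


def codon_frequencies(alignment, scheme: str) -> np.ndarray:
    if scheme == "F_equal":
        return equal_codon_freqs(alignment.code)
    if scheme == "F3x4":
        return f3x4_codon_freqs(alignment)
    if scheme == "F61":
        return f61_codon_freqs(alignment)
    raise ValueError(f"frequency scheme must be one of {FREQUENCY_SCHEMES}")


def gy94_rate_matrix(params: CodonParams, omega: float, code: GeneticCode,
                     normalize: str = "self") -> np.ndarray:
    """S x S GY94 generator.

    ``normalize="self"`` scales to one expected substitution per codon at
    stationarity (the single-matrix convention, used for M0-style output).
    ``normalize="neutral"`` divides by the total rate the same (kappa, pi)
    process would have at omega = 1, so that across the categories of a
    site-class mixture a higher-omega class genuinely evolves faster —
    the convention used throughout the mixture likelihoods and the
    simulator (a free global branch scale absorbs the constant).
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    single, transition, nonsyn = _pair_structure(code.name)
    S = code.n_states
    if params.pi.shape != (S,):
        raise ValueError("codon frequency vector does not match the code")
    factor = np.where(single, 1.0, 0.0)
    factor = factor * np.where(transition, params.kappa, 1.0)
    base = factor * params.pi[None, :]          # omega-free part
    Q = base * np.where(nonsyn, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    flow = params.pi[:, None] * Q
    syn_rate = float(flow[~nonsyn].sum())
    nonsyn_rate = float(flow[nonsyn].sum())
    if normalize == "self":
        rate = syn_rate + nonsyn_rate
    elif normalize == "neutral":
        # total rate of the same process at omega = 1
        flow1 = params.pi[:, None] * base
        np.fill_diagonal(flow1, 0.0)
        rate = float(flow1.sum())
    else:
        raise ValueError("normalize must be 'self' or 'neutral'")
    if rate <= 0:
        raise ValueError("degenerate codon process (zero total rate)")
    Q = Q / rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def gy94_eigen(params: CodonParams, omega: float, code: GeneticCode,
               normalize: str = "neutral") -> ReversibleEigen:
    return ReversibleEigen.from_rates(
        gy94_rate_matrix(params, omega, code, normalize), params.pi)


# ---------------------------------------------------------------------------
# omega distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OmegaDistribution:
    """Finite mixture of dN/dS categories (sorted non-decreasing)."""

    omegas: np.ndarray   # (K,)
    weights: np.ndarray  # (K,) sums to 1
    source: str = "literal"

    def __post_init__(self) -> None:
        om = np.asarray(self.omegas, float)
        w = np.asarray(self.weights, float)
        if om.ndim != 1 or om.shape != w.shape or om.size < 1:
            raise ValueError("omegas and weights must be matching 1-D arrays")
        if (om < 0).any():
            raise ValueError("omega categories must be non-negative")
        if not np.isclose(w.sum(), 1.0) or (w < 0).any():
            raise ValueError("weights must be non-negative and sum to 1")
        order = np.argsort(om, kind="stable")
        object.__setattr__(self, "omegas", om[order])
        object.__setattr__(self, "weights", w[order])

    @property
    def n_categories(self) -> int:
        return self.omegas.size

    def mean(self) -> float:
        return float(np.dot(self.weights, self.omegas))

    def variance(self) -> float:
        m = self.mean()
        return float(np.dot(self.weights, self.omegas ** 2) - m * m)

    def positive_mask(self) -> np.ndarray:
        return self.omegas > 1.0


def discretize_beta(p: float, q: float, K: int) -> OmegaDistribution:
    """K equiprobable categories of Beta(p, q) at their conditional means."""
    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return OmegaDistribution([p / (p + q)], [1.0], source=f"beta({p},{q})")
    cuts = beta_dist.ppf(np.arange(1, K) / K, p, q)
    bounds = np.concatenate([[0.0], cuts, [1.0]])
    mass = betainc(p + 1.0, q, bounds[1:]) - betainc(p + 1.0, q, bounds[:-1])
    means = mass * (p / (p + q)) * K
    return OmegaDistribution(means, np.full(K, 1.0 / K), source=f"beta({p},{q})")


def discretize_gamma_omega(shape: float, rate: float, K: int,
                           shift: float = 0.0) -> OmegaDistribution:
    """K equiprobable categories of shift + Gamma(shape, rate)."""
    if shape <= 0 or rate <= 0:
        raise ValueError("gamma parameters must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    mean = shape / rate
    if K == 1:
        return OmegaDistribution([shift + mean], [1.0])
    cuts = gamma_dist.ppf(np.arange(1, K) / K, shape, scale=1.0 / rate)
    bounds = np.concatenate([[0.0], cuts * rate, [np.inf]])
    mass = gammainc(shape + 1.0, bounds[1:]) - gammainc(shape + 1.0, bounds[:-1])
    means = mass * mean * K
    return OmegaDistribution(shift + means, np.full(K, 1.0 / K),
                             source=f"gamma({shape},{rate})+{shift}")


def point_mass(omega: float) -> OmegaDistribution:
    return OmegaDistribution([omega], [1.0], source="point")


def mix(components: list[OmegaDistribution],
        weights: np.ndarray) -> OmegaDistribution:
    """Mixture of component distributions with the given component weights."""
    weights = np.asarray(weights, float)
    if len(components) != weights.size:
        raise ValueError("one weight per component required")
    om = np.concatenate([c.omegas for c in components])
    w = np.concatenate([w0 * c.weights for w0, c in zip(weights, components)])
    return OmegaDistribution(om, w, source="mixture")
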