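"""GTR-family nucleotide substitution models with discrete-gamma rates.

The general time-reversible generator has off-diagonal entries
``q_ij = s_ij * pi_j`` with six symmetric exchangeabilities ``s`` (order
AC, AG, AT, CG, CT, GT; GT fixed to 1 when estimating) and stationary base
frequencies ``pi``.  The generator is normalized so the expected number of
substitutions per site per unit time at stationarity is one.  Among-site
rate variation uses Yang's discrete-gamma approximation: K equiprobable
categories at their conditional means, weighted mean rate one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .likelihood import ReversibleEigen

#: order of the six exchangeability parameters
EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class NucSubstModel:
    exchangeabilities: np.ndarray  # (6,) order EXCH_ORDER
    base_freqs: np.ndarray        # (4,) order A,C,G,T; sums to 1
    gamma_shape: float | None = None
    n_rate_categories: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "exchangeabilities",
                           np.asarray(self.exchangeabilities, float))
        object.__setattr__(self, "base_freqs", np.asarray(self.base_freqs, float))
        if self.exchangeabilities.shape != (6,) or (self.exchangeabilities <= 0).any():
            raise ValueError("need 6 positive exchangeabilities")
        if self.base_freqs.shape != (4,) or not np.isclose(self.base_freqs.sum(), 1.0):
            raise ValueError("base frequencies must be 4 values summing to 1")
        if self.gamma_shape is None:
            object.__setattr__(self, "n_rate_categories", 1)
        elif self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    @classmethod
    def jc(cls) -> "NucSubstModel":
        return cls(np.ones(6), np.full(4, 0.25))

    @classmethod
    def hky(cls, kappa: float, base_freqs) -> "NucSubstModel":
        # transitions: AG and CT
        ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls(ex, base_freqs)

    def with_(self, **kw) -> "NucSubstModel":
        return replace(self, **kw)


def gtr_rate_matrix(model: NucSubstModel) -> np.ndarray:
    """4x4 generator: q_ij = s_ij * pi_j, rows sum to 0, mean rate 1."""
    pi = model.base_freqs
    if (pi <= 0).any():
        raise ValueError("base frequencies must be strictly positive")
    Q = np.zeros((4, 4))
    for s, (i, j) in zip(model.exchangeabilities, _PAIRS):
        Q[i, j] = s * pi[j]
        Q[j, i] = s * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.dot(pi, np.diag(Q))
    return Q / rate


def transition_probabilities(generator: np.ndarray, t: float) -> np.ndarray:
    """Matrix exponential P(t) = expm(Q t); rows sum to 1."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return expm(np.asarray(generator, float) * t)


def discrete_gamma_rates(alpha: float, K: int) -> tuple[np.ndarray, np.ndarray]:
    """K equiprobable gamma(alpha, alpha) rate categories at conditional means."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return np.array([1.0]), np.array([1.0])
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    cuts = gamma_dist.ppf(np.arange(1, K) / K, alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], cuts * alpha, [np.inf]])
    # E[X; slice]/(1/K) with X ~ gamma(alpha, rate alpha), mean 1:
    mass = gammainc(alpha + 1.0, bounds[1:]) - gammainc(alpha + 1.0, bounds[:-1])
    rates = mass * K
    rates = rates / np.dot(rates, np.full(K, 1.0 / K))  # exact renormalization
    return rates, np.full(K, 1.0 / K)


def model_eigensystems(model: NucSubstModel) -> tuple[list[ReversibleEigen], np.ndarray]:
    """One eigensystem per rate category plus the category weights."""
    Q = gtr_rate_matrix(model)
    if model.gamma_shape is None:
        rates, weights = np.array([1.0]), np.array([1.0])
    else:
        rates, weights = discrete_gamma_rates(model.gamma_shape,
                                              model.n_rate_categories)
    base = ReversibleEigen.from_rates(Q, model.base_freqs)
    eigs = [ReversibleEigen(base.U, base.V, base.eigvals * r, base.pi)
            for r in rates]
    return eigs, weights


def empirical_base_freqs(data: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Base frequencies counted over an integer-coded alignment (-1 ignored)."""
    counts = np.array([(data == b).sum() for b in range(4)], float) + pseudocount
    return counts / counts.sum()
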