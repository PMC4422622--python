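"""Site-class codon model fitting, AIC ranking and empirical-Bayes site
detection.

Every model in the registry shares the GY94 substitution core (kappa, codon
frequencies, a global branch-length scale) and differs only in how dN/dS
varies across sites: a finite mixture of omega categories, literal or
induced by discretizing parametric laws.  Fitting alternates bounded
quasi-Newton updates of the continuous parameters (log-transformed) with EM
updates of the free mixture weights; the lnL trace over accepted outer
iterations is monotone.  Per-site category posteriors are naive empirical
Bayes: P(class k | site) = p_k L_k / sum_m p_m L_m at the MLEs.

Model registry (HyPhy-menu aliases in parentheses; "reported parameters"
counts the omega-distribution side only, the convention of the published
summary tables):

===============  ==========================================  ========
id               omega distribution                          reported
===============  ==========================================  ========
M0               one ratio                                   1
neutral          {0, 1}, free weight                         1
selection        {w0 in [0,1], 1, w2 >= 1}, free weights     4
discrete3        3 free categories, free weights (M3-like)   5
freqs            fixed grid {0, 1/3, 2/3, 1, 3}, free w      4
beta             Beta(p,q), K slices                         2
beta_w           Beta(p,q) + point w >= 1, free weight       4
beta_1           Beta(p,q) + point 1, free weight            3
beta_gamma1      Beta(p,q) + (1 + Gamma(a,b)), free weight   5
gamma_mod_beta   Beta(p,q) x Gamma(a,b) product              4
===============  ==========================================  ========
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alignments import CodonAlignment
from .codonmodel import (CodonParams, OmegaDistribution, codon_frequencies,
                         discretize_beta, discretize_gamma_omega, gy94_eigen,
                         point_mass)
from .likelihood import TreeIndex, compress_patterns

logger = logging.getLogger(__name__)

DEFAULT_K = 8   # discretization slices per continuous omega component
_FREQS_GRID = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0, 3.0)

_OMEGA_LO, _OMEGA_HI = 1e-4, 50.0
_SHAPE_LO, _SHAPE_HI = 5e-3, 99.0


def aic(lnL: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 lnL."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return 2.0 * k - 2.0 * lnL


@dataclass(frozen=True)
class CodonSiteModel:
    """One entry of the site-model registry (see module docstring)."""

    model_id: str
    name: str
    aliases: tuple[str, ...]
    n_reported_params: int
    theta_init: tuple[float, ...]          # raw-scale continuous parameters
    theta_bounds: tuple[tuple[float, float], ...]
    n_components: int
    free_weights: bool

    def components(self, theta: np.ndarray, K: int = DEFAULT_K
                   ) -> list[OmegaDistribution]:
        return _BUILDERS[self.model_id](theta, K)

    def init_weights(self) -> np.ndarray:
        return np.full(self.n_components, 1.0 / self.n_components)

    def jitter_theta(self, rng: np.random.Generator) -> np.ndarray:
        lo = np.array([b[0] for b in self.theta_bounds])
        hi = np.array([b[1] for b in self.theta_bounds])
        z = np.log(np.asarray(self.theta_init)) + rng.normal(0, 0.7,
                                                             len(self.theta_init))
        return np.clip(np.exp(z), lo, hi)


def _build_m0(theta, K):
    return [point_mass(theta[0])]


def _build_neutral(theta, K):
    return [point_mass(0.0), point_mass(1.0)]


def _build_selection(theta, K):
    return [point_mass(theta[0]), point_mass(1.0), point_mass(theta[1])]


def _build_discrete3(theta, K):
    return [point_mass(w) for w in theta]


def _build_freqs(theta, K):
    return [point_mass(w) for w in _FREQS_GRID]


def _build_beta(theta, K):
    return [discretize_beta(theta[0], theta[1], K)]


def _build_beta_w(theta, K):
    return [discretize_beta(theta[0], theta[1], K), point_mass(theta[2])]


def _build_beta_1(theta, K):
    return [discretize_beta(theta[0], theta[1], K), point_mass(1.0)]


def _build_beta_gamma1(theta, K):
    return [discretize_beta(theta[0], theta[1], K),
            discretize_gamma_omega(theta[2], theta[3], K, shift=1.0)]


def _build_gamma_mod_beta(theta, K):
    # product law Beta(p,q) x Gamma(a,b), discretized 4x4
    b = discretize_beta(theta[0], theta[1], 4)
    g = discretize_gamma_omega(theta[2], theta[3], 4)
    om = np.outer(b.omegas, g.omegas).ravel()
    w = np.outer(b.weights, g.weights).ravel()
    return [OmegaDistribution(om, w, source="beta*gamma")]


_BUILDERS = {
    "M0": _build_m0,
    "neutral": _build_neutral,
    "selection": _build_selection,
    "discrete3": _build_discrete3,
    "freqs": _build_freqs,
    "beta": _build_beta,
    "beta_w": _build_beta_w,
    "beta_1": _build_beta_1,
    "beta_gamma1": _build_beta_gamma1,
    "gamma_mod_beta": _build_gamma_mod_beta,
}

_OB = (_OMEGA_LO, _OMEGA_HI)
_SB = (_SHAPE_LO, _SHAPE_HI)

MODEL_REGISTRY: dict[str, CodonSiteModel] = {
    m.model_id: m for m in [
        CodonSiteModel("M0", "One ratio", ("MODEL 0", "one-ratio"), 1,
                       (0.3,), (_OB,), 1, False),
        CodonSiteModel("neutral", "Neutral", ("MODEL 1 (Neutral)",), 1,
                       (), (), 2, True),
        CodonSiteModel("selection", "Selection", ("MODEL 2 (Selection)",), 4,
                       (0.2, 2.0), ((_OMEGA_LO, 1.0), (1.0, _OMEGA_HI)),
                       3, True),
        CodonSiteModel("discrete3", "Discrete", ("MODEL 3 (Discrete)", "M3"), 5,
                       (0.1, 0.8, 2.5), (_OB, _OB, _OB), 3, True),
        CodonSiteModel("freqs", "Freqs", ("MODEL 4 (Freqs)",), 4,
                       (), (), 5, True),
        CodonSiteModel("beta", "Beta", ("MODEL 7 (Beta)", "M7"), 2,
                       (0.5, 1.5), (_SB, _SB), 1, False),
        CodonSiteModel("beta_w", "Beta & w", ("MODEL 8 (Beta & w)", "M8"), 4,
                       (0.5, 1.5, 2.0), (_SB, _SB, (1.0, _OMEGA_HI)), 2, True),
        CodonSiteModel("beta_1", "Beta & 1", ("MODEL 15 (Beta & 1)",), 3,
                       (0.5, 1.5), (_SB, _SB), 2, True),
        CodonSiteModel("beta_gamma1", "Beta & (Gamma+1)",
                       ("MODEL 10 (Beta & (Gamma+1))",), 5,
                       (0.5, 1.5, 1.0, 2.0), (_SB, _SB, _SB, _SB), 2, True),
        CodonSiteModel("gamma_mod_beta", "Gamma mod Beta",
                       ("MODEL 14 (Gamma mod Beta)",), 4,
                       (2.0, 2.0, 1.0, 1.5), (_SB, _SB, _SB, _SB), 1, False),
    ]
}


def resolve_model(name: str) -> CodonSiteModel:
    if name in MODEL_REGISTRY:
        return MODEL_REGISTRY[name]
    for m in MODEL_REGISTRY.values():
        if name == m.name or name in m.aliases:
            return m
    raise KeyError(f"unknown codon site model {name!r}; known ids: "
                   + ", ".join(MODEL_REGISTRY))


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class CodonFitResult:
    model: CodonSiteModel
    omega_distribution: OmegaDistribution
    kappa: float
    scale: float
    params: CodonParams
    log_likelihood: float
    aic: float
    k_full: int
    #: (n_sites, K) category posteriors; masked sites are NaN rows
    site_posteriors: np.ndarray
    #: per-site posterior mass on categories with omega > 1 (NaN if masked)
    positive_posterior: np.ndarray
    gene: str = ""
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def global_omega(self) -> float:
        return self.omega_distribution.mean()

    @property
    def omega_variance(self) -> float:
        return self.omega_distribution.variance()

    @property
    def selection_threshold(self) -> float:
        return selection_threshold(self.omega_distribution)

    @property
    def prior_positive_weight(self) -> float:
        d = self.omega_distribution
        return float(d.weights[d.positive_mask()].sum())

    @property
    def positive_proportion(self) -> float:
        return positive_proportion(self)

    def candidate_sites(self, threshold: float = 0.5) -> list[tuple[int, float]]:
        """(1-based site, positive posterior) above threshold, descending."""
        out = [(i + 1, float(p)) for i, p in enumerate(self.positive_posterior)
               if np.isfinite(p) and p > threshold]
        return sorted(out, key=lambda t: -t[1])


def omega_summary(omega_dist: OmegaDistribution) -> tuple[float, float]:
    """Global mean and variance of dN/dS under the fitted distribution."""
    return omega_dist.mean(), omega_dist.variance()


def selection_threshold(omega_dist: OmegaDistribution) -> float:
    """Smallest category value strictly above 1, else exactly 1.00.

    This is the dN/dS of the positive-selection component; models without a
    category above one report 1.00 ("no positive selection in the model").
    """
    above = omega_dist.omegas[omega_dist.omegas > 1.0]
    return float(above.min()) if above.size else 1.0


def positive_proportion(fit_result: CodonFitResult) -> float:
    """NEB fraction of unmasked sites with positive-class posterior > 0.5."""
    p = fit_result.positive_posterior
    finite = np.isfinite(p)
    if not finite.any():
        return 0.0
    return float((p[finite] > 0.5).sum() / finite.sum())


# ---------------------------------------------------------------------------
# likelihood core
# ---------------------------------------------------------------------------

def _category_arrays(model, theta, K):
    comps = model.components(theta, K)
    om = np.concatenate([c.omegas for c in comps])
    relw = np.concatenate([c.weights for c in comps])
    comp_of = np.concatenate([np.full(c.n_categories, i)
                              for i, c in enumerate(comps)])
    return om, relw, comp_of


def _cat_logliks(tidx, patterns, params, code, omegas, base_lengths, scale):
    eigs = []
    cache: dict[float, object] = {}
    for w in omegas:
        key = round(float(w), 12)
        if key not in cache:
            cache[key] = gy94_eigen(params, float(w), code)
        eigs.append(cache[key])
    from .likelihood import category_site_logliks
    return category_site_logliks(tidx, patterns, eigs, base_lengths * scale)


def _make_lcl_fn(tidx, patterns, pi, scheme, code, base_lengths):
    """Per-category site log-likelihood columns with memoization.

    Finite-difference steps of the optimizer perturb one parameter at a
    time; caching columns by (kappa, scale, omega) means such steps only
    recompute the pruning pass for the categories actually affected.
    """
    from .likelihood import category_site_logliks
    col_cache: dict[tuple, np.ndarray] = {}
    eig_cache: dict[tuple, object] = {}

    def lcl_for(kappa: float, scale: float, omegas: np.ndarray) -> np.ndarray:
        if len(col_cache) > 5000:
            col_cache.clear()
        cols = np.empty((patterns.shape[1], len(omegas)))
        keys = [(round(float(kappa), 10), round(float(scale), 10),
                 round(float(w), 10)) for w in omegas]
        missing = [i for i, k in enumerate(keys) if k not in col_cache]
        for i, k in enumerate(keys):
            if k in col_cache:
                cols[:, i] = col_cache[k]
        if missing:
            params = CodonParams(float(kappa), pi, scheme)
            eigs = []
            for i in missing:
                ek = (keys[i][0], keys[i][2])
                if ek not in eig_cache:
                    if len(eig_cache) > 2000:
                        eig_cache.clear()
                    eig_cache[ek] = gy94_eigen(params, float(omegas[i]), code)
                eigs.append(eig_cache[ek])
            sub = category_site_logliks(tidx, patterns, eigs,
                                        base_lengths * scale)
            for slot, i in enumerate(missing):
                cols[:, i] = sub[:, slot]
                col_cache[keys[i]] = sub[:, slot].copy()
        return cols

    return lcl_for


def codon_site_loglik(tree, alignment: CodonAlignment, params: CodonParams,
                      omega_dist: OmegaDistribution, scale: float = 1.0):
    """Mixture lnL plus the per-site per-category log-likelihood table.

    Returns ``(lnL, site_cat_logliks)`` where the table is (n_unmasked_sites
    ordered as in the alignment, K) — the raw material for NEB posteriors.
    """
    if not alignment.mask.any():
        raise ValueError("all codon columns are masked")
    tidx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree, alignment.taxa)
    patterns, pat_w, site_to_pat = compress_patterns(alignment.codons,
                                                     alignment.mask)
    lcl = _cat_logliks(tidx, patterns, params, alignment.code,
                       omega_dist.omegas, tidx.edge_len, scale)
    logw = np.log(np.clip(omega_dist.weights, 1e-300, None))
    lnL = float(np.dot(pat_w, logsumexp(lcl + logw[None, :], axis=1)))
    site_lcl = np.full((alignment.n_sites, omega_dist.n_categories), np.nan)
    unmasked = site_to_pat >= 0
    site_lcl[unmasked] = lcl[site_to_pat[unmasked]]
    return lnL, site_lcl


def _softmax_weights(logits: np.ndarray) -> np.ndarray:
    """Component weights from free logits (first component's logit pinned 0)."""
    z = np.concatenate([[0.0], logits])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def fit_codon_model(
    tree,
    alignment: CodonAlignment,
    model: CodonSiteModel | str,
    *,
    frequency_scheme: str = "F3x4",
    K: int = DEFAULT_K,
    n_starts: int = 3,
    seed: int = 0,
    optimize_branches: bool = False,
    max_outer: int = 40,
    tol: float = 1e-6,
) -> CodonFitResult:
    """Maximum-likelihood fit of one site model on a fixed topology.

    Branch lengths are taken from the tree up to a global scale factor
    estimated by ML (codon units); with ``optimize_branches`` (M0 only) each
    branch is additionally optimized.  Multi-start: the first start uses the
    registry initial values, further starts jitter them (seeded).
    """
    if isinstance(model, str):
        model = resolve_model(model)
    if not alignment.mask.any():
        raise ValueError("all codon columns are masked")
    tidx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree, alignment.taxa)
    base_lengths = tidx.copy_lengths()
    if base_lengths[:-1].max() <= 0:
        raise ValueError("tree must carry positive branch lengths")
    patterns, pat_w, site_to_pat = compress_patterns(alignment.codons,
                                                     alignment.mask)
    pi = codon_frequencies(alignment, frequency_scheme)
    code = alignment.code
    rng = np.random.default_rng(seed)
    lcl_for = _make_lcl_fn(tidx, patterns, pi, frequency_scheme, code,
                           base_lengths)

    n_theta = len(model.theta_init)
    n_free_w = model.n_components - 1 if model.free_weights else 0
    lo = np.concatenate([
        np.log(np.array([0.01, 1e-3] + [b[0] for b in model.theta_bounds])),
        np.full(n_free_w, -15.0)])
    hi = np.concatenate([
        np.log(np.array([100.0, 1e3] + [b[1] for b in model.theta_bounds])),
        np.full(n_free_w, 15.0)])

    def unpack(zv):
        kappa = float(np.exp(zv[0]))
        scale = float(np.exp(zv[1]))
        th = np.exp(zv[2:2 + n_theta])
        comp_w = (_softmax_weights(zv[2 + n_theta:]) if n_free_w
                  else model.init_weights())
        return kappa, scale, th, comp_w

    def neg(zv):
        zv = np.clip(zv, lo, hi - 1e-12)
        kappa, scale, th, comp_w = unpack(zv)
        om, relw, comp_of = _category_arrays(model, th, K)
        lcl = lcl_for(kappa, scale, om)
        catw = relw * comp_w[comp_of]
        lse = logsumexp(lcl + np.log(np.clip(catw, 1e-300, None))[None, :],
                        axis=1)
        return -float(np.dot(pat_w, lse))

    best = None
    for start in range(n_starts):
        if start == 0:
            theta0 = np.asarray(model.theta_init, float)
            kappa0, scale0 = 2.0, 1.0
            logits0 = np.zeros(n_free_w)
        elif start in (1, 2) and n_free_w:
            # sparse positive class: a rare strongly selected component is a
            # narrow likelihood valley that equal-weight starts often miss;
            # the second sparse start targets a single-site-scale weight
            hi_om = 4.0 if start == 1 else 8.0
            theta0 = np.array([min(hi_om, b[1]) if b[1] > 1.0 else t0
                               for t0, b in zip(model.theta_init,
                                                model.theta_bounds)])
            kappa0, scale0 = 2.0, 1.0
            logits0 = np.zeros(n_free_w)
            logits0[-1] = -3.0 if start == 1 else -6.0
        else:
            theta0 = model.jitter_theta(rng)
            kappa0 = float(np.exp(rng.normal(np.log(2.0), 0.5)))
            scale0 = float(np.exp(rng.normal(0.0, 0.5)))
            logits0 = rng.normal(0.0, 0.8, n_free_w)
        z = np.concatenate([np.log([kappa0, scale0]),
                            np.log(theta0) if n_theta else [], logits0])
        z = np.clip(z, lo, hi)
        res = minimize(neg, z, method="L-BFGS-B", bounds=list(zip(lo, hi)),
                       options={"maxiter": max_outer * 10, "ftol": tol * 1e-4,
                                "gtol": 1e-6})
        lnL = -res.fun
        if best is None or lnL > best[0]:
            best = (lnL, np.clip(res.x, lo, hi - 1e-12), bool(res.success))

    lnL, z, converged = best
    kappa, scale, theta, comp_w = unpack(z)
    params = CodonParams(kappa, pi, frequency_scheme)

    if optimize_branches:
        if model.model_id != "M0":
            raise ValueError("per-branch optimization is supported under M0 only")
        from .likelihood import optimize_branch_lengths
        eig = [gy94_eigen(params, float(theta[0]), code)]
        tidx.edge_len = base_lengths * scale
        lengths, lnL, _ = optimize_branch_lengths(tidx, patterns, pat_w, eig,
                                                  np.array([1.0]))
        base_lengths, scale = lengths, 1.0

    om, relw, comp_of = _category_arrays(model, theta, K)
    lcl = lcl_for(kappa, scale, om) if not optimize_branches else \
        _cat_logliks(tidx, patterns, params, code, om, base_lengths, scale)
    cat_w = relw * comp_w[comp_of]
    dist = OmegaDistribution(om, cat_w, source=model.model_id)
    # category posteriors, ordered like the sorted distribution
    order = np.argsort(om, kind="stable")
    logcat = lcl[:, order] + np.log(np.clip(cat_w[order], 1e-300, None))[None, :]
    lse = logsumexp(logcat, axis=1)
    post_pat = np.exp(logcat - lse[:, None])
    n_sites = alignment.n_sites
    posts = np.full((n_sites, om.size), np.nan)
    unmasked = site_to_pat >= 0
    posts[unmasked] = post_pat[site_to_pat[unmasked]]
    pos = np.full(n_sites, np.nan)
    pos[unmasked] = posts[unmasked][:, dist.positive_mask()].sum(axis=1)

    n_free_w = model.n_components - 1 if model.free_weights else 0
    k_full = 2 + len(theta) + n_free_w  # kappa + scale + continuous + weights
    if optimize_branches:
        k_full += tidx.n_nodes - 2
    result = CodonFitResult(
        model=model, omega_distribution=dist, kappa=kappa, scale=scale,
        params=params, log_likelihood=lnL, aic=aic(lnL, k_full),
        k_full=k_full, site_posteriors=posts, positive_posterior=pos,
        gene=alignment.gene, converged=converged,
    )
    if not converged:
        result.notes.append("optimizer did not fully converge")
    return result


def model_scan(tree, alignment: CodonAlignment,
               registry=None, **fit_options) -> list[CodonFitResult]:
    """Fit every registry model and rank by AIC (ties -> fewer parameters).

    Single-model failures are logged and skipped; the scan continues.
    """
    registry = list(MODEL_REGISTRY) if registry is None else list(registry)
    if not registry:
        raise ValueError("empty model registry")
    tidx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree, alignment.taxa)
    fits = []
    for name in registry:
        try:
            fits.append(fit_codon_model(tidx, alignment, name, **fit_options))
        except Exception:
            logger.exception("fit failed for model %s on gene %s", name,
                             alignment.gene)
    if not fits:
        raise RuntimeError(f"every model fit failed for gene {alignment.gene!r}")
    fits.sort(key=lambda f: (round(f.aic, 9), f.k_full))
    return fits
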