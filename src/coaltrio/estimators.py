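"""The four species-tree estimation methods for rooted triplets.

* two-step (majority vote): per-locus maximum-likelihood gene trees
  (the count rule: the ML gene tree under JC with the clock is the
  topology whose supporting informative pattern count is largest),
  aggregated by majority vote;
* concatenation: pooled pattern counts, argmax of the informative
  categories for the topology, plus a JC-clock node-age fit;
* independent-sites ML (isml): same topology rule as concatenation
  (pooled-count argmax), plus a moment inversion of the equal-theta
  marginal pattern probabilities for (tau0, tau1, theta);
* full maximum likelihood under the MSC: per-locus likelihood obtained
  by summing over the four gene-tree classes and integrating the
  coalescent times against the MSC density with Gauss-Legendre
  quadrature, maximized over all four parameters per candidate tree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .core import (
    GeneTreeSample,
    ParameterError,
    SpeciesTreeParams,
    conditional_pattern_probs,
    marginal_pattern_probs_equal_theta,
)
from .simulate import LocusCounts, MultilocusDataset

__all__ = [
    "ConcatFit",
    "EstimationError",
    "GeneTreeCall",
    "IsmlMoments",
    "IsmlParamEstimate",
    "MscFit",
    "SpeciesTreeCall",
    "concat_fit_times",
    "concat_isml_topology",
    "isml_estimate_params",
    "ml_gene_tree",
    "ml_msc_fit",
    "ml_msc_species_tree",
    "msc_loglik",
    "species_tree_from_true_gene_trees",
    "two_step",
]

#: counts-column permutation that maps data to the S1 orientation of each
#: candidate species tree (swap the informative category that plays the
#: "matching" role): S2 swaps xxy<->yxx, S3 swaps xxy<->xyx.
TREE_COUNT_PERMUTATION = {
    1: (0, 1, 2, 3, 4),
    2: (0, 2, 1, 3, 4),
    3: (0, 3, 2, 1, 4),
}

ML_TIE_TOL = 1e-6


class EstimationError(RuntimeError):
    """Raised when an estimator's admissibility conditions fail."""


@dataclass(frozen=True)
class GeneTreeCall:
    """ML gene tree for one locus: winner index in {1,2,3}, or a tie-set."""

    winner: int | None
    tie: tuple[int, ...]


@dataclass(frozen=True)
class SpeciesTreeCall:
    """A species-tree estimate with its comparison statistics.

    ``support`` holds the method's statistic for (S1, S2, S3): the vote
    counts for two-step, pooled informative counts for concat/isml, and
    maximized log-likelihoods for ML. ``winner`` is None when tied.
    """

    winner: int | None
    tie: tuple[int, ...]
    support: np.ndarray
    method: str
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class IsmlMoments:
    """Moment combinations of pooled frequencies used by the isml inversion."""

    h1: float
    h2: float
    h3: float
    A: float
    B: float
    C: float


@dataclass(frozen=True)
class IsmlParamEstimate:
    theta_hat: float
    tau0_hat: float
    tau1_hat: float
    moments: IsmlMoments


@dataclass(frozen=True)
class ConcatFit:
    """JC-clock node-age MLEs from pooled counts."""

    t0_hat: float
    t1_hat: float
    loglik: float
    boundary: bool = False


@dataclass(frozen=True)
class MscFit:
    """Maximized MSC likelihood for one candidate species tree."""

    tree: int
    params_hat: SpeciesTreeParams
    loglik: float
    quad_nodes: int
    converged: bool
    boundary: bool
    n_starts: int
    message: str = ""


def _argmax_call(stats, tol: float = 0.0) -> tuple[int | None, tuple[int, ...]]:
    stats = np.asarray(stats, dtype=float)
    top = stats.max()
    tie = tuple(int(i) + 1 for i in np.flatnonzero(stats >= top - tol))
    winner = tie[0] if len(tie) == 1 else None
    return winner, tie


def ml_gene_tree(counts: LocusCounts | np.ndarray) -> GeneTreeCall:
    """ML gene tree for one locus by the count rule.

    Under JC with the clock, the ML (and UPGMA) gene tree is G_j when
    the informative count x_j is strictly largest among (x1, x2, x3);
    equal maxima are reported as a tie-set.
    """
    x = counts.x if isinstance(counts, LocusCounts) else np.asarray(counts)
    winner, tie = _argmax_call(x[1:4])
    return GeneTreeCall(winner=winner, tie=tie)


def _informative(data: MultilocusDataset) -> np.ndarray:
    arr = data.probs if data.exact else data.counts
    return np.asarray(arr, dtype=float)[:, 1:4]


def two_step(
    data: MultilocusDataset,
    tie_policy: str = "even",
    rng: np.random.Generator | None = None,
) -> SpeciesTreeCall:
    """Majority vote over per-locus ML gene trees.

    Tie policies for unresolved loci: ``even`` credits each tied tree
    1/k of the locus vote, ``drop`` discards the locus, ``random``
    assigns the vote uniformly at random (requires ``rng``).
    """
    inf = _informative(data)
    mx = inf.max(axis=1, keepdims=True)
    is_max = inf == mx
    k = is_max.sum(axis=1)
    if tie_policy == "even":
        votes = (is_max / k[:, None]).sum(axis=0)
    elif tie_policy == "drop":
        votes = is_max[k == 1].sum(axis=0).astype(float)
    elif tie_policy == "random":
        if rng is None:
            raise ParameterError("tie_policy='random' requires rng")
        r = np.where(is_max, rng.random(is_max.shape), -1.0)
        votes = np.bincount(np.argmax(r, axis=1), minlength=3).astype(float)
    else:
        raise ParameterError(f"unknown tie_policy {tie_policy!r}")
    winner, tie = _argmax_call(votes)
    return SpeciesTreeCall(winner=winner, tie=tie, support=votes, method="2step")


def concat_isml_topology(data: MultilocusDataset) -> SpeciesTreeCall:
    """Species tree from pooled pattern counts (concatenation == isml).

    The winner is the species tree whose informative category has the
    largest pooled count (for infinite-sites data, the largest mean
    per-locus pattern probability).
    """
    pooled = _informative(data).sum(axis=0)
    winner, tie = _argmax_call(pooled)
    return SpeciesTreeCall(winner=winner, tie=tie, support=pooled, method="concat/isml")


def concat_fit_times(pooled) -> ConcatFit:
    """JC-clock MLEs (t0_hat, t1_hat) of the node ages of a single gene
    tree fitted to pooled pattern counts.

    ``pooled`` may be a :class:`LocusCounts` or any nonnegative 5-vector
    (counts, frequencies, or exact probabilities); the fit maximizes
    sum_j x_j log p_j(t0, t1) subject to t0 >= t1 >= 0.  This is the
    concatenation estimator, which is biased under the MSC because it
    ignores the coalescent fluctuation of gene trees among loci.
    """
    x = pooled.x if isinstance(pooled, LocusCounts) else np.asarray(pooled, dtype=float)
    if x.shape != (5,) or np.any(x < 0):
        raise ParameterError("pooled must be a nonnegative 5-vector")
    total = x.sum()
    if total <= 0 or x[1:].sum() == 0:
        warnings.warn("degenerate (all-constant) pooled counts; boundary estimate")
        return ConcatFit(t0_hat=0.0, t1_hat=0.0, loglik=0.0, boundary=True)

    f = x / total
    # JC distance starts from pairwise mismatch proportions
    d_ab = min(f[2] + f[3] + f[4], 0.70)
    d_bc = min(f[1] + f[3] + f[4], 0.70)
    t1_0 = max(-0.75 * math.log1p(-4.0 * d_ab / 3.0) / 2.0, 1e-6)
    t0_0 = max(-0.75 * math.log1p(-4.0 * d_bc / 3.0) / 2.0, 2e-6, 1.001 * t1_0)

    def nll(z):
        t1 = math.exp(z[0])
        t0 = t1 + math.exp(z[1])
        with np.errstate(divide="ignore"):
            lp = np.log(conditional_pattern_probs(t0, t1))
        val = -(x @ lp)
        return val if np.isfinite(val) else 1e300

    z0 = [math.log(t1_0), math.log(max(t0_0 - t1_0, 1e-8))]
    res = minimize(
        nll, z0, method="Nelder-Mead",
        options=dict(xatol=1e-12, fatol=1e-14, maxiter=10_000, maxfev=10_000),
    )
    t1_hat = math.exp(res.x[0])
    t0_hat = t1_hat + math.exp(res.x[1])
    return ConcatFit(t0_hat=t0_hat, t1_hat=t1_hat, loglik=-res.fun)


def isml_estimate_params(pooled_freqs) -> IsmlParamEstimate:
    """Moment inversion of the equal-theta marginal pattern probabilities.

    From pooled frequencies form h1 = f0 + f1, h2 = f0 + (f2 + f3)/2,
    h3 = f1 + (f2 + f3)/2 and A = 4 h3 - 2 h1 - 1, B = 4 h1 - 1,
    C = 4 h2 - 1.  theta_hat is the unique positive root of

        4 A^2 theta^2 + (3 A^2 - B C^2)(4 theta + 3) = 0,

    and tau1_hat, tau0_hat follow by inverting a1 = B/9, a0 = C/9 at
    theta_hat.  When the generating model has theta0 != theta1 the
    estimates converge to pseudotrue values, not the truth.
    """
    f = np.asarray(pooled_freqs, dtype=float)
    if f.shape != (5,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-6:
        raise ParameterError("pooled_freqs must be a probability 5-vector")
    h1 = f[0] + f[1]
    h2 = f[0] + 0.5 * (f[2] + f[3])
    h3 = f[1] + 0.5 * (f[2] + f[3])
    A = 4.0 * h3 - 2.0 * h1 - 1.0
    B = 4.0 * h1 - 1.0
    C = 4.0 * h2 - 1.0
    mom = IsmlMoments(h1=h1, h2=h2, h3=h3, A=A, B=B, C=C)
    if B <= 0:
        raise EstimationError(f"inadmissible moments: B = 4 h1 - 1 = {B:.6g} <= 0")
    if C <= 0:
        raise EstimationError(f"inadmissible moments: C = 4 h2 - 1 = {C:.6g} <= 0")
    if A == 0:
        raise EstimationError("inadmissible moments: A = 4 h3 - 2 h1 - 1 = 0")
    disc = 3.0 * A * A - B * C * C
    if disc >= 0:
        raise EstimationError(
            f"inadmissible moments: 3 A^2 - B C^2 = {disc:.6g} >= 0 (no positive root)"
        )
    # 4 A^2 t^2 + 4 disc t + 3 disc = 0, disc < 0 => unique positive root
    alpha = 4.0 * A * A
    theta = (-4.0 * disc + math.sqrt(16.0 * disc * disc - 12.0 * alpha * disc)) / (
        2.0 * alpha
    )
    arg1 = (B / 9.0) * (3.0 + 4.0 * theta)
    arg0 = (C / 9.0) * (3.0 + 4.0 * theta)
    if not (0.0 < arg0 < arg1 < 1.0):
        raise EstimationError(
            "inadmissible moments: inverted a0/a1 do not give 0 < tau1 < tau0"
        )
    tau1 = -0.375 * math.log(arg1)
    tau0 = -0.375 * math.log(arg0)
    return IsmlParamEstimate(theta_hat=theta, tau0_hat=tau0, tau1_hat=tau1, moments=mom)


# ---------------------------------------------------------------------------
# full ML under the MSC


@lru_cache(maxsize=8)
def _quad_rules(K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on (0, 1) and Gauss-Laguerre nodes/weights."""
    from scipy.special import roots_laguerre, roots_legendre

    x, w = roots_legendre(K)
    xi, wq = roots_laguerre(K)
    return (x + 1.0) / 2.0, w / 2.0, xi, wq


def _tree_index(tree) -> int:
    if isinstance(tree, str):
        if tree.upper() in ("S1", "S2", "S3"):
            return int(tree[1])
        raise ParameterError(f"unknown tree {tree!r}")
    tree = int(tree)
    if tree not in (1, 2, 3):
        raise ParameterError("tree index must be 1, 2 or 3")
    return tree


def _quadrature_logp_logw(
    params: SpeciesTreeParams, K: int
) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes for the per-locus MSC likelihood (S1 orientation).

    The bounded coordinate (t1 of class G1a, on (tau1, tau0)) is mapped
    through the exponential probability transform
    y = exp(-(2/theta1)(t1 - tau1)) and integrated with Gauss-Legendre;
    each unbounded coordinate carries the MSC exponential density as its
    weight function exactly, so Gauss-Laguerre applies and converges to
    machine precision by K ~ 16.  Returns (log pattern probs, log
    weights) with one row per (node, gene-tree class) pair.
    """
    tau0, tau1, theta0, theta1 = params.astuple()
    phi = params.phi
    y, w, xi, wq = _quad_rules(K)

    # class G1a: t1 in (tau1, tau0), t0 in (tau0, inf)
    y1 = phi + (1.0 - phi) * y              # exp(-(2/theta1)(t1-tau1)) in (phi, 1)
    t1a = tau1 - 0.5 * theta1 * np.log(y1)
    t0a = tau0 + 0.5 * theta0 * xi
    w1a = np.outer((1.0 - phi) * w, wq).ravel()
    grid_t1 = np.repeat(t1a, K)
    grid_t0 = np.tile(t0a, K)
    p_g1a = conditional_pattern_probs(grid_t0, grid_t1)

    # classes G1b/G2/G3: t1 in (tau0, inf), t0 in (t1, inf)
    t1b = tau0 + theta0 / 6.0 * xi
    g_t1 = np.repeat(t1b, K)
    g_t0 = g_t1 + 0.5 * theta0 * np.tile(xi, K)
    wb = (phi / 3.0) * np.outer(wq, wq).ravel()
    p_base = conditional_pattern_probs(g_t0, g_t1)

    blocks = [p_g1a, p_base, p_base[:, (0, 2, 1, 3, 4)], p_base[:, (0, 3, 2, 1, 4)]]
    logp = np.log(np.concatenate(blocks, axis=0))
    # sums of logs: raw products of Laguerre tail weights underflow, and
    # phi itself can under/overflow at extreme internal branch lengths
    log_phi = -2.0 * (tau0 - tau1) / theta1
    log_1mphi = math.log(-math.expm1(log_phi)) if log_phi < 0.0 else -math.inf
    lw = np.log(w)
    lwq = np.log(wq)
    lw1a = (log_1mphi + lw[:, None] + lwq[None, :]).ravel()
    lwb = (log_phi - math.log(3.0) + lwq[:, None] + lwq[None, :]).ravel()
    logw = np.concatenate([lw1a, lwb, lwb, lwb])
    return logp, logw


def _counts_matrix(data) -> tuple[np.ndarray, float]:
    if isinstance(data, MultilocusDataset):
        if data.exact:
            raise ParameterError("the finite-n likelihood needs pattern counts")
        return data.counts, data.n
    arr = np.asarray(data, dtype=np.int64)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size and arr.shape[1] != 5:
        raise ParameterError("counts must have 5 columns")
    n = arr.sum(axis=1).max() if arr.size else 0
    return arr, n


def msc_loglik(
    data,
    tree,
    params: SpeciesTreeParams,
    quad_nodes: int = 32,
    per_locus: bool = False,
):
    """Log-likelihood of a multilocus dataset under one species tree.

    Per locus the likelihood is the 4-class mixture of the multinomial
    site-pattern probability integrated over the coalescent times with
    the MSC density (Gauss-Legendre quadrature with ``quad_nodes`` nodes
    per dimension).  Trees S2/S3 are handled by permuting the count
    columns into the S1 orientation.  Includes the multinomial
    coefficient, so exp of the per-locus value is the probability of the
    locus's count vector.  An empty dataset gives 0.
    """
    if quad_nodes < 8:
        raise ParameterError("quad_nodes must be >= 8")
    counts, _n = _counts_matrix(data)
    if counts.shape[0] == 0:
        return np.zeros(0) if per_locus else 0.0
    j = _tree_index(tree)
    x = counts[:, TREE_COUNT_PERMUTATION[j]]
    logp, logw = _quadrature_logp_logw(params, quad_nodes)

    uniq, inv = np.unique(x, axis=0, return_inverse=True)
    ns = uniq.sum(axis=1)
    logcoef = gammaln(ns + 1) - gammaln(uniq + 1).sum(axis=1)
    m_nodes = uniq @ logp.T + logw  # (n_unique, n_nodes)
    lu = logsumexp(m_nodes, axis=1) + logcoef
    if not np.all(np.isfinite(lu)):
        raise FloatingPointError("non-finite quadrature likelihood")
    if per_locus:
        return lu[inv]
    return float(np.bincount(inv, minlength=len(lu)).astype(float) @ lu)


def _heuristic_starts(data, n_starts: int) -> list[np.ndarray]:
    """Starting points in (log tau1, log dtau, log theta0, log theta1)."""
    if isinstance(data, MultilocusDataset):
        f = data.pooled_frequencies()
    else:
        counts, _ = _counts_matrix(data)
        tot = counts.sum()
        f = counts.sum(axis=0) / tot if tot else np.full(5, 0.2)
    start = None
    try:
        est = isml_estimate_params(f)
        start = (est.tau1_hat, est.tau0_hat - est.tau1_hat, est.theta_hat, est.theta_hat)
    except (EstimationError, ParameterError):
        pass
    if start is None:
        d_ab = min(f[2] + f[3] + f[4], 0.70)
        d_bc = min(f[1] + f[3] + f[4], 0.70)
        t1 = max(-0.75 * math.log1p(-4.0 * d_ab / 3.0) / 2.0, 1e-5)
        t0 = max(-0.75 * math.log1p(-4.0 * d_bc / 3.0) / 2.0, 1.5 * t1)
        start = (0.8 * t1, max(t0 - t1, 0.2 * t1), 0.5 * t1, 0.5 * t1)
    base = np.log(np.maximum(start, 1e-8))
    starts = [base]
    dispersions = [
        np.array([0.5, 1.0, 1.2, 1.2]),
        np.array([-0.5, -1.0, -1.2, 1.5]),
        np.array([0.3, -0.7, 0.8, -0.8]),
        np.array([-0.3, 0.7, -0.8, 0.8]),
    ]
    for d in dispersions[: max(n_starts - 1, 0)]:
        starts.append(base + d)
    return starts


_LOG_LO, _LOG_HI = math.log(1e-8), math.log(10.0)


def ml_msc_fit(
    data,
    tree,
    quad_nodes: int = 32,
    n_starts: int = 3,
    tol: float = 1e-8,
) -> MscFit:
    """Maximize the MSC log-likelihood of one candidate species tree.

    Optimizes over (log tau1, log(tau0 - tau1), log theta0, log theta1),
    which enforces 0 < tau1 < tau0 and positive thetas; coordinates are
    clamped to [1e-8, 10].  Multi-start bounded quasi-Newton; the best
    of ``n_starts`` runs is returned.
    """
    j = _tree_index(tree)
    counts, n = _counts_matrix(data)
    if counts.shape[0] < 1:
        raise ParameterError("need at least one locus")
    if n == 1:
        warnings.warn(
            "n=1 leaves only three free frequencies for four parameters; "
            "the fit is not identifiable",
            stacklevel=2,
        )

    # collapse to unique permuted count rows once; the multinomial
    # coefficient is a data constant, added back after optimization
    x = counts[:, TREE_COUNT_PERMUTATION[j]]
    uniq, inv = np.unique(x, axis=0, return_inverse=True)
    mult = np.bincount(inv, minlength=len(uniq)).astype(float)
    ns = uniq.sum(axis=1)
    logcoef = float(mult @ (gammaln(ns + 1) - gammaln(uniq + 1).sum(axis=1)))

    def nll(z):
        z = np.clip(z, _LOG_LO, _LOG_HI)
        tau1 = math.exp(z[0])
        tau0 = tau1 + math.exp(z[1])
        p = SpeciesTreeParams(
            tau0=tau0, tau1=tau1, theta0=math.exp(z[2]), theta1=math.exp(z[3])
        )
        logp, logw = _quadrature_logp_logw(p, quad_nodes)
        val = -float(mult @ logsumexp(uniq @ logp.T + logw, axis=1))
        return val if np.isfinite(val) else 1e300

    best = None
    bounds = [(_LOG_LO, _LOG_HI)] * 4
    for z0 in _heuristic_starts(data, n_starts):
        res = minimize(
            nll,
            np.clip(z0, _LOG_LO, _LOG_HI),
            method="L-BFGS-B",
            bounds=bounds,
            options=dict(ftol=tol / max(abs(nll(z0)), 1.0), maxiter=500),
        )
        if best is None or res.fun < best.fun:
            best = res
    z = np.clip(best.x, _LOG_LO, _LOG_HI)
    tau1 = math.exp(z[0])
    tau0 = tau1 + math.exp(z[1])
    params_hat = SpeciesTreeParams(
        tau0=tau0, tau1=tau1, theta0=math.exp(z[2]), theta1=math.exp(z[3])
    )
    boundary = bool(np.any(np.isclose(z, _LOG_LO)) or np.any(np.isclose(z, _LOG_HI)))
    return MscFit(
        tree=j,
        params_hat=params_hat,
        loglik=-float(best.fun) + logcoef,
        quad_nodes=quad_nodes,
        converged=bool(best.success),
        boundary=boundary,
        n_starts=n_starts,
        message=str(best.message),
    )


def ml_msc_species_tree(
    data,
    quad_nodes: int = 32,
    n_starts: int = 3,
    tol: float = 1e-8,
    tie_tol: float = ML_TIE_TOL,
) -> SpeciesTreeCall:
    """Full-likelihood species-tree estimate: fit all three trees and
    take the one with the highest maximized log-likelihood.

    Trees within ``tie_tol`` log-likelihood units of the maximum are
    reported as a tie-set.
    """
    fits = [
        ml_msc_fit(data, j, quad_nodes=quad_nodes, n_starts=n_starts, tol=tol)
        for j in (1, 2, 3)
    ]
    support = np.array([f.loglik for f in fits])
    winner, tie = _argmax_call(support, tol=tie_tol)
    return SpeciesTreeCall(
        winner=winner, tie=tie, support=support, method="ml", extras={"fits": fits}
    )


def species_tree_from_true_gene_trees(gts) -> SpeciesTreeCall:
    """ML species tree in the infinite-sites limit, where gene trees and
    coalescent times are known exactly.

    The species tree joining the pair with the smallest coalescent time
    across all loci achieves infinite likelihood (collapsing its
    divergence onto that coalescence), so the estimate is the argmin of
    the per-pair minima; ``support`` holds the negated minima.
    """
    if isinstance(gts, tuple) and len(gts) == 3:
        cls, t1, t0 = (np.asarray(a) for a in gts)
        topo = np.where(cls == 0, 1, cls)  # class codes 0,1 -> topology 1
    else:
        gts = list(gts)
        if not gts:
            raise ParameterError("need at least one gene tree")
        topo = np.array([g.topology for g in gts])
        t1 = np.array([g.t1 for g in gts])
        t0 = np.array([g.t0 for g in gts])
    t_pairs = np.stack(
        [np.where(topo == j, t1, t0) for j in (1, 2, 3)], axis=1
    )  # columns: t_ab, t_bc, t_ca
    minima = t_pairs.min(axis=0)
    winner, tie = _argmax_call(-minima)
    return SpeciesTreeCall(
        winner=winner, tie=tie, support=-minima, method="ml-infinite-sites"
    )
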