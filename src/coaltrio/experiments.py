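"""Replicated-simulation experiment drivers and diagnostics.

Error rates are estimated by simulating R independent multilocus
datasets, applying a species-tree method to each, and counting wrong
calls; tied calls are credited fractionally (a k-way tie containing the
true tree contributes (k-1)/k of an error).  The infinite-sites regime
is handled per method: the two-step vote scores true topologies, the
pooled-count methods average exact per-locus pattern probabilities, and
full ML applies the minimum-coalescent-time rule.

The probit diagnostic regresses Phi^{-1}(error) on sqrt(m); the normal
approximations are exactly affine on that scale, and the simulated
errors follow suit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.stats import linregress, multinomial as multinomial_dist, norm

from .core import (
    ParameterError,
    SpeciesTreeParams,
    gene_tree_topology_probs,
    marginal_pattern_probs,
)
from .error_theory import (
    CovTriple,
    bounds_L1_U1,
    gene_tree_recovery,
    predict_isml_error,
    sigma_infinite,
    sigma_n,
    sigma_one_site,
    zeta_N,
    zeta_multinomial,
)
from .estimators import ml_msc_species_tree
from .simulate import (
    MultilocusDataset,
    sample_counts,
    sample_gene_trees,
    sample_pattern_probs,
)

__all__ = [
    "ErrorEstimate",
    "ProbitFit",
    "exact_error_single_site",
    "probit_linearity",
    "run_error_experiment",
    "table1_report",
]

_METHODS = ("2step", "concat", "isml", "ml")


@dataclass(frozen=True)
class ErrorEstimate:
    """Monte-Carlo species-tree error estimate."""

    method: str
    m: int
    n: float
    R: int
    error: float
    mc_se: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.error <= 1.0:
            raise ParameterError("error must lie in [0, 1]")


@dataclass(frozen=True)
class ProbitFit:
    """Least-squares fit of Phi^{-1}(error) on sqrt(m)."""

    slope: float
    intercept: float
    r_squared: float


def _error_credit(stats: np.ndarray) -> np.ndarray:
    """Fractional error credit per replicate from (R, 3) support stats.

    Strict winner 1 -> 0; k-way tie containing 1 -> (k-1)/k; else 1.
    """
    mx = stats.max(axis=1, keepdims=True)
    is_max = stats == mx
    k = is_max.sum(axis=1)
    credit = np.where(is_max[:, 0], (k - 1) / k, 1.0)
    return credit


def _two_step_votes(counts3: np.ndarray, tie_policy: str, rng) -> np.ndarray:
    """(R, 3) vote totals from (R, m, 3) informative counts."""
    mx = counts3.max(axis=2, keepdims=True)
    is_max = counts3 == mx
    k = is_max.sum(axis=2)
    if tie_policy == "even":
        return (is_max / k[..., None]).sum(axis=1)
    if tie_policy == "drop":
        return np.where(k[..., None] == 1, is_max, 0).sum(axis=1).astype(float)
    if tie_policy == "random":
        r = np.where(is_max, rng.random(is_max.shape), -1.0)
        winner = r.argmax(axis=2)
        votes = np.zeros(counts3.shape[::2])
        for j in range(3):
            votes[:, j] = (winner == j).sum(axis=1)
        return votes
    raise ParameterError(f"unknown tie_policy {tie_policy!r}")


def run_error_experiment(
    method: str,
    params: SpeciesTreeParams,
    m: int,
    n,
    R: int,
    seed: int | np.random.SeedSequence = 0,
    tie_policy: str = "even",
    quad_nodes: int = 32,
    n_starts: int = 2,
) -> ErrorEstimate:
    """Estimate a method's species-tree error from R simulated datasets.

    ``n`` may be 1, a finite integer, or ``math.inf``.  The data are
    always generated with the species tree labelled S1 as truth, so an
    error is any call other than S1 (ties credited fractionally).

    At n = 1 every method reduces exactly to the argmax of pooled
    informative counts, and that shared rule is scored directly.  Full
    ML at finite n > 1 fits all three trees per replicate and is orders
    of magnitude slower than the summary methods; a guard warns for
    large R.
    """
    if method not in _METHODS:
        raise ParameterError(f"method must be one of {_METHODS}")
    if m < 1 or R < 1:
        raise ParameterError("m and R must be >= 1")
    rng = np.random.default_rng(seed)
    infinite = math.isinf(n)

    if not infinite and int(n) == 1:
        # all four methods coincide: argmax of pooled informative counts.
        # The two-step vote is a deterministic function of the pooled
        # counts at n = 1 (even spreading of uninformative-site ties
        # preserves the argmax), so every method scores the same draws.
        pbar = marginal_pattern_probs(params).pbar
        pooled = rng.multinomial(m, pbar, size=R)
        votes = pooled[:, 1:4].astype(float)
        if method == "2step":
            if tie_policy == "even":
                votes = votes + (pooled[:, 0] + pooled[:, 4])[:, None] / 3.0
            elif tie_policy == "random":
                # allocate each unresolved locus's vote uniformly at random
                unresolved = pooled[:, 0] + pooled[:, 4]
                alloc = np.stack(
                    [rng.multinomial(int(u), [1 / 3] * 3) for u in unresolved]
                )
                votes = votes + alloc
        credits = _error_credit(votes)
    elif infinite:
        credits = _infinite_sites_credits(method, params, m, R, rng, tie_policy)
    elif method in ("concat", "isml", "2step"):
        credits = np.empty(R)
        done = 0
        chunk = max(1, 2_000_000 // max(m, 1))
        while done < R:
            size = min(R - done, chunk)
            counts = sample_counts(params, size * m, int(n), rng).reshape(size, m, 5)
            if method == "2step":
                votes = _two_step_votes(counts[:, :, 1:4], tie_policy, rng)
            else:
                votes = counts[:, :, 1:4].sum(axis=1).astype(float)
            credits[done : done + size] = _error_credit(votes)
            done += size
    else:  # full ML at finite n > 1
        if R * m * int(n) > 5e7:
            warnings.warn(
                "full-ML error experiment at this scale will be very slow; "
                "consider reducing R", stacklevel=2,
            )
        credits = np.empty(R)
        for r in range(R):
            counts = sample_counts(params, m, int(n), rng)
            call = ml_msc_species_tree(
                MultilocusDataset(n=int(n), counts=counts),
                quad_nodes=quad_nodes, n_starts=n_starts,
            )
            k = len(call.tie)
            credits[r] = (k - 1) / k if 1 in call.tie else 1.0

    error = float(credits.mean())
    mc_se = float(math.sqrt(max(error * (1.0 - error), 1e-300) / R))
    return ErrorEstimate(
        method=method, m=m, n=n, R=R, error=error, mc_se=mc_se,
        seed=seed if isinstance(seed, int) else None,
    )


def _infinite_sites_credits(method, params, m, R, rng, tie_policy) -> np.ndarray:
    if method == "2step":
        # estimated gene trees are the true topologies
        g = gene_tree_topology_probs(params)
        votes = rng.multinomial(m, g, size=R).astype(float)
        return _error_credit(votes)
    credits = np.empty(R)
    done = 0
    chunk = max(1, 2_000_000 // max(m, 1))
    while done < R:
        size = min(R - done, chunk)
        if method in ("concat", "isml"):
            probs = sample_pattern_probs(params, size * m, rng)
            fbar = probs.reshape(size, m, 5)[:, :, 1:4].mean(axis=1)
            credits[done : done + size] = _error_credit(fbar)
        else:  # ml: minimum-coalescent-time rule
            cls, t1, t0 = sample_gene_trees(params, size * m, rng)
            topo = np.where(cls == 0, 1, cls).reshape(size, m)
            t1 = t1.reshape(size, m)
            t0 = t0.reshape(size, m)
            t_pairs = np.stack(
                [np.where(topo == j, t1, t0).min(axis=1) for j in (1, 2, 3)], axis=1
            )
            credits[done : done + size] = _error_credit(-t_pairs)
        done += size
    return credits


def probit_linearity(estimates) -> ProbitFit:
    """Fit Phi^{-1}(error) against sqrt(m) by least squares.

    Points with error exactly 0 or 1 are excluded with a warning (the
    probit is infinite there); at least three usable points required.
    """
    pts = [(e.m, e.error) for e in estimates]
    usable = [(m, e) for m, e in pts if 0.0 < e < 1.0]
    if len(usable) < len(pts):
        warnings.warn(f"excluded {len(pts) - len(usable)} degenerate error points")
    if len(usable) < 3:
        raise ParameterError("need at least 3 points with error strictly in (0, 1)")
    x = np.sqrt([m for m, _ in usable])
    y = norm.ppf([e for _, e in usable])
    res = linregress(x, y)
    return ProbitFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def exact_error_single_site(params: SpeciesTreeParams, m: int) -> float:
    """Exact species-tree error at n = 1 by complete enumeration.

    At one site per locus the pooled counts are multinomial(m, pbar) and
    every method reduces to their informative argmax; the error is the
    exact sum of outcome probabilities weighted by fractional tie
    credit.  Feasible for small m (the outcome count grows as m^4).
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    pbar = marginal_pattern_probs(params).pbar
    total = 0.0
    # enumerate counts over the 5 categories summing to m
    for bars in combinations_with_replacement(range(m + 1), 4):
        x = np.diff((0, *bars, m))
        stats = x[1:4]
        top = stats.max()
        tie = np.flatnonzero(stats == top)
        credit = 1.0 if 0 not in tie else (len(tie) - 1) / len(tie)
        if credit:
            total += credit * multinomial_dist.pmf(x, n=m, p=pbar)
    return float(total)


def table1_report(
    params: SpeciesTreeParams,
    m: int = 1000,
    n_values=(1, 2, 10, 100, 1000, math.inf),
    R_summary: int = 100_000,
    R_recovery: int = 1_000_000,
    R_cov: int = 1_000_000,
    seed: int = 0,
    simulate: bool = True,
) -> pd.DataFrame:
    """Tabulate gene-tree recovery probabilities, simulated errors, and
    the analytic error approximations across sequence lengths.

    Columns are sequence lengths; rows mirror the standard comparison
    grid: tie probability, (g1, g2), simulated two-step and isml errors,
    the zeta/zeta_N approximations, the (zetaL1, zetaU1) bounds and
    their (a, b) ingredients for both methods.  ``simulate=False`` skips
    the Monte-Carlo error rows.  Deterministic given the seed.
    """
    ss = np.random.SeedSequence(seed)
    pbar = marginal_pattern_probs(params).pbar
    Sigma1 = sigma_one_site(pbar)
    dmu = float(pbar[1] - pbar[2])
    SigmaInf = sigma_infinite(params, R=R_cov, seed=ss.spawn(1)[0])
    rows: dict[str, dict] = {}
    for n in n_values:
        child = ss.spawn(1)[0]
        rec = gene_tree_recovery(params, n, R=R_recovery, seed=child)
        cov2 = CovTriple.from_multinomial(rec.g1, rec.g2)
        b2 = bounds_L1_U1(m, cov2)
        Sn = Sigma1 if (not math.isinf(n) and n == 1) else sigma_n(Sigma1, SigmaInf, n)
        covi = CovTriple.from_matrix(dmu, Sn)
        bi = bounds_L1_U1(m, covi)
        covi0 = CovTriple(
            sigma1_sq=covi.sigma1_sq, sigma2_sq=covi.sigma2_sq,
            sigma12=0.0, sigma23=0.0, dmu=dmu,
        )
        col = {
            "P(tie)": rec.p_tie,
            "g1(n)": rec.g1,
            "g2(n)": rec.g2,
            "zeta(m,g1,g2)": zeta_multinomial(m, rec.g1, rec.g2),
            "2step zetaL1": b2.zetaL1,
            "2step zetaU1": b2.zetaU1,
            "2step a": b2.a,
            "2step b": b2.b,
            "isml zetaN": zeta_N(m, covi),
            "isml zetaN0": zeta_N(m, covi0),
            "isml zetaL1": bi.zetaL1,
            "isml zetaU1": bi.zetaU1,
            "isml a": bi.a,
            "isml b": bi.b,
        }
        if simulate:
            e2 = run_error_experiment(
                "2step", params, m, n, R=R_summary, seed=ss.spawn(1)[0]
            )
            ei = run_error_experiment(
                "isml", params, m, n, R=R_summary, seed=ss.spawn(1)[0]
            )
            col["e_2step (sim)"] = e2.error
            col["e_isml (sim)"] = ei.error
        rows[("inf" if math.isinf(n) else int(n))] = col
    df = pd.DataFrame(rows)
    df.columns.name = "n"
    return df
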