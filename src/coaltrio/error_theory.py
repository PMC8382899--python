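"""Analytic approximations to the species-tree estimation error.

The central object is the error probability of an argmax rule over an
exchangeable triple of locus-averaged statistics (vote shares, pooled
pattern frequencies, per-locus log-likelihoods).  A normal
approximation gives

    zeta_N = Phi( (-dmu sqrt(m) + sqrt((s2^2 - s23)/pi))
                  / sqrt(s1^2 - 2 s12 + s2^2 - (s2^2 - s23)/pi) )

together with lower/upper bounds zetaL1 <= zeta < zetaU1 = 2 Phi(-h).
Multinomial specializations cover the two-step vote and the pooled
pattern counts; the mixed-n covariance of per-locus pattern frequencies
combines the single-site multinomial covariance with the
coalescent-fluctuation covariance of the exact per-locus pattern
probabilities.  For the full-likelihood method the same normal
machinery applies to per-locus log-likelihoods at pseudotrue
parameters, with the Kullback-Leibler divergence as the mean separation;
and at infinite sequence length the error is exact:
e = phi^m * 2/3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .core import (
    ParameterError,
    SpeciesTreeParams,
    gene_tree_topology_probs,
    marginal_pattern_probs,
)
from .estimators import ml_msc_fit, msc_loglik
from .simulate import sample_counts, sample_dataset, sample_pattern_probs

__all__ = [
    "BoundsResult",
    "CovTriple",
    "ErrorPrediction",
    "GeneTreeRecovery",
    "KlSummary",
    "PatternCov",
    "bounds_L1_U1",
    "gene_tree_recovery",
    "kl_predict_ml_error",
    "ml_error_infinite_n",
    "pattern_cov",
    "predict_isml_error",
    "predict_two_step_error",
    "sigma_infinite",
    "sigma_n",
    "sigma_one_site",
    "zeta_N",
    "zeta_multinomial",
    "zeta_zly",
]


@dataclass(frozen=True)
class CovTriple:
    """Covariance structure of the exchangeable triple (z1, z2, z3).

    The statistic supporting the true tree has variance ``sigma1_sq``;
    the two mismatching statistics share variance ``sigma2_sq``,
    covariance ``sigma23`` with each other and ``sigma12`` with the
    first.  ``dmu`` is the mean separation mu1 - mu2.
    """

    sigma1_sq: float
    sigma2_sq: float
    sigma12: float
    sigma23: float
    dmu: float

    def __post_init__(self) -> None:
        if self.sigma1_sq <= 0:
            raise ParameterError("sigma1_sq must be positive")
        if self.sigma2_sq < self.sigma23:
            raise ParameterError("require sigma2_sq >= sigma23")
        if min(np.linalg.eigvalsh(self.matrix())) < -1e-10:
            raise ParameterError("implied covariance matrix is not PSD")

    def matrix(self) -> np.ndarray:
        s1, s2, s12, s23 = self.sigma1_sq, self.sigma2_sq, self.sigma12, self.sigma23
        return np.array([[s1, s12, s12], [s12, s2, s23], [s12, s23, s2]])

    @classmethod
    def from_multinomial(cls, q1: float, q2: float) -> "CovTriple":
        """Trinomial covariance with category probabilities (q1, q2, q2)."""
        if not (0.0 < q2 < q1 and q1 + 2.0 * q2 <= 1.0 + 1e-12):
            raise ParameterError("require 0 < q2 < q1 and q1 + 2 q2 <= 1")
        return cls(
            sigma1_sq=q1 * (1.0 - q1),
            sigma2_sq=q2 * (1.0 - q2),
            sigma12=-q1 * q2,
            sigma23=-q2 * q2,
            dmu=q1 - q2,
        )

    @classmethod
    def from_matrix(cls, dmu: float, Sigma: np.ndarray) -> "CovTriple":
        """Symmetrize an empirical 3x3 covariance into the exchangeable form."""
        Sigma = np.asarray(Sigma, dtype=float)
        return cls(
            sigma1_sq=Sigma[0, 0],
            sigma2_sq=0.5 * (Sigma[1, 1] + Sigma[2, 2]),
            sigma12=0.5 * (Sigma[0, 1] + Sigma[0, 2]),
            sigma23=Sigma[1, 2],
            dmu=dmu,
        )


@dataclass(frozen=True)
class BoundsResult:
    """Analytic argmax-error bounds: zetaL1 <= zeta < zetaU1 = 2 Phi(-h)."""

    s1_sq: float
    s2_sq: float
    a: float
    b: float
    h: float
    zetaL1: float
    zetaU1: float


@dataclass(frozen=True)
class PatternCov:
    """Covariances of the informative-pattern frequencies (f1, f2, f3)
    at n = 1 (multinomial), n = inf (coalescent fluctuation, Monte
    Carlo), and their mixed-n combination."""

    Sigma1: np.ndarray
    SigmaInf: np.ndarray
    SigmaN: np.ndarray
    n: float
    R: int
    se: float


@dataclass(frozen=True)
class GeneTreeRecovery:
    """Probabilities that the estimated gene tree at one locus of n
    sites is G1/G2/G3, plus the tie (unresolved) probability."""

    g1: float
    g2: float
    g3: float
    p_tie: float
    mode: str
    n: float
    R: int = 0
    seed: int | None = None
    se: float = 0.0


@dataclass(frozen=True)
class KlSummary:
    """Kullback-Leibler separations and per-locus log-likelihood moments
    at the pseudotrue parameters of the two mismatching trees."""

    D12: float
    D13: float
    mu: np.ndarray
    Sigma: np.ndarray
    pseudotrue2: SpeciesTreeParams
    pseudotrue3: SpeciesTreeParams


@dataclass(frozen=True)
class ErrorPrediction:
    """A predicted species-tree error probability."""

    method: str
    m: int
    n: float
    value: float
    flavor: str


def zeta_N(m: int, cov: CovTriple) -> float:
    """Normal approximation to P(z1_bar < max(z2_bar, z3_bar)).

    The max of the two exchangeable mismatching statistics contributes
    the sqrt((sigma2^2 - sigma23)/pi) mean shift and the matching
    variance reduction in the denominator.
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    gap = cov.sigma2_sq - cov.sigma23
    num = -cov.dmu * math.sqrt(m) + math.sqrt(gap / math.pi)
    den_sq = cov.sigma1_sq - 2.0 * cov.sigma12 + cov.sigma2_sq - gap / math.pi
    if den_sq <= 0:
        raise ParameterError("degenerate covariance: nonpositive denominator")
    return float(norm.cdf(num / math.sqrt(den_sq)))


def zeta_multinomial(m: int, q1: float, q2: float) -> float:
    """Multinomial specialization of :func:`zeta_N`: the error of the
    argmax of trinomial counts with cell probabilities (q1, q2, q2)."""
    if not (0.0 < q2 < q1 and q1 + 2.0 * q2 <= 1.0 + 1e-12):
        raise ParameterError("require 0 < q2 < q1 and q1 + 2 q2 <= 1")
    if m < 1:
        raise ParameterError("m must be >= 1")
    dq = q1 - q2
    num = -dq * math.sqrt(m) + math.sqrt(q2 / math.pi)
    den = math.sqrt(q1 + q2 - dq * dq - q2 / math.pi)
    return float(norm.cdf(num / den))


#: Reference values of the discontinuity-corrected approximation for the
#: two-step method at m=1000 on the standard parameter set, at
#: n = (10, 100, 1000, inf).  Retained as comparison data only: the
#: historically proposed algebraic form is ambiguous and no parse we tried
#: reproduces all four values (see zeta_zly).
ZLY_REFERENCE_TWO_STEP_M1000 = {10: 0.613, 100: 0.482, 1000: 0.271, math.inf: 0.117}


def zeta_zly(m: int, q1: float, q2: float) -> float:
    """Discontinuity-corrected variant of :func:`zeta_multinomial`
    (experimental).

    The correction subtracts 1/(dq*m) from the mean separation and drops
    the correlation terms from the denominator.  Returns ``nan`` with a
    warning when the correction exceeds the separation itself
    (m dq^2 <= 1), where the form is inapplicable.  The exact algebraic
    form of this correction is not settled; the function is retained for
    comparison only and is never used as a default predictor.
    """
    if not (0.0 < q2 < q1 and q1 + 2.0 * q2 <= 1.0 + 1e-12):
        raise ParameterError("require 0 < q2 < q1 and q1 + 2 q2 <= 1")
    dq = q1 - q2
    warnings.warn(
        "zeta_zly is experimental: the discontinuity-corrected form is "
        "not settled; prefer zeta_multinomial",
        stacklevel=2,
    )
    if m * dq * dq <= 1.0:
        return math.nan
    num = -(dq - 1.0 / (m * dq)) * math.sqrt(m) + math.sqrt(q2 / math.pi)
    den = math.sqrt(q1 + q2 - q2 / math.pi)
    return float(norm.cdf(num / den))


def bounds_L1_U1(m: int, cov: CovTriple) -> BoundsResult:
    """Lower and upper bounds on the argmax error probability.

    With s2^2 = (sigma2^2 - sigma23)/2,
    s1^2 = sigma1^2 - 2 sigma12 + sigma2^2 - s2^2, a = s2/s1,
    b = dmu sqrt(m)/s1 and h = b/sqrt(1 + a^2):

        zetaL1 = Phi(-h) (1 + (2/pi) arctan a),   zetaU1 = 2 Phi(-h).
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    s2_sq = 0.5 * (cov.sigma2_sq - cov.sigma23)
    s1_sq = cov.sigma1_sq - 2.0 * cov.sigma12 + cov.sigma2_sq - s2_sq
    if s1_sq <= 0:
        raise ParameterError("degenerate covariance: s1^2 <= 0")
    a = math.sqrt(s2_sq / s1_sq)
    b = cov.dmu * math.sqrt(m) / math.sqrt(s1_sq)
    h = b / math.sqrt(1.0 + a * a)
    phi_mh = float(norm.cdf(-h))
    return BoundsResult(
        s1_sq=s1_sq,
        s2_sq=s2_sq,
        a=a,
        b=b,
        h=h,
        zetaL1=phi_mh * (1.0 + 2.0 / math.pi * math.atan(a)),
        zetaU1=2.0 * phi_mh,
    )


def sigma_one_site(pbar) -> np.ndarray:
    """Multinomial(1) covariance of the informative-pattern frequencies:
    sigma_jj = pbar_j (1 - pbar_j), sigma_jk = -pbar_j pbar_k."""
    p = np.asarray(pbar, dtype=float)
    if p.shape != (5,) or np.any(p < 0):
        raise ParameterError("pbar must be a 5-vector of probabilities")
    q = p[1:4]
    out = -np.outer(q, q)
    np.fill_diagonal(out, q * (1.0 - q))
    return out




def sigma_infinite(
    params: SpeciesTreeParams,
    R: int = 1_000_000,
    seed: int | np.random.SeedSequence = 20210125,
    return_se: bool = False,
):
    """Monte-Carlo covariance of the exact per-locus informative pattern
    probabilities (p_i1, p_i2, p_i3) over the coalescent process.

    This is the infinite-sites covariance of per-locus pattern
    frequencies: a 4-component mixture over the gene-tree classes.
    ``return_se`` adds a scalar batch-means standard error summary for
    the covariance entries.
    """
    if R < 10_000:
        raise ParameterError("R must be >= 10^4 for a stable covariance")
    rng = np.random.default_rng(seed)
    probs = sample_pattern_probs(params, R, rng)[:, 1:4]
    Sigma = np.cov(probs.T)
    if not return_se:
        return Sigma
    nb = 10
    batches = np.array_split(probs, nb)
    mats = np.array([np.cov(b.T) for b in batches])
    se = float(mats.std(axis=0).max() / math.sqrt(nb))
    return Sigma, se


def sigma_n(Sigma1: np.ndarray, SigmaInf: np.ndarray, n) -> np.ndarray:
    """Mixed-n covariance: (1/n) Sigma(1) + ((n-1)/n) Sigma(inf)."""
    if not math.isinf(n) and n < 1:
        raise ParameterError("n must be >= 1")
    if math.isinf(n):
        return np.asarray(SigmaInf, dtype=float)
    return np.asarray(Sigma1) / n + (n - 1.0) / n * np.asarray(SigmaInf)


def pattern_cov(
    params: SpeciesTreeParams,
    n,
    R: int = 1_000_000,
    seed: int | np.random.SeedSequence = 20210125,
) -> PatternCov:
    """Bundle Sigma(1), Sigma(inf) and Sigma(n) for the parameters."""
    pbar = marginal_pattern_probs(params).pbar
    Sigma1 = sigma_one_site(pbar)
    SigmaInf, se = sigma_infinite(params, R=R, seed=seed, return_se=True)
    return PatternCov(
        Sigma1=Sigma1, SigmaInf=SigmaInf, SigmaN=sigma_n(Sigma1, SigmaInf, n),
        n=n, R=R, se=se,
    )


def gene_tree_recovery(
    params: SpeciesTreeParams,
    n,
    R: int = 1_000_000,
    seed: int | np.random.SeedSequence = 20210125,
) -> GeneTreeRecovery:
    """Probabilities (g1, g2, g3) of the estimated (count-rule) gene tree
    at sequence length n, with the tie probability.

    Exact at n = 1 (a single site resolves the gene tree only if it is
    informative) and at n = inf (the estimated gene tree is the true
    topology); Monte Carlo with R simulated loci otherwise.  For finite
    n, g1 < P(G1): phylogenetic error inflates apparent discordance.
    """
    if math.isinf(n):
        g = gene_tree_topology_probs(params)
        return GeneTreeRecovery(
            g1=float(g[0]), g2=float(g[1]), g3=float(g[2]), p_tie=0.0,
            mode="exact-inf", n=n,
        )
    n = int(n)
    if n < 1:
        raise ParameterError("n must be >= 1")
    if n == 1:
        pbar = marginal_pattern_probs(params).pbar
        return GeneTreeRecovery(
            g1=float(pbar[1]), g2=float(pbar[2]), g3=float(pbar[3]),
            p_tie=float(pbar[0] + pbar[4]), mode="exact-n1", n=1,
        )
    rng = np.random.default_rng(seed)
    wins = np.zeros(3)
    ties = 0
    done = 0
    chunk = max(1, min(R, 4_000_000 // max(n, 1) + 1))
    while done < R:
        size = min(chunk, R - done)
        counts = sample_counts(params, size, n, rng)[:, 1:4]
        mx = counts.max(axis=1, keepdims=True)
        is_max = counts == mx
        strict = is_max.sum(axis=1) == 1
        wins += is_max[strict].sum(axis=0)
        ties += int((~strict).sum())
        done += size
    g = wins / R
    se = float(np.sqrt(g.max() * (1 - g.max()) / R))
    return GeneTreeRecovery(
        g1=float(g[0]), g2=float(g[1]), g3=float(g[2]), p_tie=ties / R,
        mode="monte-carlo", n=n, R=R, se=se,
        seed=seed if isinstance(seed, int) else None,
    )


def predict_two_step_error(
    params: SpeciesTreeParams,
    m: int,
    n,
    R: int = 1_000_000,
    seed: int | np.random.SeedSequence = 20210125,
) -> ErrorPrediction:
    """Predicted two-step (majority-vote) error: zeta(m, g1, g2) with the
    estimated-gene-tree probabilities at sequence length n."""
    rec = gene_tree_recovery(params, n, R=R, seed=seed)
    value = zeta_multinomial(m, rec.g1, rec.g2)
    return ErrorPrediction(method="2step", m=m, n=n, value=value, flavor="zeta")


def predict_isml_error(
    params: SpeciesTreeParams,
    m: int,
    n,
    R: int = 1_000_000,
    seed: int | np.random.SeedSequence = 20210125,
    correlations: bool = True,
) -> ErrorPrediction:
    """Predicted isml/concatenation error: zeta_N at the marginal-pattern
    mean separation with the mixed-n frequency covariance.

    ``correlations=False`` zeroes sigma12 and sigma23 (the "no
    correlation" variant, less accurate at large n).
    """
    pbar = marginal_pattern_probs(params).pbar
    Sigma1 = sigma_one_site(pbar)
    if math.isinf(n) or n > 1:
        SigmaInf = sigma_infinite(params, R=R, seed=seed)
        Sigma = sigma_n(Sigma1, SigmaInf, n)
    else:
        Sigma = Sigma1
    cov = CovTriple.from_matrix(dmu=float(pbar[1] - pbar[2]), Sigma=Sigma)
    if not correlations:
        cov = CovTriple(
            sigma1_sq=cov.sigma1_sq, sigma2_sq=cov.sigma2_sq,
            sigma12=0.0, sigma23=0.0, dmu=cov.dmu,
        )
    return ErrorPrediction(
        method="isml", m=m, n=n, value=zeta_N(m, cov),
        flavor="zetaN" if correlations else "zetaN0",
    )


def ml_error_infinite_n(params: SpeciesTreeParams, m: int) -> ErrorPrediction:
    """Exact ML species-tree error at infinite sequence length.

    The ML tree is wrong only if the ingroup pair fails to coalesce in
    its own ancestral population at every locus (probability phi^m) and
    is not the first pair to coalesce in the root (probability 2/3):
    e = phi^m * 2/3, exact for every m.
    """
    if m < 0:
        raise ParameterError("m must be >= 0")
    return ErrorPrediction(
        method="ml", m=m, n=math.inf,
        value=params.phi ** m * 2.0 / 3.0, flavor="exact-eq12",
    )


def kl_predict_ml_error(
    params: SpeciesTreeParams,
    n: int,
    m: int,
    R: int = 4000,
    seed: int = 20210125,
    m_ref: int = 2000,
    quad_nodes: int = 32,
    n_starts: int = 2,
) -> tuple[ErrorPrediction, KlSummary]:
    """Predicted full-ML error via the Kullback-Leibler machinery.

    Estimates the pseudotrue parameters of the two mismatching trees by
    maximizing their likelihood on a large reference sample (m_ref
    loci), then Monte-Carlo estimates the per-locus log-likelihood
    moments (means and 3x3 covariance) at the pseudotrue points from R
    fresh loci, and feeds the separation D12 = mu1 - mu2 and the
    covariance into zeta_N.  Research-grade: the moments are not
    available in closed form.
    """
    if n < 2:
        warnings.warn("n >= 2 recommended: the model is not identifiable at n = 1")
    ss = np.random.SeedSequence(seed)
    ss_ref, ss_mc = ss.spawn(2)
    ref = sample_dataset(params, m_ref, n, ss_ref)
    fit2 = ml_msc_fit(ref, 2, quad_nodes=quad_nodes, n_starts=n_starts)
    fit3 = ml_msc_fit(ref, 3, quad_nodes=quad_nodes, n_starts=n_starts)
    fresh = sample_dataset(params, R, n, ss_mc)
    l1 = msc_loglik(fresh, 1, params, quad_nodes=quad_nodes, per_locus=True)
    l2 = msc_loglik(fresh, 2, fit2.params_hat, quad_nodes=quad_nodes, per_locus=True)
    l3 = msc_loglik(fresh, 3, fit3.params_hat, quad_nodes=quad_nodes, per_locus=True)
    L = np.stack([l1, l2, l3])
    mu = L.mean(axis=1)
    Sigma = np.cov(L)
    summary = KlSummary(
        D12=float(mu[0] - mu[1]), D13=float(mu[0] - mu[2]), mu=mu, Sigma=Sigma,
        pseudotrue2=fit2.params_hat, pseudotrue3=fit3.params_hat,
    )
    cov = CovTriple.from_matrix(dmu=float(mu[0] - mu[1]), Sigma=Sigma)
    pred = ErrorPrediction(
        method="ml", m=m, n=n, value=zeta_N(m, cov), flavor="kl-mc"
    )
    return pred, summary
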