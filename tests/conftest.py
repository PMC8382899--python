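"""Shared fixtures: reference parameter sets and independent oracles.

The oracles are deliberately written with different machinery than the
package (brute-force enumeration, adaptive integration, direct
optimization of the closed-form marginal) so that agreement is a real
cross-check rather than a tautology.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.optimize import minimize
from scipy.special import gammaln

import coaltrio as ct

SEED = 20210125


@pytest.fixture(scope="session")
def std_params() -> ct.SpeciesTreeParams:
    """The challenging reference species tree used throughout: shallow
    divergences, small root population, large internal population."""
    return ct.SpeciesTreeParams(tau0=0.02, tau1=0.019, theta0=0.01, theta1=0.05)


@pytest.fixture(scope="session")
def deep_params() -> ct.SpeciesTreeParams:
    """The parameter set used for the concatenation-bias experiments."""
    return ct.SpeciesTreeParams(tau0=0.02, tau1=0.01, theta0=0.02, theta1=0.01)


@pytest.fixture(scope="session")
def jc_enumeration_oracle():
    """Brute-force site-pattern probabilities for a rooted triplet
    ((a,b),c) with node ages (t0, t1) under JC.

    Enumerates the 4^3 tip-base assignments against 4x4 JC transition
    matrices on the four branches, summing over root and internal node
    states.  Completely independent of the closed form.
    """

    def transition(t: float) -> np.ndarray:
        same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
        diff = 0.25 - 0.25 * math.exp(-4.0 * t / 3.0)
        return np.where(np.eye(4, dtype=bool), same, diff)

    def oracle(t0: float, t1: float) -> np.ndarray:
        p_int = transition(t0 - t1)  # root -> internal node
        p_tip1 = transition(t1)      # internal -> a, b
        p_tip0 = transition(t0)      # root -> c
        probs = np.zeros(5)
        for a, b, c in itertools.product(range(4), repeat=3):
            mass = 0.0
            for r in range(4):
                for s in range(4):
                    mass += (
                        0.25 * p_int[r, s] * p_tip1[s, a] * p_tip1[s, b] * p_tip0[r, c]
                    )
            if a == b == c:
                probs[0] += mass
            elif a == b:
                probs[1] += mass
            elif b == c:
                probs[2] += mass
            elif a == c:
                probs[3] += mass
            else:
                probs[4] += mass
        return probs

    return oracle


@pytest.fixture(scope="session")
def adaptive_loglik_oracle():
    """Per-locus MSC log-likelihood by adaptive 2-D integration.

    Sums the four gene-tree classes, integrating the joint density of
    (t1, t0) times the multinomial pattern probability with
    scipy.integrate.dblquad.  The integrand is rescaled to order one so
    the adaptive tolerance is effectively relative.
    """

    def oracle(x: np.ndarray, params: ct.SpeciesTreeParams, scale_hint: float) -> float:
        tau0, tau1, th0, th1 = params.astuple()
        phi = params.phi
        x = np.asarray(x)

        def weighted(t0, t1, xp, dens):
            p = ct.conditional_pattern_probs(t0, t1)
            return dens * math.exp(float(xp @ np.log(p)) - scale_hint)

        def g1a(t0, t1):
            dens = (
                (2 / th1) * math.exp(-(2 / th1) * (t1 - tau1))
                * (2 / th0) * math.exp(-(2 / th0) * (t0 - tau0))
            )
            return weighted(t0, t1, x, dens)

        hi = tau0 + 3.0  # ~e^{-600} tail mass at theta ~ 0.01
        total, _ = integrate.dblquad(
            g1a, tau1, tau0, lambda t1: tau0, lambda t1: hi,
            epsabs=1e-300, epsrel=1e-11,
        )
        for perm in [(0, 1, 2, 3, 4), (0, 2, 1, 3, 4), (0, 3, 2, 1, 4)]:
            xp = x[list(perm)]

            def other(t0, t1, xp=xp):
                dens = (
                    phi * (2 / th0) * (2 / th0)
                    * math.exp(-(6 / th0) * (t1 - tau0))
                    * math.exp(-(2 / th0) * (t0 - t1))
                )
                return weighted(t0, t1, xp, dens)

            v, _ = integrate.dblquad(
                other, tau0, hi, lambda t1: t1, lambda t1: t1 + 3.0,
                epsabs=1e-300, epsrel=1e-11,
            )
            total += v
        logcoef = float(gammaln(x.sum() + 1) - gammaln(x + 1).sum())
        return math.log(total) + scale_hint + logcoef

    return oracle


@pytest.fixture(scope="session")
def pooled_ml_oracle():
    """Maximized pooled-multinomial log-likelihood for one species tree
    by direct optimization over the marginal-pattern parameter space.

    Multi-start Nelder-Mead over (log tau1, log dtau, log theta0,
    log theta1), evaluating the closed-form marginal pattern
    probabilities; used to verify that the pooled-count argmax equals
    the argmax of maximized likelihoods.
    """

    def fit_one(pooled: np.ndarray) -> float:
        def nll(z):
            z = np.clip(z, -30.0, 3.0)
            tau1 = math.exp(z[0])
            tau0 = tau1 + math.exp(z[1])
            try:
                params = ct.SpeciesTreeParams(
                    tau0=tau0, tau1=tau1,
                    theta0=math.exp(z[2]), theta1=math.exp(z[3]),
                )
            except ct.ParameterError:
                return 1e300
            pbar = ct.marginal_pattern_probs(params).pbar
            with np.errstate(divide="ignore"):
                val = -float(pooled @ np.log(pbar))
            return val if np.isfinite(val) else 1e300

        best = math.inf
        for z0 in (
            np.log([0.02, 0.005, 0.02, 0.02]),
            np.log([0.1, 0.1, 0.005, 0.005]),
            np.log([0.01, 0.05, 0.1, 0.01]),
        ):
            res = minimize(
                nll, z0, method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-12, maxiter=4000, maxfev=4000),
            )
            best = min(best, res.fun)
        return -best

    def oracle(pooled: np.ndarray) -> np.ndarray:
        """Maximized log-likelihood for each of the three species trees."""
        perms = {1: (0, 1, 2, 3, 4), 2: (0, 2, 1, 3, 4), 3: (0, 3, 2, 1, 4)}
        pooled = np.asarray(pooled, dtype=float)
        return np.array([fit_one(pooled[list(perms[j])]) for j in (1, 2, 3)])

    return oracle
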