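"""Closed-form probability machinery for the three-species MSC + JC model.

For three species A, B, C related by a rooted species tree under the
molecular clock, the multispecies coalescent (MSC) describes the gene
tree (topology and coalescent times) at each locus, and the Jukes-Cantor
(JC) substitution model describes the sequence data given the gene tree.
All ages and population-size parameters are measured in expected
substitutions per site; for a population, theta = 4*N*mu.

Site patterns across the three sequences (a, b, c) collapse under JC
symmetry into five classes, fixed throughout the package in the order

    index 0: xxx   (constant)
    index 1: xxy   (a = b != c; supports gene tree G1 = ((ab)c))
    index 2: yxx   (b = c != a; supports G2 = ((bc)a))
    index 3: xyx   (a = c != b; supports G3 = ((ca)b))
    index 4: xyz   (three distinct bases)

where x, y, z denote distinct nucleotides.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PATTERN_NAMES: tuple[str, ...] = ("xxx", "xxy", "yxx", "xyx", "xyz")
GENE_TREE_CLASSES: tuple[str, ...] = ("G1a", "G1b", "G2", "G3")
SPECIES_TREES: tuple[str, ...] = ("S1", "S2", "S3")

#: topology index (1, 2 or 3) of each gene-tree class
CLASS_TOPOLOGY: dict[str, int] = {"G1a": 1, "G1b": 1, "G2": 2, "G3": 3}

PROB_SUM_TOL = 1e-12


class ParameterError(ValueError):
    """Raised when MSC parameters violate their domain."""


@dataclass(frozen=True)
class SpeciesTreeParams:
    """A labelled rooted triplet species tree with its MSC parameters.

    Parameters
    ----------
    tau0 : float
        Age of the root divergence (expected substitutions per site).
    tau1 : float
        Age of the internal divergence, 0 < tau1 <= tau0.  Equality is
        admitted as the degenerate star-tree boundary (phi = 1).
    theta0 : float
        Population-size parameter of the root ancestral population.
    theta1 : float
        Population-size parameter of the internal ancestral population.
    label : str
        Which of the three species trees the parameters belong to; the
        labelling is by symmetry and does not enter any formula.
    """

    tau0: float
    tau1: float
    theta0: float
    theta1: float
    label: str = "S1"

    def __post_init__(self) -> None:
        if not (self.tau1 > 0.0 and self.tau0 >= self.tau1):
            raise ParameterError(
                f"require 0 < tau1 <= tau0, got tau0={self.tau0}, tau1={self.tau1}"
            )
        if not (self.theta0 > 0.0 and self.theta1 > 0.0):
            raise ParameterError(
                f"require theta0, theta1 > 0, got {self.theta0}, {self.theta1}"
            )
        if self.label not in SPECIES_TREES:
            raise ParameterError(f"label must be one of {SPECIES_TREES}")

    @property
    def phi(self) -> float:
        """Probability the two ingroup lineages fail to coalesce in their
        ancestral population: exp(-2 (tau0 - tau1) / theta1)."""
        return math.exp(-2.0 * (self.tau0 - self.tau1) / self.theta1)

    @property
    def internal_branch_coalescent_units(self) -> float:
        """Internal branch length 2 (tau0 - tau1) / theta1 in coalescent units."""
        return 2.0 * (self.tau0 - self.tau1) / self.theta1

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.tau0, self.tau1, self.theta0, self.theta1)

    @classmethod
    def from_mapping(cls, mapping: dict, label: str = "S1") -> "SpeciesTreeParams":
        return cls(
            tau0=float(mapping["tau0"]),
            tau1=float(mapping["tau1"]),
            theta0=float(mapping["theta0"]),
            theta1=float(mapping["theta1"]),
            label=str(mapping.get("label", label)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesTreeParams":
        """Read parameters from a plain-text config.

        Accepts either JSON (``{"tau0": ..., ...}``) or simple
        ``key = value`` lines with keys tau0, tau1, theta0, theta1.
        """
        text = Path(path).read_text()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            return cls.from_mapping(json.loads(text))
        mapping: dict[str, str] = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, _, value = line.partition("=")
            elif ":" in line:
                key, _, value = line.partition(":")
            else:
                raise ParameterError(f"cannot parse config line: {line!r}")
            mapping[key.strip()] = value.strip()
        return cls.from_mapping(mapping)


@dataclass(frozen=True)
class GeneTreeSample:
    """One locus's gene tree: class (G1a, G1b, G2, G3) and node ages.

    t1 is the first (more recent) coalescent time and t0 the root
    coalescent time, both in expected substitutions per site.  For class
    G1a the first coalescence happens in the internal ancestral
    population (tau1 < t1 < tau0 < t0); for the other three classes all
    coalescences happen in the root population (tau0 < t1 < t0).
    """

    cls: str
    t1: float
    t0: float

    def __post_init__(self) -> None:
        if self.cls not in GENE_TREE_CLASSES:
            raise ParameterError(f"cls must be one of {GENE_TREE_CLASSES}")
        if not (0.0 <= self.t1 <= self.t0):
            raise ParameterError(f"require 0 <= t1 <= t0, got {self.t1}, {self.t0}")

    @property
    def topology(self) -> int:
        """Gene-tree topology index: 1 for G1a/G1b, 2 for G2, 3 for G3."""
        return CLASS_TOPOLOGY[self.cls]

    def in_support(self, params: SpeciesTreeParams) -> bool:
        if self.cls == "G1a":
            return params.tau1 < self.t1 < params.tau0 < self.t0
        return params.tau0 < self.t1 < self.t0


@dataclass(frozen=True)
class PatternProbs:
    """Site-pattern probabilities for one gene tree with given node ages.

    ``p`` is the 5-vector in the fixed pattern order; ``u`` and ``v`` are
    the JC transforms exp(-8 t0 / 3) and exp(-4 t1 / 3).
    """

    p: np.ndarray
    u: float
    v: float

    @classmethod
    def from_times(cls, t0: float, t1: float) -> "PatternProbs":
        p = conditional_pattern_probs(t0, t1)
        u = 0.0 if math.isinf(t0) else math.exp(-8.0 * t0 / 3.0)
        v = 0.0 if math.isinf(t1) else math.exp(-4.0 * t1 / 3.0)
        return cls(p=p, u=u, v=v)


@dataclass(frozen=True)
class MarginalPatternModel:
    """Marginal (locus-averaged) site-pattern probabilities and their
    scalar intermediates a0, a1, b, c0, c1.

    The marginal integrates the conditional pattern probabilities over
    the MSC distribution of gene trees and coalescent times, so it does
    not depend on the sequence length.  c0 = c1 = 0 when theta0 = theta1.
    """

    a0: float
    a1: float
    b: float
    c0: float
    c1: float
    pbar: np.ndarray


def noncoalescence_prob(params: SpeciesTreeParams) -> float:
    """Probability phi that the two ingroup lineages do not coalesce in
    their ancestral population, exp(-2 (tau0 - tau1) / theta1)."""
    return params.phi


def gene_tree_topology_probs(params: SpeciesTreeParams) -> np.ndarray:
    """Probabilities of the three gene-tree topologies given the species tree.

    Returns ``(1 - 2 phi / 3, phi / 3, phi / 3)``: the matching topology
    G1 occurs whenever the ingroup pair coalesces first, which is certain
    if they coalesce in their own ancestral population (probability
    1 - phi) and has probability 1/3 otherwise.
    """
    phi = params.phi
    return np.array([1.0 - 2.0 * phi / 3.0, phi / 3.0, phi / 3.0])


def msc_density(gt: GeneTreeSample, params: SpeciesTreeParams) -> float:
    """Joint MSC density of a gene-tree class and its coalescent times.

    Two lineages in a population of size theta coalesce at rate 2/theta,
    three at rate 6/theta.  Returns 0 outside the class's support.
    """
    tau0, tau1, theta0, theta1 = params.astuple()
    t1, t0 = gt.t1, gt.t0
    if gt.cls == "G1a":
        if not (tau1 < t1 < tau0 < t0):
            return 0.0
        return (
            (2.0 / theta1) * math.exp(-(2.0 / theta1) * (t1 - tau1))
            * (2.0 / theta0) * math.exp(-(2.0 / theta0) * (t0 - tau0))
        )
    if not (tau0 < t1 < t0):
        return 0.0
    return (
        params.phi
        * (2.0 / theta0) * (2.0 / theta0)
        * math.exp(-(6.0 / theta0) * (t1 - tau0))
        * math.exp(-(2.0 / theta0) * (t0 - t1))
    )


def _uv(t0, t1):
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    u = np.where(np.isinf(t0), 0.0, np.exp(-8.0 / 3.0 * np.where(np.isinf(t0), 0.0, t0)))
    v = np.where(np.isinf(t1), 0.0, np.exp(-4.0 / 3.0 * np.where(np.isinf(t1), 0.0, t1)))
    return u, v


def conditional_pattern_probs(t0, t1) -> np.ndarray:
    """Site-pattern probabilities for a G1-topology gene tree with node
    ages (t0, t1), t0 >= t1.

    With u = exp(-8 t0 / 3) and v = exp(-4 t1 / 3):

        p0 = (1 + 3 v^2 + 6 u + 6 u v) / 16
        p1 = (3 + 9 v^2 - 6 u - 6 u v) / 16
        p2 = p3 = (3 - 3 v^2 + 6 u - 6 u v) / 16
        p4 = (6 - 6 v^2 - 12 u + 12 u v) / 16

    Accepts scalars or arrays (broadcast); infinite times mean u = v = 0
    (random sequences).  The result has shape ``broadcast(t0, t1) + (5,)``
    with the 5-axis last.
    """
    t0a = np.asarray(t0, dtype=float)
    t1a = np.asarray(t1, dtype=float)
    if np.any(t1a > t0a):
        raise ParameterError("require t0 >= t1")
    if np.any(t1a < 0.0):
        raise ParameterError("require t1 >= 0")
    u, v = _uv(t0a, t1a)
    v2 = v * v
    uv = u * v
    p0 = (1.0 + 3.0 * v2 + 6.0 * u + 6.0 * uv) / 16.0
    p1 = (3.0 + 9.0 * v2 - 6.0 * u - 6.0 * uv) / 16.0
    p2 = (3.0 - 3.0 * v2 + 6.0 * u - 6.0 * uv) / 16.0
    p4 = (6.0 - 6.0 * v2 - 12.0 * u + 12.0 * uv) / 16.0
    return np.stack([p0, p1, p2, p2, p4], axis=-1)


#: column permutation applied to the G1-topology pattern vector to obtain
#: the pattern vector of each topology: the informative index carrying
#: the "matching pair" probability moves with the topology.
TOPOLOGY_PERMUTATION: dict[int, tuple[int, ...]] = {
    1: (0, 1, 2, 3, 4),
    2: (0, 2, 1, 2, 4),
    3: (0, 2, 2, 1, 4),
}


def pattern_probs_for_class(cls: str, t0, t1) -> np.ndarray:
    """Site-pattern probabilities for a gene tree of the given class.

    G1a and G1b share the G1 topology; for G2 (resp. G3) the high
    informative probability sits at pattern yxx (resp. xyx).
    """
    if cls not in GENE_TREE_CLASSES:
        raise ParameterError(f"cls must be one of {GENE_TREE_CLASSES}")
    base = conditional_pattern_probs(t0, t1)
    perm = TOPOLOGY_PERMUTATION[CLASS_TOPOLOGY[cls]]
    return base[..., perm]


def _marginal_from_intermediates(a0, a1, b, c0, c1) -> np.ndarray:
    bc = b + c0
    ac = a1 + c1
    p0 = (1.0 + 18.0 * a0 + 54.0 * a0 * bc + 9.0 * ac) / 16.0
    p1 = 3.0 * (1.0 - 6.0 * a0 - 18.0 * a0 * bc + 9.0 * ac) / 16.0
    p2 = 3.0 * (1.0 + 6.0 * a0 - 18.0 * a0 * bc - 3.0 * ac) / 16.0
    p4 = 6.0 * (1.0 - 6.0 * a0 + 18.0 * a0 * bc - 3.0 * ac) / 16.0
    return np.array([p0, p1, p2, p2, p4])


def marginal_pattern_probs(params: SpeciesTreeParams) -> MarginalPatternModel:
    """Marginal site-pattern probabilities, averaging the conditional
    probabilities over the MSC distribution of gene trees and times.

    The closed form uses the scalar intermediates

        a0 = exp(-8 tau0 / 3) / (3 + 4 theta0)
        a1 = exp(-8 tau1 / 3) / (3 + 4 theta1)
        b  = exp(-4 tau1 / 3) / (3 + 2 theta1)
        c0 = 2 phi (theta1 - theta0) exp(-4 tau0 / 3)
             / ((3 + 2 theta0)(3 + 2 theta1))
        c1 = 4 phi (theta1 - theta0) a0 / (3 + 4 theta1)

    and the marginal vector is a function of a0, b + c0 and a1 + c1 only.
    """
    tau0, tau1, theta0, theta1 = params.astuple()
    phi = params.phi
    a0 = math.exp(-8.0 * tau0 / 3.0) / (3.0 + 4.0 * theta0)
    a1 = math.exp(-8.0 * tau1 / 3.0) / (3.0 + 4.0 * theta1)
    b = math.exp(-4.0 * tau1 / 3.0) / (3.0 + 2.0 * theta1)
    c0 = (
        2.0 * phi * (theta1 - theta0) * math.exp(-4.0 * tau0 / 3.0)
        / ((3.0 + 2.0 * theta0) * (3.0 + 2.0 * theta1))
    )
    c1 = 4.0 * phi * (theta1 - theta0) * a0 / (3.0 + 4.0 * theta1)
    pbar = _marginal_from_intermediates(a0, a1, b, c0, c1)
    return MarginalPatternModel(a0=a0, a1=a1, b=b, c0=c0, c1=c1, pbar=pbar)


def marginal_pattern_probs_equal_theta(
    tau0: float, tau1: float, theta: float
) -> MarginalPatternModel:
    """Marginal site-pattern probabilities under the constraint
    theta0 = theta1 = theta, where c0 = c1 = 0.

    This is the three-parameter model inverted by the independent-sites
    ML parameter estimator.
    """
    if not (0.0 < tau1 <= tau0 and theta > 0.0):
        raise ParameterError("require 0 < tau1 <= tau0 and theta > 0")
    a0 = math.exp(-8.0 * tau0 / 3.0) / (3.0 + 4.0 * theta)
    a1 = math.exp(-8.0 * tau1 / 3.0) / (3.0 + 4.0 * theta)
    b = math.exp(-4.0 * tau1 / 3.0) / (3.0 + 2.0 * theta)
    pbar = _marginal_from_intermediates(a0, a1, b, 0.0, 0.0)
    return MarginalPatternModel(a0=a0, a1=a1, b=b, c0=0.0, c1=0.0, pbar=pbar)
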