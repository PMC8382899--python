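"""Exact simulator for gene trees and multilocus site-pattern data.

Simulation follows the MSC generative process exactly. For each locus an
exponential coalescent waiting time s1 with mean theta1/2 is drawn for
the two ingroup lineages. If tau1 + s1 < tau0 they coalesce in their own
ancestral population (class G1a) with t1 = tau1 + s1 and t0 = tau0 + s0,
s0 ~ Exp(mean theta0/2). Otherwise all three lineages enter the root
population, the three classes G1b, G2, G3 are equiprobable, and
t1 = tau0 + s1' with s1' ~ Exp(mean theta0/6) (three lineages), then
t0 = t1 + s0' with s0' ~ Exp(mean theta0/2).

Given the gene tree, site-pattern counts are multinomial draws from the
conditional pattern probabilities. In the infinite-sites regime (n set
to ``math.inf``) the exact per-locus pattern probabilities are stored in
place of counts.

Datasets are generated in fixed-size locus blocks, each block from its
own spawned random substream, so that enlarging m extends a dataset
without reshuffling earlier loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    GENE_TREE_CLASSES,
    GeneTreeSample,
    ParameterError,
    SpeciesTreeParams,
    conditional_pattern_probs,
)

_BLOCK = 4096  # loci per random substream block

#: class code order used by the vectorized sampler
CLASS_CODES: tuple[str, ...] = GENE_TREE_CLASSES  # ("G1a", "G1b", "G2", "G3")

_BASES = np.array(list("TCAG"))


@dataclass(frozen=True)
class LocusCounts:
    """Site-pattern data for one locus.

    In the finite-n regime ``x`` holds the 5-vector of pattern counts
    summing to ``n``. In the infinite-sites regime (``exact`` True) the
    locus is represented by its exact pattern-probability vector
    ``probs`` and ``x`` is None.
    """

    n: float
    x: np.ndarray | None = None
    probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.x is None and self.probs is None:
            raise ParameterError("either counts x or exact probs required")
        if self.x is not None:
            x = np.asarray(self.x, dtype=np.int64)
            if x.shape != (5,) or np.any(x < 0):
                raise ParameterError("x must be 5 nonnegative integers")
            if x.sum() != self.n:
                raise ParameterError(f"counts sum {x.sum()} != n={self.n}")
            object.__setattr__(self, "x", x)

    @property
    def exact(self) -> bool:
        return self.probs is not None

    @property
    def frequencies(self) -> np.ndarray:
        if self.exact:
            return np.asarray(self.probs)
        return self.x / self.n


@dataclass(frozen=True)
class MultilocusDataset:
    """Pattern-count data at m loci, all with the same sequence length.

    ``counts`` is the (m, 5) integer matrix of per-locus pattern counts;
    in the infinite-sites regime ``probs`` is the (m, 5) matrix of exact
    per-locus pattern probabilities instead.
    """

    n: float
    counts: np.ndarray | None = None
    probs: np.ndarray | None = None
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if self.counts is None and self.probs is None:
            raise ParameterError("either counts or probs required")
        if self.counts is not None:
            c = np.asarray(self.counts, dtype=np.int64)
            if c.ndim != 2 or c.shape[1] != 5 or c.shape[0] < 1:
                raise ParameterError("counts must have shape (m, 5), m >= 1")
            if np.any(c < 0) or np.any(c.sum(axis=1) != self.n):
                raise ParameterError("each locus's counts must sum to n")
            object.__setattr__(self, "counts", c)
        if self.probs is not None and (
            np.ndim(self.probs) != 2 or np.shape(self.probs)[1] != 5
        ):
            raise ParameterError("probs must have shape (m, 5)")

    @property
    def m(self) -> int:
        arr = self.counts if self.counts is not None else self.probs
        return arr.shape[0]

    @property
    def exact(self) -> bool:
        return self.probs is not None and self.counts is None

    @property
    def loci(self) -> list[LocusCounts]:
        if self.exact:
            return [LocusCounts(n=self.n, probs=row) for row in self.probs]
        return [LocusCounts(n=self.n, x=row) for row in self.counts]

    def pooled(self) -> LocusCounts:
        """Pooled pattern counts across loci (the concatenation summary)."""
        if self.exact:
            raise ParameterError("cannot pool counts of an infinite-sites dataset")
        return LocusCounts(n=self.n * self.m, x=self.counts.sum(axis=0))

    def pooled_frequencies(self) -> np.ndarray:
        """Mean site-pattern frequencies across loci."""
        if self.exact:
            return self.probs.mean(axis=0)
        return self.counts.mean(axis=0) / self.n


def sample_gene_trees(
    params: SpeciesTreeParams, size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized gene-tree sampler.

    Returns ``(cls, t1, t0)`` where ``cls`` is an integer array indexing
    into :data:`CLASS_CODES` (0=G1a, 1=G1b, 2=G2, 3=G3).
    """
    tau0, tau1, theta0, theta1 = params.astuple()
    s1 = rng.exponential(theta1 / 2.0, size)
    coalesced = tau1 + s1 < tau0
    cls = np.empty(size, dtype=np.int64)
    t1 = np.empty(size)
    t0 = np.empty(size)
    k = int(coalesced.sum())
    cls[coalesced] = 0
    t1[coalesced] = tau1 + s1[coalesced]
    t0[coalesced] = tau0 + rng.exponential(theta0 / 2.0, k)
    nk = size - k
    idx = ~coalesced
    cls[idx] = rng.integers(1, 4, nk)
    t1[idx] = tau0 + rng.exponential(theta0 / 6.0, nk)
    t0[idx] = t1[idx] + rng.exponential(theta0 / 2.0, nk)
    return cls, t1, t0


def sample_gene_tree(
    params: SpeciesTreeParams, rng: np.random.Generator
) -> GeneTreeSample:
    """Draw one gene tree (class and coalescent times) from the MSC."""
    cls, t1, t0 = sample_gene_trees(params, 1, rng)
    return GeneTreeSample(cls=CLASS_CODES[cls[0]], t1=float(t1[0]), t0=float(t0[0]))


def _pattern_probs_for_codes(cls: np.ndarray, t1: np.ndarray, t0: np.ndarray) -> np.ndarray:
    """(size, 5) pattern probabilities with the topology permutation applied."""
    base = conditional_pattern_probs(t0, t1)  # G1 orientation
    out = base.copy()
    for code, perm in ((2, (0, 2, 1, 3, 4)), (3, (0, 3, 2, 1, 4))):
        sel = cls == code
        out[sel] = base[sel][:, perm]
    return out


def sample_pattern_probs(
    params: SpeciesTreeParams, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact per-locus site-pattern probabilities for `size` simulated loci."""
    cls, t1, t0 = sample_gene_trees(params, size, rng)
    return _pattern_probs_for_codes(cls, t1, t0)


def sample_counts(
    params: SpeciesTreeParams, m: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(m, 5) multinomial site-pattern counts for m simulated loci of n sites."""
    probs = sample_pattern_probs(params, m, rng)
    return rng.multinomial(n, probs)


def sample_locus_counts(
    params: SpeciesTreeParams, n: int, rng: np.random.Generator
) -> LocusCounts:
    """Simulate one locus: draw a gene tree, then multinomial counts."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    return LocusCounts(n=n, x=sample_counts(params, 1, n, rng)[0])


def sample_dataset(
    params: SpeciesTreeParams, m: int, n: int | float, seed: int | np.random.SeedSequence
) -> MultilocusDataset:
    """Simulate a multilocus dataset of m loci, each with n sites.

    ``n = math.inf`` produces the infinite-sites regime, in which each
    locus is represented by its exact pattern-probability vector.  Loci
    are generated in fixed blocks with independent substreams, so a
    dataset with larger m extends one with smaller m locus-for-locus.
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    infinite = math.isinf(n)
    if not infinite and n < 1:
        raise ParameterError("n must be >= 1 (or math.inf)")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    nblocks = (m + _BLOCK - 1) // _BLOCK
    children = ss.spawn(nblocks)
    rows = []
    for i, child in enumerate(children):
        keep = min(_BLOCK, m - i * _BLOCK)
        rng = np.random.default_rng(child)
        # always draw a full block so a larger m extends a smaller one
        if infinite:
            rows.append(sample_pattern_probs(params, _BLOCK, rng)[:keep])
        else:
            rows.append(sample_counts(params, _BLOCK, int(n), rng)[:keep])
    data = np.concatenate(rows, axis=0)
    prov = {
        "params": dict(zip(("tau0", "tau1", "theta0", "theta1"), params.astuple())),
        "label": params.label,
        "m": m,
        "n": "inf" if infinite else int(n),
        "seed": ss.entropy,
    }
    if infinite:
        return MultilocusDataset(n=math.inf, probs=data, provenance=prov)
    return MultilocusDataset(n=int(n), counts=data, provenance=prov)


# pattern realization: which sequences share base x (a, b, c order)
_PATTERN_GROUPS = {
    0: ((0, 1, 2),),            # xxx
    1: ((0, 1), (2,)),          # xxy
    2: ((1, 2), (0,)),          # yxx
    3: ((0, 2), (1,)),          # xyx
    4: ((0,), (1,), (2,)),      # xyz
}


def realize_alignment(
    counts: LocusCounts, rng: np.random.Generator
) -> dict[str, str]:
    """Realize a three-sequence alignment whose per-site pattern classes
    reproduce ``counts`` exactly.

    Base identities are assigned uniformly at random consistent with
    each pattern class, and site order is shuffled.  Sequences are
    labelled ``a``, ``b``, ``c`` for species A, B, C.
    """
    if counts.exact:
        raise ParameterError("cannot realize an infinite-sites locus")
    n = int(counts.n)
    sites = np.empty((n, 3), dtype=np.int64)
    pos = 0
    for j, count in enumerate(counts.x):
        count = int(count)
        if count == 0:
            continue
        groups = _PATTERN_GROUPS[j]
        # uniformly random distinct bases, one per group of identical sequences
        choice = np.argsort(rng.random((count, 4)), axis=1)[:, : len(groups)]
        for g, members in enumerate(groups):
            for sp in members:
                sites[pos : pos + count, sp] = choice[:, g]
        pos += count
    rng.shuffle(sites, axis=0)
    seqs = _BASES[sites]
    return {label: "".join(seqs[:, i]) for i, label in enumerate("abc")}


def counts_from_sequences(seqs: dict[str, str] | list[str]) -> LocusCounts:
    """Reduce a three-sequence alignment to its 5-category pattern counts."""
    if isinstance(seqs, dict):
        try:
            rows = [seqs[k] for k in ("a", "b", "c")]
        except KeyError:
            rows = list(seqs.values())
    else:
        rows = list(seqs)
    if len(rows) != 3 or len({len(r) for r in rows}) != 1:
        raise ParameterError("need three aligned sequences of equal length")
    a, b, c = (np.frombuffer(r.upper().encode(), dtype="S1") for r in rows)
    ab, bc, ca = a == b, b == c, c == a
    x = np.empty(5, dtype=np.int64)
    x[0] = np.sum(ab & bc)
    x[1] = np.sum(ab & ~bc)
    x[2] = np.sum(bc & ~ab)
    x[3] = np.sum(ca & ~ab)
    x[4] = np.sum(~ab & ~bc & ~ca)
    return LocusCounts(n=len(rows[0]), x=x)
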