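# coaltrio

Species-tree estimation for a rooted three-species triplet under the
multispecies coalescent (MSC), with Jukes–Cantor (JC) sequences and a
molecular clock — the smallest species-tree problem that still has all
the complexity of the general one.

For species A, B, C there are three rooted species trees
S1 = ((A,B),C), S2 = ((B,C),A), S3 = ((C,A),B), each parameterized by
two divergence ages (τ0 root, τ1 internal) and two ancestral
population-size parameters (θ0, θ1), all in expected substitutions per
site. Because ancestral lineages may fail to coalesce in their own
ancestral population (probability φ = exp(−2(τ0−τ1)/θ1)), the gene tree
at a locus can differ from the species tree: the matching topology has
probability 1 − 2φ/3 and each mismatching topology φ/3. Under JC the
data at a locus reduce to counts of five site patterns
(xxx, xxy, yxx, xyx, xyz).

The package provides, as a library and a CLI:

* **Closed forms** (`coaltrio.core`) — gene-tree topology probabilities,
  the joint MSC density of gene trees and coalescent times, conditional
  site-pattern probabilities given node ages, and the marginal
  (locus-averaged) site-pattern probabilities p̄.
* **An exact simulator** (`coaltrio.simulate`) — gene trees, multinomial
  site-pattern counts, infinite-sites loci, and realized three-sequence
  alignments (PHYLIP/FASTA).
* **Four estimation methods** (`coaltrio.estimators`) —
  two-step majority vote over per-locus ML gene trees, concatenation
  (pooled counts + JC-clock node ages), independent-sites ML
  (pooled counts + moment inversion of p̄ under θ0 = θ1), and full
  maximum likelihood under the MSC via Gaussian quadrature over
  coalescent times.
* **Error theory** (`coaltrio.error_theory`) — the normal approximation
  ζ_N to the error of argmax rules over exchangeable triples, its
  multinomial specialization ζ(m, q1, q2), lower/upper bounds, the
  single-site / infinite-sites / mixed-n covariances of pattern
  frequencies, the exact full-ML error φ^m·(2/3) at infinite sequence
  length, and a Kullback–Leibler Monte-Carlo predictor for finite-n ML.
* **Experiment drivers** (`coaltrio.experiments`) — replicated
  simulation error rates, an exact enumeration oracle for single-site
  loci, probit-linearity diagnostics (Φ⁻¹(error) is affine in √m), and
  a tabulated comparison grid across sequence lengths.

## Worked example

```python
import math
import coaltrio as ct

params = ct.SpeciesTreeParams(tau0=0.02, tau1=0.019, theta0=0.01, theta1=0.05)

print(ct.gene_tree_topology_probs(params))
# [0.35947371 0.32026315 0.32026315]

print(ct.marginal_pattern_probs(params).pbar)
# [0.92831926 0.02377711 0.0233728  0.0233728  0.00115803]

data = ct.sample_dataset(params, m=1000, n=1000, seed=1)
print(ct.two_step(data).support)
# [336.33333333 341.33333333 322.33333333]
print(ct.concat_isml_topology(data).winner)
# 1

print(ct.predict_two_step_error(params, m=1000, n=math.inf).value)
# 0.11260153283082552
print(ct.ml_error_infinite_n(params, m=10).value)
# 0.4468800306904261
```

The topology probabilities say that even though S1 is the true tree,
nearly two thirds of loci carry a mismatching gene tree (φ ≈ 0.96: the
internal branch spans only 0.04 coalescent units). The marginal pattern
probabilities show that at a single site the signal separating the
trees is the difference p̄1 − p̄2 ≈ 0.0004. The simulated dataset then
illustrates how hard the problem is: with 1000 loci of 1000 sites the
majority vote lands on the *wrong* tree S2 (votes 336.3 : 341.3 : 322.3
after even tie splitting — phylogenetic error in the per-locus gene
trees erodes the majority), while the pooled counts recover S1. That is
no accident of the seed: the two-step error at these settings is about
26%. The last two numbers are error predictions at infinite sequence
length: the two-step method with perfectly known gene trees at 1000
loci is still wrong 11.3% of the time, while full ML with perfectly
known gene trees *and* coalescent times errs 45% of the time at m = 10
but only 1% at m = 100.

The same functionality is exposed on the command line:

```bash
coaltrio simulate --tau0 0.02 --tau1 0.019 --theta0 0.01 --theta1 0.05 \
    --m 1000 --n 1000 --seed 1 --out data
coaltrio estimate data.tsv --method isml
coaltrio predict --params params.txt --method 2step --m 1000 --n inf
coaltrio report-table1 --params params.txt --no-simulation
```

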