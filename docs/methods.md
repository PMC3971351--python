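# Methods

## The fingerprinting model

A fingerprint represents one expression profile as the ternary activity of a
fixed, ordered gene-set collection. Three transformations take a raw
profile there, and each is responsible for one kind of robustness:

1. **Rank transform.** Genes are ranked within the sample, 1 = lowest of the
   `T` measured genes, ties averaged (which keeps the column rank sum at
   exactly `T(T+1)/2`). Ranks discard the intensity scale, so everything
   downstream is invariant to monotone per-sample transformations —
   normalization scheme, log vs. linear units, scanner gain.
2. **Pathway scoring.** A pathway represented by `n ≥ min_genes` member
   genes gets `En(P) = (1/n)·Σ R_i²`. Squaring weights the top of the
   ranking, so coordinated high expression of a pathway moves the score
   strongly; a pathway with fewer than `min_genes` measured members is
   marked absent, never imputed, and absence propagates to a 0 fingerprint
   entry (recoverable via the POE missingness mask).
3. **Background normalization (POE).** Raw `En` is platform- and
   pathway-specific, so scores are calibrated against the empirical
   distribution of the same pathway on the same platform over a large,
   heterogeneous collection of arrays. Each such distribution is fitted
   with the two-component mixture `π·U(lo,hi) + (1−π)·N(μ,σ²)`: the normal
   is the core of unremarkable pathway expression, the uniform absorbs
   outlying scores. The signed probability of expression
   `POE(y) = sign(y−μ)·π f_U / (π f_U + (1−π) f_N)` is a dimensionless
   quantity in (−1, 1) comparable across platforms and species. The
   sign convention uses the fitted normal mean μ as the reference point.

The ternary transform applies a threshold `T` with inclusive boundaries
(`+1` iff `POE ≥ T`). The default `T = 0.001` is deliberately permissive:
at the pathway level the discriminating signal is carried by many modest,
coordinated shifts rather than a few extreme ones, and benchmark sweeps
(`benchmark.threshold_sweep`) show retrieval quality flat-to-falling as `T`
rises. A consequence worth stating plainly: at `T = 0.001` most pathways
receive a non-zero call, and the fingerprint behaves nearly as a
"side-of-the-core" binarization; its power comes from which *combination*
of pathways is called up or down.

## EM details and numerical choices

The uniform support is held fixed at the observed range padded by 0.1% of
its width; a free-support uniform makes the likelihood unbounded. With the
support fixed, EM over (π, μ, σ) is standard and deterministic:
initialization π₀ = 0.1, μ₀ = median, σ₀ = 1.4826·MAD; convergence when the
log-likelihood improves by < 1e−8; cap 1000 iterations; σ floored at
1e−6·(hi−lo). The log-likelihood trajectory is retained on the fit object
and is non-decreasing up to floating-point noise. Degenerate inputs
(constant scores, fewer than `n_min = 50` observations) are refused with
the pathway named.

When scoring *new* samples the uniform density is evaluated as the constant
1/(hi−lo) everywhere, including beyond the fitted support, so a score more
extreme than anything in the background gets |POE| → 1 rather than an
undefined density. The posterior is clamped to the largest double below 1
to keep POE in the open interval.

Backgrounds are immutable JSON documents stamped with a content hash of the
gene-set collection (names, order, members, species). Applying a background
to scores computed against any other collection is an error: silently
misaligned fingerprint coordinates are the worst failure mode this tool can
have.

## Distances, consensus, retrieval significance

Fingerprint distance is normalized Manhattan, `Σ|a_i − b_i| / (2N)`, a
metric on ternary vectors scaled to [0, 1]. The consensus of a group is the
mean ternary score thresholded strictly at ±t; distance from a consensus is
computed only over its non-zero coordinates, so disagreement is measured on
the pathways that actually define the group. Retrieval significance models
the corpus as a small matched population plus a large non-matched one whose
distances are approximately normal; that null is estimated robustly as
N(median, (IQR/1.349)²) so the matched tail cannot contaminate it, and the
reported p-value is the lower tail. The estimate assumes unimodality of the
non-matched distances; no multiplicity adjustment is applied to retrieval
tables.

## Benchmarks

`nearest_centroid_cv` is repeated stratified k-fold (default 5×10)
nearest-class-mean classification; stratification prevents empty-class
training folds, and classes smaller than k trigger a leave-one-out
fallback. `cluster_validity` is the ratio of summed squared Euclidean
distance to the own-class mean over the summed mean squared distance to
other-class means; the inter term is one of several defensible readings of
"inter-class variance" — it was chosen for symmetry and scale-consistency
with the intra term. `retrieval_pr` uses the standard interpolated
precision convention (max precision at recall ≥ r), distance ties broken by
sample id. `threshold_sweep` re-thresholds one POE matrix and, when asked,
builds the random-gene-set comparator by re-running the entire pipeline on
sets randomized with the run seed (size distribution preserved, members
drawn from the pooled gene universe).

## Lineage reconstruction

Cell-type consensus fingerprints (t = 0.75) form a taxa × pathways ternary
character matrix. Tree length is computed exactly by Sankoff dynamic
programming under the score-difference cost |a − b| (a −1↔+1 change counts
as two steps); the DP is vectorized across characters and rooting is
immaterial because costs are symmetric. The search hill-climbs by NNI from
a neighbor-joining tree built on normalized Manhattan distances between
character rows — a deterministic, data-informed start — accepting the first
strict improvement in a fixed edge order. Bootstrap support resamples
characters with replacement, re-runs the search, and reports the fraction
of replicates containing each bipartition of the point-estimate tree (not a
consensus of replicates). NNI hill-climbing finds local optima; for the
small numbers of cell types this tool targets (≲ 20) that has been adequate,
but no global-optimality claim is made beyond 4 taxa, where the search
provably covers all 3 topologies.

## Survival signatures

A stem signature is extracted as the pathways whose consensus agrees
(non-zero, same sign) between the two stem groups and differs in
progenitors — consensus disagreement at t is the operational definition of
"differential" here, as no distributional test is meaningful on ternary
consensus values — then intersected across species with signs required to
match. Patients are scored by the plain sum of their ternary values over
the signature (a sign-weighted variant is available behind a flag), split
into high/low by *exact* one-dimensional 2-means (all n−1 sorted splits
scanned; ties to the smallest split; no iterative initialization to go
wrong), and compared by the standard two-group log-rank test (lifelines).
Significance of the observed signature is judged against the distribution
of log-rank p-values from random pathway sets of the same size (default
1000 permutations); permutations with degenerate stratifications are
skipped and counted.

## The synthetic corpus

The generator produces the situation the method claims to handle, with
ground truth:

- **Platform effects** are a strictly monotone intensity transform (cycled
  per platform) plus per-gene, per-platform offsets. The monotone part must
  be invisible to rank scoring; the offsets must be absorbed by the
  per-platform background — these are exactly the claims under test.
- **Classes** are ±1 activation patterns over a shared informative pathway
  subset. Because the default threshold is permissive, class identity in
  fingerprints is carried by broad coordinated patterns, as tissue identity
  is in real compendia; small disjoint pathway lists would be an unfairly
  easy (and unrealistic) target at high thresholds and an impossible one at
  low thresholds.
- **Activation** compresses member genes' within-sample rank quantiles
  toward the top (or bottom): effect 0.9 forces an up-activated gene into
  the top tenth of the sample's ranking. Parameterizing on the quantile
  scale makes "strong" platform-independent.
- **Backgrounds** contain a fraction (default 30%) of "outlier" samples
  with random activations, so per-pathway score distributions genuinely
  have an outlier component, as in a public repository; the remainder are
  quiet.
- **Defaults** (2 platforms × 2 species, 2500 genes/platform with an 80%
  shared core, 50 pathways of 10–20 genes, 30 informative, 4 classes × 10
  samples per platform, 60 background arrays per platform, homology
  covering 90% of the core): large enough that every pathway is scoreable
  on both species and backgrounds exceed the EM minimum, small enough that
  the full pipeline runs in seconds.
- **Lineages** evolve a base fingerprint down a tree, mutating a fixed
  number of randomly chosen characters per edge by ±1 steps; a step that
  clamping at ±1 would nullify is applied in the opposite direction, so
  every requested flip changes state. Note that random placement lets
  different edges hit the same character; guaranteed topology recovery
  needs enough characters that such collisions are rare (the recovery
  checks use 120 characters for 10 flips/edge on six taxa).
- **Survival** times are exponential with hazard ∝ exp(β·centered score);
  censoring is independent uniform U(0, τ) with τ calibrated by
  root-finding so the expected censored fraction matches the request.

What passing on this corpus does *not* show: robustness to probe-level
artifacts (cross-hybridization, batch chemistry), to correlated gene–gene
noise within samples, to multimodal background distributions, or to
RNA-seq count characteristics — none of which the generator emulates.

## Known limitations

- The retrieval null is a single normal; heterogeneous corpora with large
  matched sub-populations violate it and p-values become conservative or
  anti-conservative depending on shape.
- POE signs are referenced to the fitted normal mean; under strong skew the
  mean and mode of the core differ and near-zero calls can flip side.
- The two-component mixture treats high and low outliers as one component;
  asymmetric outlier structure is averaged.
- Homology mapping collapses many-to-one targets to a single gene and
  drops unmapped members; paralog-aware mapping is out of scope.
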