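# Methods

## Per-sample annotation networks

The core object is a per-sample graph over annotation terms. For sample
*j* with expression vector *e⁽ʲ⁾* restricted to the selected genes, the
profile matrix *M⁽ʲ⁾* masks expression by set membership
(*M⁽ʲ⁾ₚ_q = eₚ⁽ʲ⁾·1[p ∈ q]*), and the annotation distance
*A_{q,q\*}* is the Euclidean distance between profile columns. Distances
are computed over the full selected-gene vector; algebraically this equals
the symmetric-difference form *A² = Σₚ eₚ²* over genes in exactly one of
the two sets (shared genes contribute identical coordinates and cancel).
The identity is used as an independent cross-check in the tests, not as
the implementation.

**Edge thresholding.** The graph keeps *k* = max(1, ⌊fraction · m⌋) of the
*m = Q(Q−1)/2* candidate edges, fraction 0.10 by default. The default
`largest_distance` rule takes "top weight" literally on the distance
matrix; the `smallest_distance` option covers the similarity reading in
which near-identical profiles should be linked. Which rule was used is
carried on every `SampleNetwork` and in provenance output. Two numerical
details: the floor is evaluated as ⌊fraction·m + 1e−9⌋ so that decimal
fractions whose binary representation falls a hair short (0.3 · 10 =
2.999…96) still floor to the intended integer, and ties at the cutoff
break by ascending node-index pair, making the edge set reproducible
across platforms with no dependence on sort stability.

**Degrees.** The feature vector is the node degree — the one topological
summary used downstream. Every row of the feature matrix sums to 2k, so
the features live on a simplex-like lattice; one consequence is that the
feature columns are linearly dependent, which the mixture-model stage must
tolerate (see the variance floor below).

**Feature selection.** "Total variance" is interpreted as the per-gene
across-sample unbiased variance (denominator n−1); ties at the cutoff
break by input row order. Selection happens once per cohort, not per
sample, so all networks share one gene universe. Annotations with no
member among the selected genes are kept as isolated all-zero columns so
the feature space is identical across samples. Gene identifiers are
matched by exact case-sensitive string comparison; no alias resolution is
attempted, and callers mixing identifier conventions (symbols vs.
Ensembl) will silently get empty intersections — hence the loud
"annotation/gene universe disjoint" error when no set overlaps at all.
The package is unit-agnostic: counts, TPM or log-scale values are all
accepted, and nothing assumes a particular normalisation (the per-sample
scale invariance of the network removes sample-level scale effects, but
the cohort-level variance ranking does depend on the unit supplied).

## Cluster-count selection

`gmm_select_k` fits Gaussian mixtures for each k (default 1…6) over four
covariance families — spherical, diagonal, tied (shared full), full — and
selects the (k, family) pair maximising BIC in the convention
BIC = 2·logL − p·log n (larger is better). The minimise-convention BIC of
scikit-learn is negated internally; the report table stores the
maximise-convention values to avoid the classic sign confusion.

Degree features are integers, so duplicated rows are common, and EM will
otherwise chase spurious "spike" components of unbounded likelihood
sitting on repeated points. `reg_covar` (default 0.2) floors every
covariance diagonal: slightly above the 1/12 variance of unit rounding
noise, far below any unit-scale group separation, it suppresses the
spikes while leaving genuine structure detectable. For standardised
continuous inputs the floor is negligible against unit variance; callers
fitting data with much smaller natural scales should lower it. Constant
feature columns are dropped before fitting (they carry no information and
break covariance estimation).

## Hierarchical, K-means and consensus clustering

Pairwise dissimilarity is 1 − Pearson correlation of sample rows; a
constant row makes the correlation undefined and is rejected by name.
"Error sum of squares" linkage is the Ward criterion. Two dialects exist
in the wild: `ward.D` applies the Lance–Williams update to the
dissimilarities as given, `ward.D2` to their squares. The default here is
`ward.D`; since scipy's `linkage(…, 'ward')` implements the ward.D2
recurrence, ward.D is obtained by passing the square roots of the
dissimilarities (identical merge order; heights on the transformed
scale). Both dialects are exposed as `linkage_dialect`.

Consensus clustering draws ⌊0.8·n⌋ samples and ⌊0.8·p⌋ features per
resample **without replacement** (fractions "taken", not bootstrapped),
clusters each subsample hierarchically at the requested k, and divides
pairwise co-clustering counts by co-sampling counts. The final partition —
left open by common practice — is defined here as a Ward cut of
1 − consensus at the same k. A sample pair never co-drawn after all
resamples is an error advising more resamples rather than a silent NaN.
Resampling is unstratified. K-means is scikit-learn's Lloyd
implementation, best of `n_restarts` by within-cluster sum of squares,
with its standard empty-cluster re-seeding.

The two-stage subtype flow (split the cohort at the BIC-chosen k, then
re-cluster one class at a finer k, e.g. with K-means) is supported by the
CLI's `cluster --stage2`; the provenance file records which algorithm
produced which labels.

## Scores

Cytolytic activity is √((e_GZMA + δ)(e_PRF1 + δ)) per sample. The offset
δ (default 0.01) guards zero expression — log-scale summaries otherwise
collapse — and is recorded in output metadata; δ = 0 reproduces the plain
geometric mean. Purity adjustment divides a score by (1 − purity),
defined only for purity < 1. The differential-expression filter takes an
externally computed table (the DE model itself is deliberately not
reimplemented) and applies fold change ≥ 2 with FDR < 0.05 for
up-regulation, fold change ≤ 1/2 with FDR < 0.05 for down-regulation;
the fold-change boundary is inclusive and the FDR boundary exclusive,
exactly as the thresholds are printed. Comparisons run in log2 space so
the boundary cases are exact in floating point.

## Synthetic cohorts

The generator emulates the inputs the pipeline consumes, not any
particular dataset. Baseline expression is log-normal: gene *p* has a
log2-mean drawn from N(5, 1); samples add N(0, 0.5) log2 noise; values
are returned as 2^log2. Gene sets are sampled with a shared-core scheme:
a core of c genes common to all sets plus disjoint remainders gives mean
pairwise Jaccard c/(2s̄ − c), so c is solved from the requested overlap
(default 0.1). Group structure is planted at the **set level**: each of
the three groups (n = 60 samples in equal thirds) owns four informative
sets whose member genes are shifted up by 2 log2 units (fourfold) in that
group's samples. Set-level injection is deliberate — degree features see
only annotation-level structure, so this is the signal the method is
premised on detecting.

Default sizes: 1000 genes (so the top-500 variance cut is an active
filter), 30 sets of 20–40 genes. Thirty sets give ⌊0.1 · 435⌋ = 43 edges
per network; with many fewer sets the degree space is so coarse that
within-group vectors collapse onto a handful of discrete patterns and
model selection fragments them into spurious clusters.

What the generator does **not** emulate: count noise and
mean–variance coupling of sequencing data, batch effects, correlated
co-expression modules within sets, tumour purity gradients, or realistic
(hierarchically redundant) gene-set collections. Passing recovery tests
therefore demonstrates the machinery is correct and the signal path is
intact, not that real cohorts of comparable size are separable.

**A null-model caveat.** With effect size 0, planted labels are
unrecoverable (ARI ≈ 0 against any partition — the tested invariant), but
mixture-model selection on the null degree features does *not* settle on
k = 1: several annotation columns have near-tied profile norms, the
identity of the dominant hub flips from sample to sample, and the degree
features are genuinely discretely multimodal. This is a property of
rank-thresholded networks worth knowing before reading a BIC-chosen k > 1
as evidence of biology; corroborating structure (consensus stability,
score separation) should be required.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen as
the smallest sizes at which each property is meaningfully exercised:
oracle comparisons on ≤20 genes × ≤8 sets × 5 samples; recovery studies
on the default 60-sample cohort; consensus at 100 resamples (the
full-size default remains 500); mixture selection over k = 1…6.
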