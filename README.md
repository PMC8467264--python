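# singnet — single-sample immune signature networks

`singnet` turns a bulk gene expression cohort into **one network per
sample** whose nodes are immune gene sets (annotation terms, e.g. MSigDB
C7 immunologic signatures) rather than genes, summarises each network by
its node degrees, and clusters those degree features into candidate
immune subtypes. It is aimed at tumour-immunology analysts who want a
sample-specific, annotation-level view of expression — the setting where
it was developed is cutaneous melanoma subtyping, but nothing in the code
is cancer- or organism-specific.

## The method

Given an expression matrix (genes × samples) and a gene-set collection
with sets *q = 1…Q*:

1. **Feature selection.** Keep the top *n* genes by across-sample
   variance (default *n* = 500, unbiased variance, ties by input order).
2. **Profile matrix.** For sample *j*, build *M⁽ʲ⁾* (genes × sets) with
   *M⁽ʲ⁾ₚ_q = eₚ⁽ʲ⁾* if gene *p* belongs to set *q*, and 0 otherwise.
3. **Annotation distances.** *A⁽ʲ⁾_{q,q\*}* = Euclidean distance between
   columns *q* and *q\** of *M⁽ʲ⁾*. Equivalently
   *A²_{q,q\*} = Σₚ eₚ²* over genes in the symmetric difference of the two
   memberships.
4. **Edge thresholding.** Of the *m = Q(Q−1)/2* candidate edges, keep the
   top fraction by weight (default 10%, i.e. *k* = max(1, ⌊0.1·m⌋);
   default rule keeps the **largest** distances, a `smallest_distance`
   option is provided). Ties break by ascending node-index pair.
5. **Degree features.** *h_q⁽ʲ⁾* = number of neighbours of node *q*.
   Stacking rows gives the samples × Q integer feature matrix.

Because step 4 ranks distances, each sample's network is invariant to
positive rescaling of that sample — cross-sample normalisation differences
in overall scale do not leak into the features.

Downstream, the package provides the companion subtyping toolkit:

- **`gmm_select_k`** — Gaussian mixture models over *k* = 1…6 and four
  covariance families, scored by BIC in the maximise-`2logL − p·log n`
  convention;
- **`hierarchical_cluster`** — Ward (ESS) agglomeration on 1 − Pearson
  dissimilarities (R `ward.D` dialect by default, `ward.D2` available);
- **`kmeans_cluster`** — Lloyd's algorithm, best of several restarts;
- **`consensus_cluster`** — 500 resamples (default) of 80% of samples ×
  80% of features, co-clustering frequencies, final cut on 1 − consensus;
- **scores** — cytolytic activity √(GZMA·PRF1), tumour-purity adjustment
  score/(1 − purity), and the fold-change ≥ 2 & FDR < 0.05 signature
  filter for externally computed differential-expression tables;
- **`synth`** — a synthetic-cohort generator that plants subtype structure
  at the gene-set level, so the whole stack is testable offline.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from singnet import (SyntheticCohortSpec, generate_cohort, sing_transform,
                     gmm_select_k)

expr, sets, truth = generate_cohort(SyntheticCohortSpec(seed=1))
features, networks = sing_transform(expr, sets, return_networks=True)
print("degree features:", features.degrees.shape)
print("edges per network:", networks[0].n_edges)
selection = gmm_select_k(features, seed=1)
print("BIC-chosen k:", selection.chosen_k)
print("agreement with planted groups (ARI):",
      round(adjusted_rand_score(truth, selection.labels), 3))
```

prints

```
degree features: (60, 30)
edges per network: 43
BIC-chosen k: 3
agreement with planted groups (ARI): 1.0
```

The synthetic cohort has 60 samples in three planted groups, 1000 genes
and 30 gene sets; each sample network keeps ⌊0.1 · 435⌋ = 43 edges. BIC
selects three mixture components and the resulting labels match the
planted subtypes exactly (adjusted Rand index 1.0).

The same flow is available from the shell:

```bash
singnet simulate --out-dir cohort --seed 1
singnet transform --expression cohort/expression.tsv --gmt cohort/sets.gmt \
    --out-dir net
singnet cluster --features net/degree_matrix.tsv --method gmm --out-dir subtype
```

Every command writes a `provenance.json` (parameters, seed, input
checksums) next to its outputs.

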