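"""Subtype clustering: mixture-model selection, hierarchical, K-means,
and subsampled consensus clustering.

Four procedures are provided, mirroring common practice in tumour subtype
discovery:

* :func:`gmm_select_k` — Gaussian finite mixture models fitted over a range
  of cluster counts and a small family of covariance structures, scored by
  BIC. The BIC here follows the mclust sign convention,
  ``2 log L - n_params * log(n)``, and is **maximised**.
* :func:`hierarchical_cluster` — agglomerative clustering with pairwise
  dissimilarity ``1 - Pearson correlation`` and the Ward (error sum of
  squares) criterion.
* :func:`kmeans_cluster` — Lloyd's algorithm, best of several restarts.
* :func:`consensus_cluster` — repeated hierarchical clustering of random
  sample/feature subsets; the fraction of times two samples co-cluster
  (among resamples where both were drawn) forms the consensus matrix, and
  the final partition cuts a hierarchical tree built on 1 - consensus.

All stochastic procedures take an explicit seed; cluster labels are
1-based throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .io import NumericalError, ValidationError
from .sing import DegreeFeatureMatrix

logger = logging.getLogger("singnet")

LinkageDialect = Literal["ward.D", "ward.D2"]
COVARIANCE_FAMILIES = ("spherical", "diag", "tied", "full")

__all__ = [
    "ClusterModelSelection",
    "ConsensusResult",
    "gmm_select_k",
    "hierarchical_cluster",
    "kmeans_cluster",
    "consensus_cluster",
]


def _as_sample_matrix(features) -> tuple[np.ndarray, list[str]]:
    """Coerce features to a samples × variables float array with row ids."""
    if isinstance(features, DegreeFeatureMatrix):
        return features.degrees.astype(float), list(features.sample_ids)
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), [str(i) for i in features.index]
    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("feature matrix must be 2-D (samples x variables)")
    return arr, [str(i) for i in range(arr.shape[0])]


# ---------------------------------------------------------------------------
# Gaussian mixture model selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterModelSelection:
    """Outcome of BIC model selection over cluster counts.

    ``scores`` holds, for each k in ``k_range``, the best BIC across the
    covariance families (mclust convention: larger is better);
    ``covariance_family_per_k`` the family attaining it. ``labels`` are the
    1-based maximum-posterior assignments under the winning model.
    """

    k_range: tuple[int, ...]
    scores: tuple[float, ...]
    covariance_family_per_k: tuple[str, ...]
    chosen_k: int
    labels: np.ndarray
    bic_table: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": list(self.k_range),
                "best_bic": list(self.scores),
                "covariance_family": list(self.covariance_family_per_k),
                "chosen": [k == self.chosen_k for k in self.k_range],
            }
        )


def gmm_select_k(
    features,
    k_range: Sequence[int] = range(1, 7),
    seed: int = 0,
    covariance_families: Sequence[str] = COVARIANCE_FAMILIES,
    reg_covar: float = 0.2,
    n_init: int = 3,
    drop_constant_columns: bool = True,
) -> ClusterModelSelection:
    """Choose the number of clusters by BIC over Gaussian mixtures.

    For every k in ``k_range`` and every covariance family, an EM fit is
    scored by ``2 log L - n_params * log(n)``; the (k, family) pair with the
    largest score wins. Constant feature columns (zero variance) carry no
    information and are dropped before fitting when
    ``drop_constant_columns`` is set.

    ``reg_covar`` is a floor added to every covariance diagonal. Degree
    features are integer-valued, so duplicated rows are common and EM can
    otherwise chase unbounded-likelihood "spike" components sitting on
    repeated points; the default floor of 0.2 — a little above the 1/12
    variance of unit rounding noise, and far below any unit-scale group
    separation — suppresses those spurious maxima while leaving genuine
    structure detectable. For standardised continuous features the floor
    is negligible relative to unit variance.
    """
    x, _ = _as_sample_matrix(features)
    k_range = tuple(int(k) for k in k_range)
    if not k_range:
        raise ValidationError("k_range is empty")
    n = x.shape[0]
    if min(k_range) < 1 or max(k_range) >= n:
        raise ValidationError(f"k_range must lie within [1, {n - 1}]")
    if drop_constant_columns:
        keep = x.std(axis=0) > 0
        if not keep.all():
            logger.info("dropping %d constant feature column(s)", int((~keep).sum()))
        x = x[:, keep]
    if x.shape[1] == 0:
        raise NumericalError(
            "all feature columns are constant; nothing to cluster"
        )

    best_per_k: dict[int, tuple[float, str, GaussianMixture]] = {}
    for k in k_range:
        for family in covariance_families:
            gm = GaussianMixture(
                n_components=k,
                covariance_type=family,
                random_state=seed,
                n_init=n_init,
                reg_covar=reg_covar,
                max_iter=300,
            )
            try:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    gm.fit(x)
            except ValueError:
                logger.debug("GMM fit failed for k=%d family=%s", k, family)
                continue
            bic = -gm.bic(x)  # sklearn minimises; flip to the mclust convention
            current = best_per_k.get(k)
            if current is None or bic > current[0]:
                best_per_k[k] = (bic, family, gm)
    if not best_per_k:
        raise NumericalError(
            "every mixture fit failed (singular covariance); consider reducing "
            "dimensionality or increasing reg_covar"
        )
    missing = [k for k in k_range if k not in best_per_k]
    if missing:
        raise NumericalError(
            f"mixture fits failed for k={missing} (singular covariance); "
            "consider reducing dimensionality"
        )
    chosen_k = max(k_range, key=lambda k: best_per_k[k][0])
    labels = best_per_k[chosen_k][2].predict(x) + 1
    table = pd.DataFrame(
        {
            "k": list(k_range),
            "best_bic": [best_per_k[k][0] for k in k_range],
            "covariance_family": [best_per_k[k][1] for k in k_range],
        }
    )
    return ClusterModelSelection(
        k_range=k_range,
        scores=tuple(best_per_k[k][0] for k in k_range),
        covariance_family_per_k=tuple(best_per_k[k][1] for k in k_range),
        chosen_k=chosen_k,
        labels=labels,
        bic_table=table,
    )


# ---------------------------------------------------------------------------
# hierarchical clustering (1 - Pearson, Ward)
# ---------------------------------------------------------------------------


def _pearson_dissimilarity(x: np.ndarray, row_ids: Sequence[str]) -> np.ndarray:
    sds = x.std(axis=1)
    if (sds == 0).any():
        bad = [row_ids[i] for i in np.flatnonzero(sds == 0)]
        raise ValidationError(
            f"constant rows (Pearson correlation undefined): {bad}"
        )
    d = 1.0 - np.corrcoef(x)
    np.fill_diagonal(d, 0.0)
    # numerical noise can push entries a hair below 0 or above 2
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def _ward_linkage_from_distance(
    d: np.ndarray, dialect: LinkageDialect
) -> np.ndarray:
    """Ward agglomeration on a precomputed dissimilarity matrix.

    ``ward.D`` applies the Lance-Williams error-sum-of-squares update to the
    dissimilarities as given (the historical hclust behaviour); ``ward.D2``
    applies it to their squares. scipy's ``linkage(..., 'ward')`` implements
    the ward.D2 recurrence, so ward.D is obtained by feeding it the square
    roots of the dissimilarities (merge order is then identical to ward.D;
    the reported heights are on the transformed scale).
    """
    condensed = squareform(d, checks=False)
    if dialect == "ward.D":
        condensed = np.sqrt(condensed)
    elif dialect != "ward.D2":
        raise ValidationError(f"unknown linkage dialect {dialect!r}")
    return linkage(condensed, method="ward")


def hierarchical_cluster(
    features,
    k: int,
    linkage_dialect: LinkageDialect = "ward.D",
) -> np.ndarray:
    """Cut a Ward tree built on 1 - Pearson dissimilarities at k clusters.

    Rows are samples. Labels are 1-based and deterministic. Because Pearson
    correlation is invariant to positive affine transforms, so is the
    partition: rescaling or shifting any row leaves the labels unchanged.
    """
    x, row_ids = _as_sample_matrix(features)
    if k < 1 or k > x.shape[0]:
        raise ValidationError(f"k must be in [1, {x.shape[0]}], got {k}")
    d = _pearson_dissimilarity(x, row_ids)
    z = _ward_linkage_from_distance(d, linkage_dialect)
    return fcluster(z, t=k, criterion="maxclust")


# ---------------------------------------------------------------------------
# K-means
# ---------------------------------------------------------------------------


def kmeans_cluster(
    features, k: int, seed: int = 0, n_restarts: int = 10
) -> np.ndarray:
    """Lloyd's K-means, best of ``n_restarts`` by within-cluster SSQ."""
    x, _ = _as_sample_matrix(features)
    if k < 1 or k > x.shape[0]:
        raise ValidationError(
            f"k must be in [1, n_samples={x.shape[0]}], got {k}"
        )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(x)
    return labels + 1


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus matrix, co-sampling counts, and the final partition."""

    sample_ids: tuple[str, ...]
    consensus: np.ndarray
    labels: np.ndarray
    co_cluster_counts: np.ndarray
    co_sample_counts: np.ndarray
    k: int
    n_resamples: int
    sample_frac: float
    feature_frac: float
    seed: int

    def consensus_frame(self) -> pd.DataFrame:
        ids = list(self.sample_ids)
        return pd.DataFrame(self.consensus, index=ids, columns=ids)

    def metadata(self) -> dict:
        return {
            "k": self.k,
            "n_resamples": self.n_resamples,
            "sample_frac": self.sample_frac,
            "feature_frac": self.feature_frac,
            "seed": self.seed,
            "n_samples": len(self.sample_ids),
        }


def consensus_cluster(
    matrix,
    k: int,
    n_resamples: int = 500,
    sample_frac: float = 0.8,
    feature_frac: float = 0.8,
    seed: int = 0,
    linkage_dialect: LinkageDialect = "ward.D",
) -> ConsensusResult:
    """Subsampled consensus clustering of a features × samples matrix.

    Each resample draws ``floor(sample_frac * n)`` samples and
    ``floor(feature_frac * p)`` features without replacement, clusters the
    subsample hierarchically (1 - Pearson, Ward) at ``k``, and accumulates
    how often each sample pair lands in the same cluster. The consensus is
    the co-cluster count divided by the co-sampling count; the final labels
    cut a Ward tree built on ``1 - consensus`` at ``k``.
    """
    if isinstance(matrix, pd.DataFrame):
        sample_ids = [str(c) for c in matrix.columns]
        x = matrix.to_numpy(dtype=float).T  # samples × features
    else:
        arr = np.asarray(matrix, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("matrix must be 2-D (features x samples)")
        x = arr.T
        sample_ids = [str(j) for j in range(x.shape[0])]
    n, p = x.shape
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValidationError(f"k={k} exceeds number of samples {n}")
    for name, frac in (("sample_frac", sample_frac), ("feature_frac", feature_frac)):
        if not 0.0 < frac <= 1.0:
            raise ValidationError(f"{name} must be in (0, 1], got {frac}")
    n_sub = max(k, math.floor(sample_frac * n + 1e-9))
    p_sub = max(1, math.floor(feature_frac * p + 1e-9))

    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((n, n), dtype=int)
    co_sample = np.zeros((n, n), dtype=int)
    for _ in range(n_resamples):
        samp = np.sort(rng.choice(n, size=n_sub, replace=False))
        feat = np.sort(rng.choice(p, size=p_sub, replace=False))
        sub_labels = hierarchical_cluster(
            x[np.ix_(samp, feat)], k, linkage_dialect=linkage_dialect
        )
        co_sample[np.ix_(samp, samp)] += 1
        same = (sub_labels[:, None] == sub_labels[None, :]).astype(int)
        co_cluster[np.ix_(samp, samp)] += same
    if (co_sample == 0).any():
        never = int((np.triu(co_sample == 0, k=1)).sum())
        raise NumericalError(
            f"{never} sample pair(s) were never co-sampled in {n_resamples} "
            "resamples; increase n_resamples or sample_frac"
        )
    consensus = co_cluster / co_sample
    consensus = np.clip((consensus + consensus.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(consensus, 1.0)
    final = fcluster(
        _ward_linkage_from_distance(1.0 - consensus, linkage_dialect),
        t=k,
        criterion="maxclust",
    )
    return ConsensusResult(
        sample_ids=tuple(sample_ids),
        consensus=consensus,
        labels=final,
        co_cluster_counts=co_cluster,
        co_sample_counts=co_sample,
        k=k,
        n_resamples=n_resamples,
        sample_frac=sample_frac,
        feature_frac=feature_frac,
        seed=seed,
    )
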