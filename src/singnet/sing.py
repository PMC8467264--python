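"""The SING transform: one network per sample, summarised by node degrees.

For each sample the method builds a graph whose nodes are annotation terms
(gene sets) rather than genes:

1. restrict the cohort to the top-variance genes (default 500);
2. mask the sample's expression vector by set membership, giving a
   genes × annotations profile matrix ``M`` where ``M[p, q]`` is the
   expression of gene ``p`` if ``p`` belongs to set ``q`` and exactly 0
   otherwise;
3. compute the annotation × annotation matrix ``A`` of Euclidean distances
   between profile columns;
4. keep the top fraction of edges by weight (default 10% of the
   ``Q(Q-1)/2`` candidate pairs) to obtain a binary adjacency matrix;
5. record each node's degree.

Stacking the per-sample degree vectors yields a samples × annotations
integer feature matrix, the input to subtype clustering. The transform is
fully deterministic, and because step 4 thresholds on distance *ranks*,
each sample's network is invariant to positive rescaling of that sample's
expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
    select_top_variance_genes,
)

logger = logging.getLogger("singnet")

EdgeRule = Literal["largest_distance", "smallest_distance"]

__all__ = [
    "SampleProfileMatrix",
    "SampleNetwork",
    "DegreeFeatureMatrix",
    "build_sample_profile",
    "annotation_distance_matrix",
    "threshold_top_edges",
    "degree_vector",
    "sing_transform",
]


@dataclass(frozen=True)
class SampleProfileMatrix:
    """Per-sample genes × annotations matrix of membership-masked expression."""

    sample_id: str
    gene_ids: tuple[str, ...]
    set_names: tuple[str, ...]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.set_names)
        )


@dataclass(frozen=True)
class SampleNetwork:
    """One sample's annotation network.

    ``distances`` is the symmetric Euclidean distance matrix between
    annotation profiles; ``adjacency`` the binary matrix after rank
    thresholding at ``edge_fraction`` under ``edge_rule``.
    """

    sample_id: str
    set_names: tuple[str, ...]
    distances: np.ndarray
    adjacency: np.ndarray
    edge_fraction: float
    edge_rule: str

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, k=1).sum())

    def edge_list(self) -> pd.DataFrame:
        """Edges as a table with columns node_a, node_b, distance."""
        rows = []
        q = len(self.set_names)
        for i in range(q):
            for j in range(i + 1, q):
                if self.adjacency[i, j]:
                    rows.append(
                        (self.set_names[i], self.set_names[j], self.distances[i, j])
                    )
        return pd.DataFrame(rows, columns=["node_a", "node_b", "distance"])


@dataclass(frozen=True)
class DegreeFeatureMatrix:
    """Samples × annotations matrix of node degrees; the clustering input."""

    sample_ids: tuple[str, ...]
    set_names: tuple[str, ...]
    degrees: np.ndarray

    def __post_init__(self) -> None:
        degrees = np.asarray(self.degrees)
        if not np.issubdtype(degrees.dtype, np.integer):
            if not np.array_equal(degrees, degrees.astype(int)):
                raise ValidationError("degrees must be integer-valued")
            degrees = degrees.astype(int)
        object.__setattr__(self, "degrees", degrees)
        if degrees.shape != (len(self.sample_ids), len(self.set_names)):
            raise ValidationError("degree matrix shape mismatch")
        if (degrees < 0).any() or (degrees > len(self.set_names) - 1).any():
            raise ValidationError("degrees outside [0, Q-1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.degrees, index=list(self.sample_ids), columns=list(self.set_names)
        )


def build_sample_profile(
    expr_column: pd.Series, sets: GeneSetCollection
) -> SampleProfileMatrix:
    """Mask one sample's expression vector by gene-set membership.

    Entry ``(p, q)`` holds the sample's expression of gene ``p`` when ``p``
    is a member of set ``q`` and exactly 0 otherwise. Sets with no member
    among the supplied genes yield all-zero columns (retained so the node
    universe is identical across samples).
    """
    if len(sets) == 0:
        raise ValidationError("gene-set collection is empty")
    gene_ids = tuple(map(str, expr_column.index))
    mask = sets.membership_mask(gene_ids)
    if not mask.any():
        raise ValidationError(
            "annotation/gene universe disjoint: no gene set has any member "
            "among the selected genes"
        )
    values = expr_column.to_numpy(dtype=float)[:, None] * mask
    return SampleProfileMatrix(
        sample_id=str(expr_column.name),
        gene_ids=gene_ids,
        set_names=sets.set_names,
        values=values,
    )


def annotation_distance_matrix(profile: SampleProfileMatrix) -> np.ndarray:
    """Euclidean distances between annotation profile columns.

    Equivalently (and used as a cross-check in the test suite), the squared
    distance between sets ``q`` and ``q*`` is the sum of squared expression
    over genes belonging to exactly one of the two sets: genes in both sets
    contribute identical coordinates and cancel.
    """
    if profile.values.shape[1] < 2:
        raise ValidationError("need at least 2 annotations to build a network")
    distances = squareform(pdist(profile.values.T, metric="euclidean"))
    np.fill_diagonal(distances, 0.0)
    return distances


def _validate_square_symmetric(matrix: np.ndarray, what: str) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError(f"{what} must be square")
    if not np.allclose(matrix, matrix.T, rtol=0.0, atol=1e-8):
        raise ValidationError(f"{what} must be symmetric")
    return matrix


def threshold_top_edges(
    distances: np.ndarray,
    fraction: float,
    rule: EdgeRule = "largest_distance",
) -> np.ndarray:
    """Keep the top fraction of candidate edges by weight.

    Of the ``m = Q(Q-1)/2`` node pairs, exactly ``k = max(1, floor(fraction
    * m))`` edges are retained, ranked by distance according to ``rule``
    (``largest_distance`` keeps the heaviest edges). Ties at the cutoff are
    broken by ascending node-index pair, which makes the selection
    deterministic on any platform.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"edge fraction must be in (0, 1], got {fraction}")
    if rule not in ("largest_distance", "smallest_distance"):
        raise ValidationError(f"unknown edge rule {rule!r}")
    distances = _validate_square_symmetric(distances, "distance matrix")
    q = distances.shape[0]
    if q < 2:
        raise ValidationError("need at least 2 nodes")
    iu, ju = np.triu_indices(q, k=1)
    weights = distances[iu, ju]
    m = len(weights)
    # tiny nudge guards binary-float artifacts such as 0.3 * 10 = 2.999...96
    k = max(1, math.floor(fraction * m + 1e-9))
    key = -weights if rule == "largest_distance" else weights
    order = np.lexsort((ju, iu, key))
    keep = order[:k]
    adjacency = np.zeros((q, q), dtype=int)
    adjacency[iu[keep], ju[keep]] = 1
    adjacency += adjacency.T
    return adjacency


def degree_vector(adjacency: np.ndarray) -> np.ndarray:
    """Number of neighbours of each node."""
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.array_equal(adjacency, adjacency.T):
        raise ValidationError("adjacency must be symmetric")
    if not np.isin(adjacency, (0, 1)).all():
        raise ValidationError("adjacency must be binary")
    if np.diag(adjacency).any():
        raise ValidationError("adjacency must have zero diagonal")
    return adjacency.sum(axis=0).astype(int)


def sing_transform(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    n_top_genes: int = 500,
    edge_fraction: float = 0.10,
    rule: EdgeRule = "largest_distance",
    return_networks: bool = False,
) -> DegreeFeatureMatrix | tuple[DegreeFeatureMatrix, list[SampleNetwork]]:
    """Run the full per-sample network transform over a cohort.

    Feature selection happens once on the cohort; the profile → distance →
    threshold → degree chain then runs independently per sample. Returns
    the samples × annotations degree matrix, plus the per-sample networks
    when ``return_networks`` is set.
    """
    selected = select_top_variance_genes(expr, n_top_genes)
    mask = sets.membership_mask(selected.gene_ids)
    if not mask.any():
        raise ValidationError(
            "annotation/gene universe disjoint: no gene set has any member "
            "among the selected genes"
        )
    empty = [name for name, hit in zip(sets.set_names, mask.any(axis=0)) if not hit]
    if empty:
        logger.info(
            "%d annotation(s) have no member among the %d selected genes and "
            "form all-zero columns: %s",
            len(empty), selected.n_genes, empty,
        )
    q = len(sets)
    degrees = np.zeros((selected.n_samples, q), dtype=int)
    networks: list[SampleNetwork] = []
    for j, sample_id in enumerate(selected.sample_ids):
        profile = SampleProfileMatrix(
            sample_id=sample_id,
            gene_ids=selected.gene_ids,
            set_names=sets.set_names,
            values=selected.values[:, j][:, None] * mask,
        )
        distances = annotation_distance_matrix(profile)
        adjacency = threshold_top_edges(distances, edge_fraction, rule)
        degrees[j] = degree_vector(adjacency)
        if return_networks:
            networks.append(
                SampleNetwork(
                    sample_id=sample_id,
                    set_names=sets.set_names,
                    distances=distances,
                    adjacency=adjacency,
                    edge_fraction=edge_fraction,
                    edge_rule=rule,
                )
            )
    features = DegreeFeatureMatrix(
        sample_ids=selected.sample_ids, set_names=sets.set_names, degrees=degrees
    )
    if return_networks:
        return features, networks
    return features
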