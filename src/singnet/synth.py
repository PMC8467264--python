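"""Synthetic cohorts with planted subtype structure.

The generator stands in for real expression cohorts so every stage of the
pipeline can be exercised without downloads. It emulates:

* a genes × samples expression matrix with log-normal baseline expression
  (each gene has a log2-scale mean drawn once; samples add Gaussian noise
  on the log2 scale and values are returned as ``2**log2``),
* a gene-set collection with controlled pairwise overlap (the shape of an
  immunologic-signature database), and
* planted sample groups whose signal lives at the *gene-set* level: each
  group up-shifts the member genes of a few designated "informative" sets
  by a fixed log2 effect. Set-level shifts — not random marker genes — are
  what degree features of annotation networks can detect, which is the
  premise of the method.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import ExpressionMatrix, GeneSetCollection, ValidationError

__all__ = ["SyntheticCohortSpec", "generate_gmt", "generate_cohort"]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a planted-structure cohort.

    Defaults describe a small three-group melanoma-like cohort: 1000 genes
    (so a top-500 variance cut is an active filter), 60 samples in equal
    groups, 30 gene sets of 20-40 genes with mild (Jaccard 0.1) overlap,
    4 informative sets per group shifted by 2 log2 units (a fourfold
    change), and within-group log2 noise of 0.5. Thirty sets give each
    sample network floor(0.1 * 435) = 43 edges, a degree space rich enough
    for set-level shifts to register as more than a handful of discrete
    patterns.
    """

    n_genes: int = 1000
    n_samples: int = 60
    n_groups: int = 3
    group_proportions: tuple[float, ...] | None = None
    n_sets: int = 30
    set_size_range: tuple[int, int] = (20, 40)
    set_overlap: float = 0.1
    n_informative_sets_per_group: int = 4
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1 or self.n_groups < 1:
            raise ValidationError("n_genes, n_samples, n_groups must be >= 1")
        if self.group_proportions is not None:
            props = tuple(float(p) for p in self.group_proportions)
            if len(props) != self.n_groups:
                raise ValidationError("one proportion per group required")
            if any(p <= 0 for p in props) or not math.isclose(sum(props), 1.0):
                raise ValidationError("group proportions must be positive and sum to 1")
            object.__setattr__(self, "group_proportions", props)
        lo, hi = self.set_size_range
        if lo < 2 or hi < lo:
            raise ValidationError("set sizes must be >= 2 with lo <= hi")
        if not 0.0 <= self.set_overlap < 1.0:
            raise ValidationError("set_overlap must be in [0, 1)")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_informative_sets_per_group * self.n_groups > self.n_sets:
            raise ValidationError(
                "not enough gene sets to assign informative sets to every group"
            )


def generate_gmt(
    n_sets: int,
    size_range: tuple[int, int],
    universe: Sequence[str],
    overlap: float = 0.0,
    seed: int = 0,
) -> GeneSetCollection:
    """Sample gene sets with controlled pairwise Jaccard overlap.

    A shared core of genes is placed in every set; the rest of each set is
    drawn disjointly. For sets of mean size ``s`` and core size ``c`` the
    pairwise Jaccard index is ``c / (2s - c)``, so the core size is chosen
    as ``round(2 s J / (1 + J))`` to hit the requested overlap ``J``.
    ``overlap = 0`` yields pairwise disjoint sets.
    """
    if n_sets < 1:
        raise ValidationError("n_sets must be >= 1")
    lo, hi = size_range
    if lo < 2 or hi < lo:
        raise ValidationError("set sizes must be >= 2 with lo <= hi")
    if not 0.0 <= overlap < 1.0:
        raise ValidationError("overlap must be in [0, 1)")
    universe = [str(g) for g in universe]
    if len(set(universe)) != len(universe):
        raise ValidationError("gene universe contains duplicates")
    rng = np.random.default_rng(seed)
    sizes = rng.integers(lo, hi + 1, size=n_sets)
    mean_size = float(sizes.mean())
    core_size = int(round(2.0 * mean_size * overlap / (1.0 + overlap)))
    core_size = min(core_size, int(sizes.min()) - 1) if n_sets > 1 else 0
    core_size = max(core_size, 0)
    needed = core_size + int((sizes - core_size).sum())
    if needed > len(universe):
        raise ValidationError(
            f"universe of {len(universe)} genes too small: need {needed} for "
            f"{n_sets} sets of sizes {lo}-{hi} at overlap {overlap}"
        )
    pool = rng.permutation(len(universe))
    core = [universe[i] for i in pool[:core_size]]
    cursor = core_size
    set_names = []
    members = {}
    descriptions = {}
    for s in range(n_sets):
        own = int(sizes[s]) - core_size
        genes = core + [universe[i] for i in pool[cursor : cursor + own]]
        cursor += own
        name = f"SYN_SIG_{s + 1:03d}"
        set_names.append(name)
        members[name] = tuple(genes)
        descriptions[name] = "synthetic immunologic signature"
    return GeneSetCollection(
        set_names=tuple(set_names), members=members, descriptions=descriptions
    )


def _group_sizes(n_samples: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of samples to groups."""
    raw = [p * n_samples for p in proportions]
    sizes = [math.floor(r) for r in raw]
    remainder = n_samples - sum(sizes)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in order[:remainder]:
        sizes[i] += 1
    if any(s == 0 for s in sizes):
        raise ValidationError("a group received zero samples; adjust proportions")
    return sizes


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[ExpressionMatrix, GeneSetCollection, np.ndarray]:
    """Generate (expression, gene sets, true labels) with planted groups.

    Baseline expression is log-normal: gene ``p`` has a log2 mean drawn
    from ``N(baseline_log2_mean, baseline_log2_sd)``; each sample adds
    ``N(0, noise_sd)`` log2 noise. Samples of group ``g`` have the member
    genes of the group's informative sets shifted up by ``effect_size``
    log2 units. Returned labels are 1-based group indices.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    samples = [f"S{j + 1:04d}" for j in range(spec.n_samples)]
    sets = generate_gmt(
        n_sets=spec.n_sets,
        size_range=spec.set_size_range,
        universe=genes,
        overlap=spec.set_overlap,
        seed=int(rng.integers(2**31)),
    )
    proportions = spec.group_proportions or tuple(
        1.0 / spec.n_groups for _ in range(spec.n_groups)
    )
    sizes = _group_sizes(spec.n_samples, proportions)
    labels = np.repeat(np.arange(1, spec.n_groups + 1), sizes)

    # informative sets: disjoint blocks of a seeded permutation of set names
    per = spec.n_informative_sets_per_group
    set_order = rng.permutation(spec.n_sets)
    informative = {
        g + 1: [sets.set_names[i] for i in set_order[g * per : (g + 1) * per]]
        for g in range(spec.n_groups)
    }

    gene_index = {g: i for i, g in enumerate(genes)}
    base = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_genes)
    log2 = base[:, None] + rng.normal(0.0, spec.noise_sd, (spec.n_genes, spec.n_samples))
    if spec.effect_size > 0:
        for g in range(1, spec.n_groups + 1):
            shifted = sorted(
                {gene_index[m] for name in informative[g] for m in sets.members[name]}
            )
            cols = np.flatnonzero(labels == g)
            log2[np.ix_(shifted, cols)] += spec.effect_size
    expr = ExpressionMatrix(
        gene_ids=tuple(genes), sample_ids=tuple(samples), values=2.0**log2
    )
    return expr, sets, labels
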