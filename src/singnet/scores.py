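"""Per-sample immune scores and the differential-expression signature filter.

* :func:`cytolytic_activity` — geometric mean of the expression of two
  cytotoxic effector genes (granzyme A and perforin 1 by default), a
  standard proxy for tumour immunogenicity.
* :func:`purity_adjust` — rescales a per-sample score by ``1 / (1 - tumour
  purity)`` so that scores reflect the non-tumour compartment.
* :func:`de_signature_filter` — thresholds an externally computed
  differential-expression table into up- and down-regulated signatures
  (fold change >= 2 with FDR < 0.05, and fold change <= 1/2 with
  FDR < 0.05, by default). The differential model fit itself is out of
  scope; only the thresholding rule lives here.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

__all__ = [
    "DETable",
    "ScoreVector",
    "cytolytic_activity",
    "purity_adjust",
    "de_signature_filter",
]


@dataclass(frozen=True)
class ScoreVector:
    """One real-valued score per sample."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    score_name: str
    metadata: dict = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "metadata", dict(self.metadata or {}))
        if values.shape != (len(self.sample_ids),):
            raise ValidationError("one score per sample required")
        if not np.isfinite(values).all():
            raise ValidationError("scores must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.values, index=list(self.sample_ids), name=self.score_name
        )


@dataclass(frozen=True)
class DETable:
    """Differential-expression results: gene, log2 fold change, FDR."""

    gene_ids: tuple[str, ...]
    log2_fold_change: np.ndarray
    fdr: np.ndarray

    def __post_init__(self) -> None:
        l2fc = np.asarray(self.log2_fold_change, dtype=float)
        fdr = np.asarray(self.fdr, dtype=float)
        object.__setattr__(self, "log2_fold_change", l2fc)
        object.__setattr__(self, "fdr", fdr)
        n = len(self.gene_ids)
        if l2fc.shape != (n,) or fdr.shape != (n,):
            raise ValidationError("log2_fold_change and fdr must match gene_ids")
        if not np.isfinite(l2fc).all():
            raise ValidationError("log2 fold changes must be finite")
        if ((fdr < 0) | (fdr > 1)).any() or not np.isfinite(fdr).all():
            raise ValidationError("FDR values must lie in [0, 1]")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DETable":
        cols = {c.lower(): c for c in frame.columns}
        try:
            gene_col = cols.get("gene", cols.get("gene_id"))
            l2fc_col = cols.get("log2foldchange", cols.get("log2_fold_change", cols.get("log2fc")))
            fdr_col = cols.get("fdr", cols.get("padj"))
            return cls(
                gene_ids=tuple(map(str, frame[gene_col])),
                log2_fold_change=frame[l2fc_col].to_numpy(dtype=float),
                fdr=frame[fdr_col].to_numpy(dtype=float),
            )
        except (KeyError, TypeError):
            raise ValidationError(
                "DE table needs columns gene, log2FoldChange (or log2fc) and "
                f"fdr (or padj); found {list(frame.columns)}"
            ) from None


def cytolytic_activity(
    expr: ExpressionMatrix,
    gene_a: str = "GZMA",
    gene_b: str = "PRF1",
    offset: float = 0.01,
) -> ScoreVector:
    """Geometric mean of two effector genes per sample.

    Computes ``sqrt((e_a + offset) * (e_b + offset))``. The offset guards
    against zero expression (offset 0 reproduces the plain geometric mean)
    and is recorded in the output metadata. Symmetric in the two genes and
    monotone increasing in each.
    """
    if offset < 0:
        raise ValidationError(f"offset must be >= 0, got {offset}")
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = []
    for gene in (gene_a, gene_b):
        if gene not in index:
            near = difflib.get_close_matches(gene, expr.gene_ids, n=3)
            hint = f"; similar identifiers: {near}" if near else ""
            raise ValidationError(f"gene {gene!r} not in expression matrix{hint}")
        rows.append(expr.values[index[gene]])
    e_a, e_b = rows
    if (e_a < 0).any() or (e_b < 0).any():
        raise ValidationError(
            "cytolytic activity needs non-negative expression values"
        )
    values = np.sqrt((e_a + offset) * (e_b + offset))
    return ScoreVector(
        sample_ids=expr.sample_ids,
        values=values,
        score_name="cytolytic_activity",
        metadata={"gene_a": gene_a, "gene_b": gene_b, "offset": offset},
    )


def purity_adjust(score: ScoreVector, purity) -> ScoreVector:
    """Rescale scores by ``1 / (1 - tumour purity)``.

    ``purity`` is a per-sample vector (array or sample-indexed series) with
    values in ``[0, 1)``; purity 1 would divide by zero and is an error.
    """
    if isinstance(purity, pd.Series):
        missing = [s for s in score.sample_ids if s not in purity.index]
        if missing:
            raise ValidationError(f"purity missing for samples: {missing}")
        purity = purity.loc[list(score.sample_ids)].to_numpy(dtype=float)
    else:
        purity = np.asarray(purity, dtype=float)
    if purity.shape != (len(score.sample_ids),):
        raise ValidationError("one purity value per sample required")
    if ((purity < 0) | (purity > 1)).any() or not np.isfinite(purity).all():
        raise ValidationError("purity values must lie in [0, 1)")
    if (purity >= 1).any():
        bad = [score.sample_ids[i] for i in np.flatnonzero(purity >= 1)]
        raise ValidationError(
            f"purity of 1 makes the adjustment score/(1-purity) undefined "
            f"for samples: {bad}"
        )
    values = score.values / (1.0 - purity)
    meta = dict(score.metadata)
    meta["purity_adjusted"] = True
    return ScoreVector(
        sample_ids=score.sample_ids,
        values=values,
        score_name=f"{score.score_name}_purity_adjusted",
        metadata=meta,
    )


def de_signature_filter(
    table: DETable,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    fdr_max: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Split a DE table into up- and down-regulated gene signatures.

    Up-regulated: fold change >= ``fc_up`` (boundary included) and
    FDR strictly below ``fdr_max``. Down-regulated: fold change <=
    ``fc_down`` and FDR strictly below ``fdr_max``. Comparisons are made in
    log2 space so the printed boundary (fold change exactly 2) is included
    exactly.
    """
    if fc_up <= 0 or fc_down <= 0:
        raise ValidationError("fold-change thresholds must be positive")
    if fc_down >= fc_up:
        raise ValidationError(
            f"fc_down ({fc_down}) must be below fc_up ({fc_up})"
        )
    if not 0 < fdr_max <= 1:
        raise ValidationError(f"fdr_max must be in (0, 1], got {fdr_max}")
    l2fc = table.log2_fold_change
    sig = table.fdr < fdr_max
    up_mask = sig & (l2fc >= np.log2(fc_up))
    down_mask = sig & (l2fc <= np.log2(fc_down))
    genes = np.asarray(table.gene_ids, dtype=object)
    return list(genes[up_mask]), list(genes[down_mask])
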