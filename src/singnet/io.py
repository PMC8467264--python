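"""Reading, writing and cohort-level feature selection.

Two container types underpin the whole pipeline:

* :class:`ExpressionMatrix` — a labelled genes × samples matrix. Units are
  whatever the caller provides (counts, TPM, log scale); nothing in the
  package assumes a particular normalisation.
* :class:`GeneSetCollection` — named gene sets ("annotation terms"), the
  node universe of every sample network. The standard interchange format
  is GMT (tab-separated: name, description, member genes).

Gene identifiers are matched by exact, case-sensitive string comparison
between expression rows and gene-set members; no symbol aliasing is
performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("singnet")

__all__ = [
    "SingnetError",
    "ValidationError",
    "NumericalError",
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "select_top_variance_genes",
]


class SingnetError(Exception):
    """Base class for all package errors."""


class ValidationError(SingnetError):
    """Invalid input data or parameters."""


class NumericalError(SingnetError):
    """A numerical procedure failed (singular model, degenerate data)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Labelled genes × samples expression matrix.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))`` with all
        entries finite.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(map(str, frame.index)),
            sample_ids=tuple(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
        )

    def sample_column(self, sample_id: str) -> pd.Series:
        """Expression of one sample as a gene-labelled series."""
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample {sample_id!r}") from None
        return pd.Series(self.values[:, j], index=list(self.gene_ids), name=sample_id)


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered collection of named gene sets (annotation terms).

    ``members`` maps each set name to its member genes in file order with
    duplicates removed. Membership queries are exact and case-sensitive.
    """

    set_names: tuple[str, ...]
    members: Mapping[str, tuple[str, ...]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.set_names)
        object.__setattr__(self, "set_names", names)
        if len(set(names)) != len(names):
            raise ValidationError("duplicate gene-set names")
        members = {str(k): tuple(map(str, v)) for k, v in self.members.items()}
        object.__setattr__(self, "members", members)
        for name in names:
            if name not in members:
                raise ValidationError(f"set {name!r} has no member list")
            if len(members[name]) == 0:
                raise ValidationError(f"set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.set_names)

    def __iter__(self):
        return iter(self.set_names)

    def membership_mask(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Boolean genes × sets mask over the given gene universe."""
        index = {g: i for i, g in enumerate(gene_ids)}
        mask = np.zeros((len(gene_ids), len(self.set_names)), dtype=bool)
        for q, name in enumerate(self.set_names):
            for g in self.members[name]:
                i = index.get(g)
                if i is not None:
                    mask[i, q] = True
        return mask


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a genes × samples expression table.

    The first row is the sample header and the first column holds gene
    identifiers. The delimiter defaults to tab, or comma for ``.csv`` files.

    Duplicate gene rows are collapsed by keeping the row with the highest
    across-sample variance (logged). Duplicate sample columns and
    non-numeric cells are errors.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"expression file not found: {path}")
    sep = _infer_delimiter(path, delimiter)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").rstrip("\r").split(sep)[1:]
    seen: set[str] = set()
    dups = sorted({name for name in header if name in seen or seen.add(name)})
    if dups:
        raise ValidationError(f"{path}: duplicate sample identifiers: {dups}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")

    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at "
            f"gene {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    frame = numeric.astype(float)
    frame.index = frame.index.map(str)

    if frame.index.duplicated().any():
        if frame.shape[1] < 2:
            # variance undefined with one sample; keep first occurrence
            frame = frame[~frame.index.duplicated(keep="first")]
        else:
            variances = frame.var(axis=1, ddof=1)
            order = np.arange(len(frame))
            keep = (
                pd.DataFrame({"var": variances.to_numpy(), "order": order}, index=frame.index)
                .groupby(level=0, sort=False)
                .apply(lambda g: g["order"][g["var"] == g["var"].max()].iloc[0])
            )
            dup_names = sorted(set(frame.index[frame.index.duplicated()]))
            logger.info(
                "collapsed %d duplicate gene rows by max variance: %s",
                len(dup_names), dup_names,
            )
            frame = frame.iloc[np.sort(keep.to_numpy())]
    if not np.isfinite(frame.to_numpy()).all():
        raise ValidationError(f"{path}: expression matrix contains non-finite values")
    return ExpressionMatrix.from_frame(frame)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write an expression matrix as a delimited text table (full precision)."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    # str() of a float64 round-trips exactly under Python 3 repr rules
    expr.to_frame().to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file.

    Each non-blank line must have at least three tab-separated fields:
    set name, description, then one or more member genes. Duplicate genes
    within a set are dropped (first occurrence kept); duplicate set names
    are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"GMT file not found: {path}")
    set_names: list[str] = []
    members: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValidationError(f"{path}: line {lineno}: set {name!r} is empty")
            if name in members:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate set name {name!r}"
                )
            set_names.append(name)
            members[name] = genes
            descriptions[name] = description
    if not set_names:
        raise ValidationError(f"{path}: no gene sets found")
    return GeneSetCollection(
        set_names=tuple(set_names), members=members, descriptions=descriptions
    )


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    """Write a gene-set collection in GMT format."""
    with open(path, "w") as handle:
        for name in sets.set_names:
            desc = sets.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *sets.members[name]]) + "\n")


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


def gene_variances(expr: ExpressionMatrix) -> np.ndarray:
    """Per-gene across-sample unbiased variance (denominator n-1)."""
    if expr.n_samples < 2:
        raise ValidationError(
            "variance is undefined for a single-sample matrix (need >=2 samples)"
        )
    return expr.values.var(axis=1, ddof=1)


def select_top_variance_genes(expr: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the ``n`` genes with the largest across-sample variance.

    Rows of the result are ordered by decreasing variance; ties at the
    cutoff are broken by input row order (earlier row wins). If the matrix
    has fewer than ``n`` genes, all are returned with a warning.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    variances = gene_variances(expr)
    # stable sort on the negated variances keeps input order among ties
    order = np.argsort(-variances, kind="stable")
    if expr.n_genes < n:
        logger.warning(
            "requested top %d genes but matrix has only %d; keeping all",
            n, expr.n_genes,
        )
        n = expr.n_genes
    keep = order[:n]
    return ExpressionMatrix(
        gene_ids=tuple(expr.gene_ids[i] for i in keep),
        sample_ids=expr.sample_ids,
        values=expr.values[keep],
    )
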