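"""Gene-by-sample expression matrices and their on-disk TSV representation.

The central container is :class:`ExpressionMatrix`, a thin validated wrapper
around a pandas DataFrame of log2 expression values (rows = genes, columns =
samples) with an optional per-gene annotation table (symbol, chromosome).
All downstream stages (filtering, differential expression, scoring) consume
this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression", "read_annotation"]

ANNOTATION_COLUMNS = ("symbol", "chromosome")


@dataclass
class ExpressionMatrix:
    """Log2 expression values for genes (rows) across samples (columns).

    Parameters
    ----------
    values
        DataFrame of finite floats; index holds unique gene identifiers,
        columns hold unique sample identifiers.
    annotation
        Optional per-gene table with at least a ``symbol`` column and
        optionally a ``chromosome`` column, indexed by gene identifier.
        Only rows for genes present in ``values`` are retained.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        values = pd.DataFrame(self.values).astype(float)
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        if not np.isfinite(values.to_numpy()).all():
            bad = values.index[~np.isfinite(values).all(axis=1)].tolist()
            raise ValueError(f"non-finite expression values in genes: {bad[:5]}")
        values.index.name = None
        values.columns.name = None
        self.values = values
        if self.annotation is not None:
            ann = pd.DataFrame(self.annotation)
            if "symbol" not in ann.columns:
                raise ValueError("annotation must have a 'symbol' column")
            self.annotation = ann.reindex(values.index)

    # -- basic introspection ------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ann = "with" if self.annotation is not None else "without"
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"{ann} annotation)"
        )

    # -- subsetting ---------------------------------------------------------
    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``genes`` (order preserved)."""
        genes = pd.Index(genes)
        missing = genes.difference(self.genes)
        if len(missing):
            raise KeyError(f"genes absent from matrix: {missing[:5].tolist()}")
        ann = self.annotation.loc[genes] if self.annotation is not None else None
        return ExpressionMatrix(self.values.loc[genes], ann)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        missing = samples.difference(self.samples)
        if len(missing):
            raise KeyError(f"samples absent from matrix: {missing[:5].tolist()}")
        return ExpressionMatrix(self.values[samples], self.annotation)

    # -- serialization ------------------------------------------------------
    def to_tsv(self, path: str | Path, annotation_path: str | Path | None = None) -> None:
        """Write the matrix (and optionally its annotation) as TSV."""
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.6g")
        if annotation_path is not None:
            if self.annotation is None:
                raise ValueError("matrix carries no annotation to write")
            ann = self.annotation.copy()
            ann.index.name = "gene"
            ann.to_csv(annotation_path, sep="\t")


def read_expression(path: str | Path, annotation: str | Path | None = None) -> ExpressionMatrix:
    """Read a gene x sample TSV (gene IDs in column 1, sample IDs in header).

    Errors name the offending line/sample: duplicated sample columns,
    non-numeric cells and ragged rows are all rejected.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    counts = pd.Series(header).value_counts()
    dupes = counts.index[counts > 1].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated sample column(s): {dupes}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.isna().any().any():
        rows = np.where(raw.isna().any(axis=1))[0]
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: ragged or missing cells at line(s) {[int(r) + 2 for r in rows[:5]]}")
    try:
        values = raw.astype(float)
    except ValueError:
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        rows = np.where(numeric.isna().any(axis=1))[0]
        raise ValueError(
            f"{path}: non-numeric cell(s) at line(s) {[int(r) + 2 for r in rows[:5]]}"
        ) from None
    ann = read_annotation(annotation) if annotation is not None else None
    return ExpressionMatrix(values, ann)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV: columns gene, symbol[, chromosome]."""
    ann = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "symbol" not in ann.columns:
        raise ValueError(f"{path}: annotation requires a 'symbol' column")
    return ann
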