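"""Matrix-level gene filters applied before differential expression.

Three filters, applied in this order by :func:`preprocess_matrix`:

1. presence filter — keep genes detected (log2 value at or above a
   detection threshold) in at least a minimum fraction of samples
   (default two thirds);
2. annotation deduplication — keep only uniquely annotated genes
   (strict mode drops every row of a duplicated symbol; collapse mode keeps
   the highest-mean row);
3. sex-chromosome removal — drop genes annotated to chromosome X or Y.

Each filter returns a :class:`FilterReport` whose removal counts always sum
to input minus output genes; none of them ever touches the sample dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "FilterReport",
    "presence_filter",
    "dedup_annotations",
    "drop_sex_chromosomes",
    "preprocess_matrix",
]

DEFAULT_MIN_FRACTION = 2.0 / 3.0
_EPS = 1e-12  # guards the inclusive boundary against float rounding of fractions


@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    n_in: int
    n_out: int
    removed: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.removed.values()) != self.n_in - self.n_out:
            raise ValueError("filter report inconsistent: removals != n_in - n_out")

    def merged_with(self, other: "FilterReport") -> "FilterReport":
        if other.n_in != self.n_out:
            raise ValueError("cannot chain reports: gene counts do not line up")
        removed = dict(self.removed)
        removed.update(other.removed)
        params = dict(self.params)
        params.update(other.params)
        return FilterReport(self.n_in, other.n_out, removed, params)


def _normalize_chromosome(label) -> str | None:
    """Map chromosome-name dialects onto a canonical label.

    'chrX' / 'X' / '23' all become 'X'; '24' becomes 'Y'; other labels are
    upper-cased with any 'chr' prefix stripped. Missing values return None.
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return None
    s = str(label).strip()
    if not s or s.lower() in ("nan", "na"):
        return None
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s == "23":
        return "X"
    if s == "24":
        return "Y"
    return s


def presence_filter(
    matrix: ExpressionMatrix,
    detection_threshold: float | None = None,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes detected in at least ``min_fraction`` of samples.

    A gene is "detected" in a sample when its log2 value is at or above
    ``detection_threshold``. When no threshold is given it defaults to the
    10th percentile of all values in the matrix (recorded in the report).
    The fraction boundary is inclusive: 2 detected out of 3 samples passes
    min_fraction = 2/3.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValueError("cannot presence-filter an empty matrix")
    values = matrix.values.to_numpy()
    if detection_threshold is None:
        detection_threshold = float(np.quantile(values, 0.10))
    detected_frac = (values >= detection_threshold).mean(axis=1)
    keep = detected_frac >= min_fraction - _EPS
    out = ExpressionMatrix(
        matrix.values.loc[keep],
        matrix.annotation.loc[keep] if matrix.annotation is not None else None,
    )
    report = FilterReport(
        n_in=matrix.n_genes,
        n_out=out.n_genes,
        removed={"presence": int((~keep).sum())},
        params={"detection_threshold": detection_threshold, "min_fraction": min_fraction},
    )
    return out, report


def dedup_annotations(
    matrix: ExpressionMatrix, mode: str = "strict"
) -> tuple[ExpressionMatrix, FilterReport]:
    """Restrict to uniquely annotated genes and relabel rows by symbol.

    ``strict`` removes every row whose symbol maps to more than one row (and
    rows with no symbol at all); ``collapse`` instead keeps the row with the
    highest mean expression per symbol. After deduplication symbols are
    unique, so the gene index is replaced by the symbol — downstream stages
    identify genes by symbol.
    """
    if matrix.annotation is None:
        raise ValueError("deduplication requires a gene annotation with symbols")
    if mode not in ("strict", "collapse"):
        raise ValueError(f"unknown dedup mode: {mode!r}")
    symbols = matrix.annotation["symbol"]
    has_symbol = symbols.notna() & (symbols.astype(str).str.strip() != "")
    counts = symbols[has_symbol].value_counts()

    if mode == "strict":
        unique_syms = counts[counts == 1].index
        keep = has_symbol & symbols.isin(unique_syms)
    else:
        means = matrix.values.mean(axis=1)
        keep = pd.Series(False, index=matrix.genes)
        # per symbol keep the argmax-mean row
        best = (
            pd.DataFrame({"symbol": symbols[has_symbol], "mean": means[has_symbol]})
            .reset_index(names="gene")
            .sort_values(["symbol", "mean"], kind="stable")
            .groupby("symbol", sort=False)
            .tail(1)["gene"]
        )
        keep.loc[best] = True

    values = matrix.values.loc[keep]
    ann = matrix.annotation.loc[keep]
    values = values.set_axis(ann["symbol"].astype(str), axis=0)
    ann = ann.set_axis(ann["symbol"].astype(str), axis=0)
    out = ExpressionMatrix(values, ann)
    report = FilterReport(
        n_in=matrix.n_genes,
        n_out=out.n_genes,
        removed={"duplicate_annotation": int((~keep).sum())},
        params={"dedup_mode": mode},
    )
    return out, report


def drop_sex_chromosomes(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove genes annotated to chromosome X or Y.

    A missing chromosome annotation is an explicit error, never a silent
    pass-through; genes whose chromosome value is blank are kept (they are
    not annotated *to* X/Y).
    """
    if matrix.annotation is None or "chromosome" not in matrix.annotation.columns:
        raise ValueError("sex-chromosome removal requires a 'chromosome' annotation column")
    chroms = matrix.annotation["chromosome"].map(_normalize_chromosome)
    keep = ~chroms.isin(["X", "Y"])
    out = ExpressionMatrix(matrix.values.loc[keep], matrix.annotation.loc[keep])
    report = FilterReport(
        n_in=matrix.n_genes,
        n_out=out.n_genes,
        removed={"sex_chromosome": int((~keep).sum())},
    )
    return out, report


def preprocess_matrix(
    matrix: ExpressionMatrix,
    detection_threshold: float | None = None,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    dedup_mode: str = "strict",
) -> tuple[ExpressionMatrix, FilterReport]:
    """Apply presence filter, deduplication and sex-chromosome removal in order."""
    m1, r1 = presence_filter(matrix, detection_threshold, min_fraction)
    m2, r2 = dedup_annotations(m1, mode=dedup_mode)
    m3, r3 = drop_sex_chromosomes(m2)
    return m3, r1.merged_with(r2).merged_with(r3)
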