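"""Gene-set over-representation by one-sided Fisher's exact test.

For each named set the 2x2 table (query vs background, in-set vs out of
set) is tested for over-representation; the one-sided p is the upper
hypergeometric tail. Raw p-values are reported alongside a
Benjamini-Hochberg adjustment across the sets, so both the classical
fixed-alpha reading and an FDR-controlled reading are available. Gene
sets are read from GMT files; the background universe defaults to the
genes surviving preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "fisher_enrichment",
    "overrepresentation_p",
    "read_gmt",
]


def overrepresentation_p(k: int, N: int, K: int, n: int) -> float:
    """One-sided Fisher p for overlap k, universe N, set size K, query size n.

    Equals the hypergeometric upper tail P[X >= k]; the building block of
    :func:`fisher_enrichment`.
    """
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict
    universe: set

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("background universe is empty")
        self.universe = set(self.universe)
        restricted = {}
        for name, genes in self.sets.items():
            if name in restricted:
                raise ValueError(f"duplicate gene-set name: {name}")
            restricted[name] = set(genes) & self.universe
        self.sets = restricted

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    """Per-set over-representation summary.

    ``table`` columns: n_set, overlap, odds_ratio, p (one-sided
    hypergeometric upper tail), p_adj (BH across the sets).
    """

    table: pd.DataFrame
    n_query: int
    n_universe: int
    params: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> pd.Index:
        col = "p_adj" if adjusted else "p"
        return self.table.index[self.table[col] < alpha]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_set"
        out.to_csv(path, sep="\t", float_format="%.6g")


def fisher_enrichment(query, collection: GeneSetCollection) -> EnrichmentResult:
    """Test every set in the collection for over-representation in ``query``.

    Query genes outside the universe are dropped with a warning. For a set
    of size K in a universe of size N with a query of size n and overlap k,
    p = P[X >= k] for X hypergeometric(N, K, n) — identical to the
    one-sided Fisher exact test on the 2x2 table.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    outside = query - collection.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the background universe were dropped",
            stacklevel=2,
        )
        query &= collection.universe
    if not query:
        raise ValueError("no query gene remains inside the universe")

    N = len(collection.universe)
    n = len(query)
    rows = {}
    for name, genes in collection.sets.items():
        K = len(genes)
        k = len(query & genes)
        p = overrepresentation_p(k, N, K, n)
        # odds ratio of the 2x2 table (query x set), with 0/0 -> nan
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows[name] = {"n_set": K, "overlap": k, "odds_ratio": odds, "p": p}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return EnrichmentResult(
        table=table,
        n_query=n,
        n_universe=N,
        params={"sided": "greater"},
    )


def read_gmt(path: str | Path, universe=None) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, genes...).

    When ``universe`` is None it defaults to the union of all sets.
    """
    sets = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{line_no}: GMT line needs name, description and >=1 gene")
        name = parts[0]
        sets[name] = set(g for g in parts[2:] if g)
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=set(universe))
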