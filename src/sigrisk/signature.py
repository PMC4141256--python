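"""Deriving the knockdown-influenced prognostic gene signature.

The derivation is a two-stage filter over differential-expression results:

1. :func:`intersect_concordant` — genes significant in *both* knockdown
   contrasts with the same direction of change (the knockdown-influenced
   set);
2. :func:`cross_cancer_filter` — of those, keep genes differentially
   expressed in at least ``min_support`` of the tumor/normal contrasts with
   a tumor direction consistent with the knockdown direction under a
   declared concordance convention.

The concordance convention is deliberately explicit: ``"same"`` requires
the tumor change to match the knockdown change, ``"opposite"`` requires it
to be inverted (relevant when the silenced gene is itself elevated in
tumors). Results are never convention-silent — the convention is recorded
in the signature's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
import json
import warnings

import pandas as pd

from .diffexp import DEResult

__all__ = [
    "DerivationConfig",
    "GeneSignature",
    "intersect_concordant",
    "cross_cancer_filter",
    "derive_signature",
    "published_n39",
]

CONVENTIONS = ("same", "opposite")


@dataclass(frozen=True)
class DerivationConfig:
    """Signature-derivation settings.

    ``tumor_concordance`` has no default on purpose: the sign convention
    changes which genes survive, so the caller must state it.
    """

    tumor_concordance: str
    min_support: int = 3
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.tumor_concordance not in CONVENTIONS:
            raise ValueError(f"tumor_concordance must be one of {CONVENTIONS}")
        if self.min_support < 1:
            raise ValueError("min_support must be at least 1")


@dataclass
class GeneSignature:
    """An ordered gene list with its derivation provenance.

    ``table`` is indexed by gene symbol with columns ``kd_direction``
    (+1/-1, the direction under knockdown) and ``support`` (number of tumor
    contrasts backing the gene).
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    name: str = "signature"

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("signature contains duplicate genes")

    @property
    def genes(self) -> list[str]:
        return self.table.index.tolist()

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index

    def to_tsv(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        out = self.table.copy()
        out.index.name = "symbol"
        out.to_csv(path, sep="\t")
        if provenance_path is not None:
            Path(provenance_path).write_text(json.dumps(self.provenance, indent=2, default=str) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "signature") -> "GeneSignature":
        table = pd.read_csv(path, sep="\t", index_col=0)
        if "kd_direction" not in table.columns:
            table["kd_direction"] = 0
        if "support" not in table.columns:
            table["support"] = pd.NA
        return cls(table[["kd_direction", "support"]], name=name)

    @classmethod
    def from_genes(cls, genes, directions=None, name: str = "signature") -> "GeneSignature":
        genes = list(genes)
        if directions is None:
            directions = [0] * len(genes)
        table = pd.DataFrame(
            {"kd_direction": list(directions), "support": [pd.NA] * len(genes)},
            index=pd.Index(genes, name="symbol"),
        )
        return cls(table, name=name)


def intersect_concordant(de_a: DEResult, de_b: DEResult) -> pd.DataFrame:
    """Genes significant in both contrasts with agreeing direction.

    Returns a frame indexed by gene with a ``direction`` column taken from
    contrast A. Contrasts over different gene universes are intersected on
    the shared genes with a warning.
    """
    shared = de_a.genes.intersection(de_b.genes)
    if len(shared) < len(de_a.genes) or len(shared) < len(de_b.genes):
        warnings.warn(
            f"contrasts cover different gene universes; intersecting on "
            f"{len(shared)} shared genes",
            stacklevel=2,
        )
    a = de_a.table.loc[shared]
    b = de_b.table.loc[shared]
    keep = (
        a["significant"]
        & b["significant"]
        & (a["direction"] == b["direction"])
        & (a["direction"] != 0)
    )
    return pd.DataFrame({"direction": a.loc[keep, "direction"].astype(int)})


def cross_cancer_filter(
    kd_set: pd.DataFrame,
    tumor_des: list[DEResult],
    config: DerivationConfig,
    contrast_ids: list[str] | None = None,
) -> GeneSignature:
    """Keep knockdown-influenced genes replicated across tumor contrasts.

    A gene's support is the number of tumor/normal contrasts in which it is
    significant *and* its tumor direction satisfies the concordance
    convention relative to its knockdown direction; a significant but
    discordant contrast contributes nothing. Genes with support at or above
    ``min_support`` form the signature.
    """
    if kd_set.empty:
        raise ValueError("knockdown-influenced gene set is empty")
    if not tumor_des:
        raise ValueError("need at least one tumor/normal contrast")
    if config.min_support > len(tumor_des):
        raise ValueError(
            f"min_support={config.min_support} exceeds the {len(tumor_des)} available contrasts"
        )
    sign = 1 if config.tumor_concordance == "same" else -1
    kd_dir = kd_set["direction"].astype(int)
    support = pd.Series(0, index=kd_set.index)
    for de in tumor_des:
        tab = de.table.reindex(kd_set.index)
        ok = tab["significant"].fillna(False) & (tab["direction"] == sign * kd_dir)
        support += ok.astype(int)
    keep = support >= config.min_support
    table = pd.DataFrame(
        {
            "kd_direction": kd_dir[keep],
            "support": support[keep].astype(int),
        }
    )
    table.index.name = "symbol"
    provenance = {
        "tumor_concordance": config.tumor_concordance,
        "min_support": config.min_support,
        "n_tumor_contrasts": len(tumor_des),
        "tumor_contrasts": contrast_ids or [de.contrast for de in tumor_des],
        "fdr_threshold": config.fdr_threshold,
        "kd_set_size": int(len(kd_set)),
    }
    return GeneSignature(table, provenance=provenance)


def derive_signature(
    de_kd_a: DEResult,
    de_kd_b: DEResult,
    tumor_des: list[DEResult],
    config: DerivationConfig,
) -> GeneSignature:
    """Full derivation: knockdown intersection then cross-cancer filter."""
    kd_set = intersect_concordant(de_kd_a, de_kd_b)
    if kd_set.empty:
        return GeneSignature(
            pd.DataFrame(columns=["kd_direction", "support"]),
            provenance={"note": "empty knockdown intersection"},
        )
    sig = cross_cancer_filter(kd_set, tumor_des, config)
    sig.provenance["kd_contrasts"] = [de_kd_a.contrast, de_kd_b.contrast]
    return sig


def published_n39() -> GeneSignature:
    """The published 39-gene knockdown-influenced signature (symbols only).

    Directions and support counts were not published with the list, so
    ``kd_direction`` is 0 and ``support`` missing; the list is intended for
    scoring real cohorts, not as a derivation fixture.
    """
    path = resources.files("sigrisk.data").joinpath("n39_signature.tsv")
    with resources.as_file(path) as p:
        sig = GeneSignature.from_tsv(p, name="N39")
    sig.provenance = {"source": "published N39 signature gene list"}
    return sig
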