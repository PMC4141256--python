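"""Survival cohorts: expression plus per-patient time, event and covariates.

A :class:`SurvivalCohort` couples an :class:`~sigrisk.matrix.ExpressionMatrix`
with right-censored follow-up (time in months, event indicator 1 = recurrence,
0 = censored) and an optional clinical covariate table. Phenotype tables are
read from TSV with a ``sample``, ``time`` and ``event`` column; remaining
columns become covariates, numeric where possible and categorical otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["SurvivalCohort", "read_phenotype"]


@dataclass
class SurvivalCohort:
    """Expression and survival follow-up for one patient cohort.

    Invariants enforced at construction: strictly positive times, event
    indicators in {0, 1}, and identical patient sets (and order) between the
    expression matrix columns and the phenotype rows.
    """

    expression: ExpressionMatrix
    time: pd.Series
    event: pd.Series
    covariates: pd.DataFrame | None = field(default=None)
    name: str = "cohort"

    def __post_init__(self) -> None:
        time = pd.Series(self.time, dtype=float)
        event = pd.Series(self.event)
        samples = self.expression.samples
        if not time.index.equals(samples):
            time = time.reindex(samples)
            event = event.reindex(samples)
        if time.isna().any():
            missing = time.index[time.isna()].tolist()
            raise ValueError(f"samples missing survival time: {missing[:5]}")
        if (time <= 0).any():
            bad = time.index[time <= 0].tolist()
            raise ValueError(f"non-positive survival times for: {bad[:5]}")
        if not event.isin([0, 1]).all():
            bad = event.index[~event.isin([0, 1])].tolist()
            raise ValueError(f"event indicator outside {{0,1}} for: {bad[:5]}")
        self.time = time
        self.event = event.astype(int)
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates).reindex(samples)

    @property
    def samples(self) -> pd.Index:
        return self.expression.samples

    @property
    def n_patients(self) -> int:
        return self.expression.n_samples

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SurvivalCohort('{self.name}', {self.n_patients} patients, "
            f"{self.n_events} events, {self.expression.n_genes} genes)"
        )

    def subset_samples(self, samples) -> "SurvivalCohort":
        samples = pd.Index(samples)
        cov = self.covariates.loc[samples] if self.covariates is not None else None
        return SurvivalCohort(
            self.expression.subset_samples(samples),
            self.time.loc[samples],
            self.event.loc[samples],
            cov,
            name=self.name,
        )

    def to_tsv(self, expression_path: str | Path, phenotype_path: str | Path) -> None:
        self.expression.to_tsv(expression_path)
        pheno = pd.DataFrame({"time": self.time, "event": self.event})
        if self.covariates is not None:
            pheno = pd.concat([pheno, self.covariates], axis=1)
        pheno.index.name = "sample"
        pheno.to_csv(phenotype_path, sep="\t", float_format="%.6g")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV (sample, time, event, covariates...).

    Returns a validated DataFrame indexed by sample; covariate columns keep
    their file order. Numeric columns are parsed as numbers, everything else
    as categorical strings. Binary "+/-" codings (e.g. estrogen-receptor
    status) map "+" to 1 and "-" to 0.
    """
    pheno = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in pheno.columns:
            raise ValueError(f"{path}: phenotype requires a '{col}' column")
    bad = np.where(pheno["time"] <= 0)[0]
    if len(bad):
        raise ValueError(f"{path}: non-positive time at data row(s) {[int(b) + 2 for b in bad[:5]]}")
    if not pheno["event"].isin([0, 1]).all():
        bad = np.where(~pheno["event"].isin([0, 1]))[0]
        raise ValueError(f"{path}: event outside {{0,1}} at data row(s) {[int(b) + 2 for b in bad[:5]]}")
    for col in pheno.columns:
        if pheno[col].dtype == object:
            stripped = pheno[col].astype(str).str.strip()
            if set(stripped.unique()) <= {"+", "-"}:
                pheno[col] = (stripped == "+").astype(int)
    return pheno


def cohort_from_files(
    expression_path: str | Path,
    phenotype_path: str | Path,
    name: str = "cohort",
    annotation_path: str | Path | None = None,
) -> SurvivalCohort:
    """Assemble a cohort from an expression TSV and a phenotype TSV."""
    from .matrix import read_expression

    expr = read_expression(expression_path, annotation_path)
    pheno = read_phenotype(phenotype_path)
    missing = pheno.index.difference(expr.samples)
    if len(missing):
        raise ValueError(f"phenotype samples absent from expression matrix: {missing[:5].tolist()}")
    expr = expr.subset_samples(pheno.index)
    covs = pheno.drop(columns=["time", "event"])
    return SurvivalCohort(
        expr,
        pheno["time"],
        pheno["event"],
        covs if covs.shape[1] else None,
        name=name,
    )
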