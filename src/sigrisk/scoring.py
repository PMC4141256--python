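"""Wald-weighted risk scoring: fit on a training cohort, apply anywhere.

The model follows the statsmodels idiom: :class:`RiskScoreModel` is built
from a training cohort and a gene signature; :meth:`RiskScoreModel.fit`
returns a frozen :class:`ScoringModel` carrying, per gene i, the Wald
statistic Z_i = beta_i / SE(beta_i) from a univariate Cox regression of
survival on that gene's expression, together with the training mean mu_i
and standard deviation tau_i. A patient's risk score is

    S = sum_i Z_i * (e_i - mu_i) / tau_i

and a higher score implies a poorer outcome. Patients are classified
positive/negative by a strict median split (or a fixed zero cutoff). The
fitted model is immutable: scoring a validation cohort never recomputes
Z, mu or tau.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SurvivalCohort
from .signature import GeneSignature
from .survival import ConvergenceError, univariate_cox

__all__ = [
    "RiskScoreModel",
    "ScoringModel",
    "RiskScoreResult",
    "fit_scoring_model",
    "score_patients",
    "classify",
]

THRESHOLD_RULES = ("median", "zero")


@dataclass(frozen=True)
class ScoringModel:
    """Frozen per-gene weights and standardization constants.

    Immutable by construction (frozen dataclass, read-only arrays): the
    scoring system is fixed on the training cohort and then only *applied*
    to validation cohorts.
    """

    genes: tuple
    wald: np.ndarray
    mu: np.ndarray
    tau: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    threshold_rule: str
    standardize: str
    dropped_genes: tuple = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("wald", "mu", "tau", "beta", "se"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        if len(self.genes) != len(self.wald):
            raise ValueError("genes and weights length mismatch")
        if np.any(self.tau <= 0):
            raise ValueError("standardization SDs must be positive")
        if self.threshold_rule not in THRESHOLD_RULES:
            raise ValueError(f"threshold_rule must be one of {THRESHOLD_RULES}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def summary(self) -> pd.DataFrame:
        """Per-gene coefficient table (beta, se, Z, mu, tau)."""
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "wald_z": self.wald,
                "mu": self.mu,
                "tau": self.tau,
            },
            index=pd.Index(self.genes, name="gene"),
        )

    # -- application --------------------------------------------------------
    def score(self, cohort: SurvivalCohort) -> "RiskScoreResult":
        return score_patients(self, cohort)

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "genes": list(self.genes),
            "wald": self.wald.tolist(),
            "mu": self.mu.tolist(),
            "tau": self.tau.tolist(),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "threshold_rule": self.threshold_rule,
            "standardize": self.standardize,
            "dropped_genes": list(self.dropped_genes),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, default=str) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoringModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            genes=tuple(payload["genes"]),
            wald=np.array(payload["wald"]),
            mu=np.array(payload["mu"]),
            tau=np.array(payload["tau"]),
            beta=np.array(payload["beta"]),
            se=np.array(payload["se"]),
            threshold_rule=payload["threshold_rule"],
            standardize=payload["standardize"],
            dropped_genes=tuple(payload.get("dropped_genes", ())),
            provenance=payload.get("provenance", {}),
        )


class RiskScoreModel:
    """Univariate-Cox Wald weighting of a gene signature on a training cohort.

    Parameters
    ----------
    cohort
        Training cohort with survival follow-up.
    signature
        Gene signature (or plain iterable of gene symbols) to weight.
    threshold_rule
        'median' (strict split at the scored cohort's median) or 'zero'.
    standardize
        'training' (default) freezes mu/tau from the training cohort;
        'cohort' re-standardizes within each scored cohort (leakier but
        mirrors the observation that the median score sits near zero when
        each cohort is standardized to itself).
    ties
        Ties method for the per-gene Cox fits ('efron' or 'breslow').
    """

    def __init__(
        self,
        cohort: SurvivalCohort,
        signature,
        threshold_rule: str = "median",
        standardize: str = "training",
        ties: str = "efron",
    ) -> None:
        if threshold_rule not in THRESHOLD_RULES:
            raise ValueError(f"threshold_rule must be one of {THRESHOLD_RULES}")
        if standardize not in ("training", "cohort"):
            raise ValueError("standardize must be 'training' or 'cohort'")
        self.cohort = cohort
        self.genes = list(signature.genes) if isinstance(signature, GeneSignature) else list(signature)
        if not self.genes:
            raise ValueError("empty gene signature")
        self.threshold_rule = threshold_rule
        self.standardize = standardize
        self.ties = ties

    def fit(self) -> ScoringModel:
        """Fit per-gene univariate Cox models and freeze the scoring system.

        Signature genes absent from the training cohort, with zero variance,
        or with a degenerate Cox fit are dropped with a warning and recorded
        on the result; the remaining weights are *not* renormalized.
        """
        cohort = self.cohort
        if cohort.n_events < 2:
            raise ValueError("training cohort must contain at least 2 events")
        expr = cohort.expression.values
        time = cohort.time.to_numpy()
        event = cohort.event.to_numpy()

        present = [g for g in self.genes if g in expr.index]
        dropped = {g: "missing from training cohort" for g in self.genes if g not in expr.index}

        kept, wald, mu, tau, beta, se = [], [], [], [], [], []
        for gene in present:
            x = expr.loc[gene].to_numpy()
            sd = float(np.std(x, ddof=1))
            if sd == 0:
                dropped[gene] = "zero variance in training cohort"
                continue
            try:
                fit = univariate_cox(x, time, event, ties=self.ties)
            except (ConvergenceError, ValueError) as exc:
                dropped[gene] = f"Cox fit failed: {exc}"
                continue
            kept.append(gene)
            wald.append(fit.z)
            beta.append(fit.beta)
            se.append(fit.se)
            mu.append(float(np.mean(x)))
            tau.append(sd)

        if dropped:
            warnings.warn(
                f"dropped {len(dropped)} signature gene(s) during fitting: "
                f"{dict(list(dropped.items())[:5])}",
                stacklevel=2,
            )
        if not kept:
            raise ValueError("no signature gene could be fitted on the training cohort")

        return ScoringModel(
            genes=tuple(kept),
            wald=np.array(wald),
            mu=np.array(mu),
            tau=np.array(tau),
            beta=np.array(beta),
            se=np.array(se),
            threshold_rule=self.threshold_rule,
            standardize=self.standardize,
            dropped_genes=tuple(dropped),
            provenance={
                "training_cohort": cohort.name,
                "n_patients": cohort.n_patients,
                "n_events": cohort.n_events,
                "ties": self.ties,
                "requested_genes": len(self.genes),
            },
        )


@dataclass
class RiskScoreResult:
    """Per-patient risk scores with their positive/negative classification."""

    scores: pd.Series
    threshold: float
    positive: pd.Series  # boolean, strict S > threshold
    rule: str
    dropped_genes: tuple = ()

    @property
    def group(self) -> pd.Series:
        """String labels 'positive'/'negative' per patient."""
        return self.positive.map({True: "positive", False: "negative"})

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"score": self.scores, "group": self.group})
        out.index.name = "sample"
        out.to_csv(path, sep="\t", float_format="%.6g")


def fit_scoring_model(
    cohort: SurvivalCohort,
    signature,
    threshold_rule: str = "median",
    standardize: str = "training",
    ties: str = "efron",
) -> ScoringModel:
    """Functional wrapper around :class:`RiskScoreModel`.fit()."""
    return RiskScoreModel(cohort, signature, threshold_rule, standardize, ties).fit()


def score_patients(model: ScoringModel, cohort: SurvivalCohort) -> RiskScoreResult:
    """Apply a frozen scoring model to a cohort.

    Model genes absent from the cohort are dropped (with a warning) without
    renormalizing the remaining weights, so each weight keeps its training
    meaning. With ``standardize='cohort'`` the mean/SD are recomputed within
    the scored cohort instead of using the frozen training constants.
    """
    expr = cohort.expression.values
    present = [i for i, g in enumerate(model.genes) if g in expr.index]
    missing = tuple(g for g in model.genes if g not in expr.index)
    if not present:
        raise ValueError("none of the model's genes are present in the cohort")
    if missing:
        warnings.warn(
            f"{len(missing)} model gene(s) missing from cohort '{cohort.name}'; "
            "their terms are dropped without renormalization",
            stacklevel=2,
        )
    genes = [model.genes[i] for i in present]
    e = expr.loc[genes].to_numpy()
    z = model.wald[present]
    if model.standardize == "cohort":
        mu = e.mean(axis=1)
        tau = e.std(axis=1, ddof=1)
        zero = tau == 0
        if zero.any():
            tau[zero] = 1.0
            z = np.where(zero, 0.0, z)
    else:
        mu = model.mu[present]
        tau = model.tau[present]
    standardized = (e - mu[:, None]) / tau[:, None]
    scores = pd.Series(z @ standardized, index=cohort.samples, name="risk_score")
    return classify(scores, model.threshold_rule, dropped_genes=missing)


def classify(scores: pd.Series, rule: str = "median", dropped_genes: tuple = ()) -> RiskScoreResult:
    """Split patients into positive/negative risk groups.

    'median' uses the median of the scores being classified; 'zero' uses a
    fixed cutoff of 0. The split is strict: positive <=> S > threshold, so
    patients exactly at the threshold are negative.
    """
    scores = pd.Series(scores)
    if rule == "median":
        if len(scores) < 2:
            raise ValueError("median split needs at least 2 patients")
        threshold = float(scores.median())
    elif rule == "zero":
        threshold = 0.0
    else:
        raise ValueError(f"unknown threshold rule: {rule!r}")
    positive = scores > threshold
    return RiskScoreResult(
        scores=scores,
        threshold=threshold,
        positive=positive,
        rule=rule,
        dropped_genes=tuple(dropped_genes),
    )
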