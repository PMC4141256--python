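"""Synthetic expression and survival data with recoverable ground truth.

Every input class the signature pipeline consumes can be generated here:

* two-arm knockdown experiments (wild-type vs knockdown cell lines) with a
  planted set of truly dysregulated genes;
* paired tumor/normal tissue matrices with a per-patient random intercept and
  a planted concordant subset;
* survival cohorts whose hazard depends log-linearly on planted signature
  genes, under a Weibull proportional-hazards model with independent
  exponential plus administrative right censoring.

All generators are deterministic given their config: a single master seed
fans out into named sub-streams (one per generated object), so adding one
object never shifts another object's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import SurvivalCohort
from .matrix import ExpressionMatrix

__all__ = [
    "SimConfig",
    "PairedSimConfig",
    "SurvivalSimConfig",
    "GroundTruth",
    "generate_kd_pair",
    "generate_paired_tumor_normal",
    "generate_survival_cohort",
    "generate_study_bundle",
    "StudyBundle",
]


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named RNG sub-stream derived from a master seed.

    The stream key is a CRC32 of the name, so streams are stable across runs
    and independent of the order objects are generated in.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def _effect_map(genes: Sequence[str], effect) -> dict[str, float]:
    """Normalize a scalar-or-mapping effect spec to {gene: signed shift}."""
    if isinstance(effect, Mapping):
        return {str(g): float(v) for g, v in effect.items()}
    return {str(g): float(effect) for g in genes}


@dataclass(frozen=True)
class SimConfig:
    """Two-group knockdown experiment layout.

    ``kd_effect`` is the signed log2 shift applied to each planted gene in
    the knockdown arm; pass a mapping for per-gene effects or a scalar for a
    common shift. ``noise_sd`` is the residual SD on the log2 scale.
    """

    n_genes: int = 1000
    n_per_group: int = 5
    de_genes: tuple = ()
    kd_effect: object = 1.0
    noise_sd: float = 0.3
    baseline_mean: object = 7.0  # scalar or per-gene array
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.de_genes) > self.n_genes:
            raise ValueError("more planted genes than genes in the universe")


@dataclass(frozen=True)
class PairedSimConfig:
    """Paired tumor/normal design: one normal and one tumor sample per patient.

    ``concordant_genes`` maps planted genes to signed tumor-minus-normal log2
    shifts; ``patient_effect_sd`` is the SD of the per-patient random
    intercept shared by both samples of a patient (it cancels in paired
    differences).
    """

    n_genes: int = 1000
    n_patients: int = 20
    concordant_genes: Mapping[str, float] = field(default_factory=dict)
    patient_effect_sd: float = 1.0
    noise_sd: float = 0.4
    baseline_mean: object = 7.0  # scalar or per-gene array
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients for a paired design")
        if self.patient_effect_sd < 0:
            raise ValueError("patient_effect_sd must be non-negative")


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Weibull proportional-hazards survival layer on top of expression.

    Event times follow h(t | x) = h0(t) * exp(sum_g beta_g z_g) with z_g the
    cohort-standardized expression of gene g and h0 a Weibull hazard with
    the given shape and scale (months). Censoring is the minimum of an
    independent exponential time (rate ``censor_rate`` per month) and an
    administrative horizon ``admin_time``.
    """

    n_patients: int = 200
    beta: Mapping[str, float] = field(default_factory=dict)
    baseline_shape: float = 1.2
    baseline_scale: float = 60.0
    censor_rate: float = 0.008
    admin_time: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if self.admin_time <= 0:
            raise ValueError("admin_time must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth attached to a simulated object.

    ``planted`` maps gene ID to its signed effect (log2 shift for expression
    designs, log-hazard coefficient for survival designs); ``latent_risk``
    holds each patient's true linear predictor where applicable.
    """

    planted: dict
    latent_risk: pd.Series | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.planted)


# ---------------------------------------------------------------------------
# knockdown pair
# ---------------------------------------------------------------------------

def generate_kd_pair(config: SimConfig) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Simulate a wild-type vs knockdown two-group experiment.

    Returns the expression matrix (genes x 2*n_per_group), a sample->group
    label Series with levels ``WT`` and ``KD``, and the planted ground truth.
    Planted genes get their signed ``kd_effect`` added in the KD arm, so the
    KD-minus-WT mean log2 difference equals the effect in expectation.
    """
    genes = gene_ids(config.n_genes)
    universe = set(genes)
    effects = _effect_map(config.de_genes, config.kd_effect)
    missing = [g for g in effects if g not in universe]
    if missing:
        raise ValueError(f"planted genes outside the gene universe: {missing[:5]}")

    rng = _stream(config.seed, "kd_pair")
    n = config.n_per_group
    samples = [f"WT{i + 1}" for i in range(n)] + [f"KD{i + 1}" for i in range(n)]
    labels = pd.Series(["WT"] * n + ["KD"] * n, index=samples, name="group")

    base = np.broadcast_to(np.asarray(config.baseline_mean, dtype=float), (config.n_genes,))
    values = base[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, 2 * n))
    shift = np.array([effects.get(g, 0.0) for g in genes])
    values[:, n:] += shift[:, None]

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    return matrix, labels, GroundTruth(planted=effects)


# ---------------------------------------------------------------------------
# paired tumor/normal
# ---------------------------------------------------------------------------

def generate_paired_tumor_normal(
    config: PairedSimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate paired normal/tumor tissue expression.

    Each patient contributes one normal and one tumor sample sharing a
    patient-level random intercept; planted genes get their signed shift in
    the tumor sample. Returns the matrix, a pairing table (patient, normal,
    tumor sample IDs) and the ground truth.
    """
    genes = gene_ids(config.n_genes)
    universe = set(genes)
    effects = _effect_map(list(config.concordant_genes), config.concordant_genes)
    missing = [g for g in effects if g not in universe]
    if missing:
        raise ValueError(f"planted genes outside the gene universe: {missing[:5]}")

    rng = _stream(config.seed, "paired_tumor_normal")
    m = config.n_patients
    patients = [f"P{i + 1:03d}" for i in range(m)]
    normal_ids = [f"{p}_N" for p in patients]
    tumor_ids = [f"{p}_T" for p in patients]

    patient_intercept = rng.normal(0.0, config.patient_effect_sd, size=m)
    gene_base = np.broadcast_to(np.asarray(config.baseline_mean, dtype=float), (config.n_genes,))
    base = gene_base[:, None] + patient_intercept[None, :]  # shared by the pair
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, 2 * m))
    values = np.empty((config.n_genes, 2 * m))
    values[:, :m] = base + noise[:, :m]
    shift = np.array([effects.get(g, 0.0) for g in genes])
    values[:, m:] = base + shift[:, None] + noise[:, m:]

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=normal_ids + tumor_ids)
    )
    pairing = pd.DataFrame({"normal": normal_ids, "tumor": tumor_ids}, index=pd.Index(patients, name="patient"))
    return matrix, pairing, GroundTruth(planted=effects)


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def generate_survival_cohort(
    expr_config: SimConfig,
    surv_config: SurvivalSimConfig,
    name: str = "cohort",
    with_covariates: bool = False,
) -> tuple[SurvivalCohort, GroundTruth]:
    """Simulate a survival cohort with expression-driven hazard.

    Expression is log2 Gaussian around the gene baseline with SD
    ``expr_config.noise_sd`` (the between-patient biological spread). The
    linear predictor is sum_g beta_g * z_g over the planted genes, with z_g
    the expression standardized within the cohort; event times are drawn by
    inverse transform from the Weibull proportional-hazards model. Observed
    time is min(event, exponential censoring, administrative horizon).

    Optional clinical covariates (age in years, a binary stage indicator)
    are generated independently of expression.
    """
    beta = {str(g): float(v) for g, v in surv_config.beta.items()}
    genes = gene_ids(expr_config.n_genes)
    universe = set(genes)
    missing = [g for g in beta if g not in universe]
    if missing:
        raise ValueError(f"beta genes outside the gene universe: {missing[:5]}")

    rng = _stream(surv_config.seed, f"survival:{name}")
    m = surv_config.n_patients
    patients = [f"{name}_S{i + 1:04d}" for i in range(m)]

    base = np.broadcast_to(np.asarray(expr_config.baseline_mean, dtype=float), (expr_config.n_genes,))
    values = base[:, None] + rng.normal(
        0.0, expr_config.noise_sd, size=(expr_config.n_genes, m)
    )
    expr = pd.DataFrame(values, index=genes, columns=patients)

    if beta:
        sub = expr.loc[list(beta)]
        sd = sub.std(axis=1, ddof=1).replace(0.0, np.nan)
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0).fillna(0.0)
        eta = z.mul(pd.Series(beta), axis=0).sum(axis=0).to_numpy()
    else:
        eta = np.zeros(m)

    # inverse-transform Weibull PH: T = scale * (-log U / exp(eta))^(1/shape)
    u = rng.uniform(size=m)
    t_event = surv_config.baseline_scale * (-np.log(u) / np.exp(eta)) ** (
        1.0 / surv_config.baseline_shape
    )
    if surv_config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / surv_config.censor_rate, size=m)
    else:
        t_cens = np.full(m, np.inf)
    t_cens = np.minimum(t_cens, surv_config.admin_time)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)  # guard against exact zeros

    covariates = None
    if with_covariates:
        covariates = pd.DataFrame(
            {
                "age": np.round(rng.normal(62.0, 9.0, size=m), 1),
                "stage_high": rng.integers(0, 2, size=m),
            },
            index=patients,
        )

    cohort = SurvivalCohort(
        ExpressionMatrix(expr),
        pd.Series(time, index=patients, name="time"),
        pd.Series(event, index=patients, name="event"),
        covariates,
        name=name,
    )
    truth = GroundTruth(planted=beta, latent_risk=pd.Series(eta, index=patients, name="latent_risk"))
    return cohort, truth


# ---------------------------------------------------------------------------
# full study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Everything one end-to-end signature study consumes.

    Two knockdown contrasts, four paired tumor/normal datasets sharing the
    planted concordant subset, one training survival cohort and two
    validation cohorts whose hazard increases with the planted genes'
    knockdown-direction expression.
    """

    kd: list  # [(matrix, labels, truth), ...]
    paired: list  # [(matrix, pairing, truth), ...]
    train: SurvivalCohort
    validation: list  # [SurvivalCohort, ...]
    truth: GroundTruth
    annotation: pd.DataFrame


def default_annotation(genes: Sequence[str], seed: int, frac_sex: float = 0.02) -> pd.DataFrame:
    """Symbol/chromosome annotation: symbols equal gene IDs, a small fraction
    of genes assigned to chromosomes X/Y, the rest to autosomes."""
    rng = _stream(seed, "annotation")
    chroms = rng.choice([str(c) for c in range(1, 23)], size=len(genes))
    n_sex = int(round(frac_sex * len(genes)))
    if n_sex:
        idx = rng.choice(len(genes), size=n_sex, replace=False)
        sex = rng.choice(["X", "Y"], size=n_sex)
        chroms = np.asarray(chroms, dtype=object)
        chroms[idx] = sex
    return pd.DataFrame({"symbol": list(genes), "chromosome": chroms}, index=pd.Index(genes, name="gene"))


def generate_study_bundle(
    seed: int = 0,
    n_genes: int = 2000,
    n_signature: int = 40,
    kd_effect: float = 1.0,
    kd_noise_sd: float = 0.25,
    n_per_group: int = 5,
    paired_patients: tuple[int, ...] = (44, 19, 36, 44),
    paired_effect: float = 1.0,
    paired_noise_sd: float = 0.4,
    patient_effect_sd: float = 1.0,
    n_train: int = 150,
    n_validation: tuple[int, ...] = (150, 120),
    surv_beta: float = 0.25,
    expr_noise_sd: float = 0.5,
    frac_sex: float = 0.02,
    frac_background: float = 0.15,
    with_covariates: bool = True,
) -> StudyBundle:
    """Generate the complete synthetic study.

    Per-gene log2 baselines are drawn once and shared by every dataset: a
    mixture of clearly expressed genes (N(8, 1)) and a background fraction
    near the detection floor (N(5, 0.5)), so the presence filter has real
    work to do. A planted subset of ``n_signature`` genes (half up-, half
    down-regulated under knockdown) drives all layers: the same signed log2
    shift in both knockdown contrasts, a concordant shift in all four
    paired tumor/normal datasets, and log-hazard coefficients
    ``surv_beta * sign`` in every survival cohort. Planted genes are drawn
    from autosomal, clearly expressed genes (baseline >= 7) — a gene must
    be reliably detected to be discoverable in the first place — so neither
    the presence nor the sex-chromosome filter removes them by design.
    """
    genes = gene_ids(n_genes)
    annotation = default_annotation(genes, seed, frac_sex=frac_sex)

    rngb = _stream(seed, "bundle:baselines")
    background = rngb.uniform(size=n_genes) < frac_background
    baselines = np.where(
        background,
        rngb.normal(5.0, 0.5, size=n_genes),
        rngb.normal(8.0, 1.0, size=n_genes),
    )
    base_by_gene = pd.Series(baselines, index=genes)
    plantable = [
        g
        for g in genes
        if annotation.loc[g, "chromosome"] not in ("X", "Y") and base_by_gene[g] >= 7.0
    ]

    rng = _stream(seed, "bundle:planting")
    planted = sorted(rng.choice(plantable, size=n_signature, replace=False))
    signs = np.where(np.arange(n_signature) % 2 == 0, 1.0, -1.0)
    effects = {g: float(s) * kd_effect for g, s in zip(planted, signs)}
    paired_shifts = {g: float(s) * paired_effect for g, s in zip(planted, signs)}
    betas = {g: float(s) * surv_beta for g, s in zip(planted, signs)}

    kd = []
    for i in range(2):
        cfg = SimConfig(
            n_genes=n_genes,
            n_per_group=n_per_group,
            de_genes=tuple(planted),
            kd_effect=effects,
            noise_sd=kd_noise_sd,
            baseline_mean=baselines,
            seed=int(np.random.SeedSequence([seed, 100 + i]).generate_state(1)[0] % 2**31),
        )
        kd.append(generate_kd_pair(cfg))

    paired = []
    for i, n_pat in enumerate(paired_patients):
        cfg = PairedSimConfig(
            n_genes=n_genes,
            n_patients=n_pat,
            concordant_genes=paired_shifts,
            patient_effect_sd=patient_effect_sd,
            noise_sd=paired_noise_sd,
            baseline_mean=baselines,
            seed=int(np.random.SeedSequence([seed, 200 + i]).generate_state(1)[0] % 2**31),
        )
        paired.append(generate_paired_tumor_normal(cfg))

    def _surv(name: str, n: int, sub: int) -> SurvivalCohort:
        e_cfg = SimConfig(n_genes=n_genes, noise_sd=expr_noise_sd, baseline_mean=baselines, seed=0)
        s_cfg = SurvivalSimConfig(
            n_patients=n,
            beta=betas,
            seed=int(np.random.SeedSequence([seed, sub]).generate_state(1)[0] % 2**31),
        )
        cohort, _ = generate_survival_cohort(e_cfg, s_cfg, name=name, with_covariates=with_covariates)
        cohort.expression.annotation = annotation.copy()
        return cohort

    train = _surv("train", n_train, 300)
    validation = [_surv(f"valid{i + 1}", n, 301 + i) for i, n in enumerate(n_validation)]

    for matrix, _, _ in kd:
        matrix.annotation = annotation.copy()
    for matrix, _, _ in paired:
        matrix.annotation = annotation.copy()

    truth = GroundTruth(planted=effects)
    return StudyBundle(kd=kd, paired=paired, train=train, validation=validation, truth=truth, annotation=annotation)
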