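# Methods

This note documents the statistical procedures `sigrisk` implements, the
synthetic data they are exercised on, and the design decisions taken where
the classic workflow leaves room for interpretation. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Preprocessing

Filters operate on gene-level log2 matrices and are applied in a fixed
order: presence → deduplication → sex-chromosome removal. Gene filters
never touch the sample dimension, and each returns a report whose removal
counts sum exactly to (input − output) genes.

**Presence.** Probe-level detection calls (MAS5-style present/absent
flags) are not available at matrix level, so presence is redefined as a
detection threshold on log2 values: a gene is kept when its value reaches
the threshold in at least `min_fraction` of samples (default 2/3,
boundary inclusive — 2 of 3 samples passes). The default threshold is the
cohort's 10th percentile of all values, recorded in the filter report;
given a fixed threshold the filter is idempotent.

**Deduplication.** "Uniquely annotated" is ambiguous between dropping all
rows of a duplicated symbol and collapsing them to one. Strict drop is the
default (it matches the narrow reading and is conservative); a `collapse`
mode keeps the highest-mean row per symbol. After deduplication the gene
index is the symbol — downstream stages identify genes by symbol only;
cross-platform matching beyond symbols is out of scope.

**Sex chromosomes.** Genes on X or Y are removed to avoid sex-linked
confounding. Chromosome dialects are normalized ("chrX", "X" and "23" all
mean X; "24" means Y). A missing chromosome annotation is an error, never
a silent pass-through.

## Differential expression

**Two-group (knockdown) contrasts** use a moderated difference statistic

d_i = (x̄₂ᵢ − x̄₁ᵢ) / (sᵢ + s₀),

where sᵢ is the pooled standard error of the mean difference and s₀ a
small additive constant that stops near-zero-variance genes from
dominating the ranking. With `s0="auto"` (default), s₀ is chosen from the
percentiles {0, 5, …, 100} of the sᵢ distribution as the value that makes
the spread of d most uniform across variance strata: genes are binned into
100 equal-count windows by sᵢ, the median absolute deviation of d is
computed per window, and the candidate minimizing the coefficient of
variation of those MADs wins (first minimum on ties; median(sᵢ) fallback
below 10 genes). The selection is deterministic given the data.

False-discovery rates come from a label-permutation null: for each gene's
cutoff c = |dᵢ|, the estimate is π₀ times the median across permutations
of #{null |d| ≥ c}, divided by the observed count #{|d| ≥ c} (ties counted
with ≥). π₀ is the fraction of observed d inside the central 25–75%
quantile band of the null d, divided by 0.5 and capped at 1. Estimates are
monotonized (q never increases with |d|) by taking, for each gene, the
minimum estimate over all cutoffs no more extreme than its own. The
default is 1000 permutations; when fewer distinct label assignments exist
they are enumerated exhaustively with a warning. Significance is gene-level
q below the FDR threshold (default 0.05) — a global reporting threshold on
the per-gene FDR rather than a single delta-style cut — combined with a
symmetric linear fold-change gate max(FC, 1/FC) > 1.1, so down-regulation
is treated symmetrically. Tests are two-sided throughout; directions are
reported, not folded into one-sided tests.

**Paired (tumor/normal) contrasts** use the classical paired t-test on
per-patient log2 differences (df = n−1, two-sided), with
Benjamini–Hochberg step-up adjustment across genes (delegated to
statsmodels). Paired contrasts default to the BH gate alone
(fold-change threshold 1), matching how replication across cancer types is
usually judged; a fold-change gate can be added. Zero-variance differences
yield t = ±∞ with p = 0 (or t = 0, p = 1 when all differences are exactly
zero) rather than a division error.

## Signature derivation

Stage one intersects the two knockdown contrasts: a gene survives if it is
significant in both with the same direction. Stage two counts, for each
surviving gene, the tumor/normal contrasts in which it is significant
*and* its tumor direction satisfies the declared concordance convention;
support at or above `min_support` (default 3 of 4) admits the gene. A
significant but discordant contrast contributes zero support (never −1).

The concordance convention is a mandatory explicit field. "Concordant"
can mean the tumor change matches the knockdown change (`"same"`) or
inverts it (`"opposite"` — relevant when the silenced regulator is itself
elevated in tumors). Both are implemented; `"same"` is the default reading
supplied by the pipeline config, and the choice is recorded in the
signature's provenance so results are never convention-silent. Derivation
is a pure function of its inputs and config: re-running yields the
identical signature, and relaxing `min_support` can only grow it.

## Risk scoring

On a training cohort, each signature gene i is fitted in a univariate Cox
proportional-hazards model of recurrence-free survival on its expression;
the gene's weight is the Wald statistic Zᵢ = β̂ᵢ/SE(β̂ᵢ). A patient's score
is S = Σᵢ Zᵢ(eᵢ − μᵢ)/τᵢ with μᵢ and τᵢ the mean and sample SD (ddof = 1)
of gene i in the training cohort. Higher S means poorer expected outcome.
The fitted model is immutable (frozen dataclass, read-only arrays):
validation cohorts are only ever *scored*, never refitted.

Patients are classified positive when S strictly exceeds the threshold:
the median of the scores in the cohort being classified (default), or an
absolute zero cutoff (useful clinically because the score median sits near
zero when cohorts are standardized to themselves). Patients exactly at the
median are negative.

Two deliberate policy choices: (1) standardization scope — the default
freezes μ, τ from training (leak-free); a `standardize="cohort"` mode
re-standardizes within each scored cohort, is logged whenever used, and
exists because per-cohort standardization is the variant under which the
score median lands near zero in every cohort. This is the single most
consequential ambiguity in workflows of this family, so it is an explicit,
surfaced switch. (2) Genes missing at scoring time are dropped *without*
renormalizing the remaining weights — each weight keeps its training
meaning — and the dropped set is recorded on the result.

## Survival analysis

Kaplan–Meier estimation, the two-group log-rank test and multivariate Cox
models are delegated to lifelines behind typed result containers (curves
with at-risk counts; chi-square, p and per-group observed/expected event
counts; coefficient tables with HR and 95% CI = exp(β ± 1.96·SE)).

Univariate Cox fits go through a dedicated single-covariate Newton–Raphson
solver on the Efron partial likelihood (Breslow switchable), because the
scoring and resampling stages need on the order of 10⁵ such fits per run.
Convergence is declared when the relative log-likelihood change falls
below 1e-9 (maximum 100 iterations, step halving on overshoot); standard
errors come from the observed information at the optimum. Monotone
likelihoods (complete separation) are detected — coefficient divergence or
a scaled coefficient/standard error beyond plausible bounds — and raised
as errors, never returned as spurious estimates. The solver is
cross-checked against lifelines in the test suite, and its score test at
β = 0 reproduces the log-rank chi-square exactly on tie-free two-group
data (an identity the acceptance tests assert numerically). Ties default
to Efron; with continuous simulated times the choice is immaterial.

Stratified re-analysis partitions a cohort by a clinical factor and redoes
the positive-vs-negative Cox/KM/log-rank analysis within each stratum. The
whole-cohort classification is carried into the strata (not re-derived per
stratum, configurable in principle because the alternative reading
exists); strata where either risk group lacks events are flagged
unevaluable and skipped rather than fitted.

## Random-signature resampling test

Many signatures predict outcome merely because much of the transcriptome
does. The resampling test asks whether the tested signature beats
size-matched random gene sets: each of `n_resamples` draws (default 1000;
sampling without replacement within a draw, independent across draws) is
pushed through the *identical* pipeline — weights fitted on the training
cohort, scores and median split on the evaluation cohort, univariate Cox
of positive-vs-negative, Wald Z recorded. Observed and null statistics are
computed by the same function, eliminating tested-differently bias by
construction. The right-tailed p uses add-one smoothing,
p = (1 + #{Z_null ≥ Z_obs}) / (1 + n_resamples), so p is never 0 and never
below 1/(n_resamples+1).

Policy defaults, each a config switch with its setting echoed in the
output metadata: the gene pool is all genes shared by the two cohorts; the
tested signature's own genes are *not* excluded from the pool; weights are
refit on the training cohort (an in-cohort mode exists for sensitivity
analysis); the Wald statistic comes from the binary group contrast,
matching the headline analyses (a continuous-score variant is available).
Degenerate draws (a risk group without events) are discarded and redrawn,
with the redraw count reported and a hard cap guarding pathological
cohorts.

## Enrichment

Over-representation of a gene list in named sets is the one-sided Fisher
exact test: p = P[X ≥ k] for X hypergeometric(N, K, n) on the 2×2 table of
query × set membership within a background universe. The universe defaults
to the genes surviving preprocessing, not the whole genome — enrichment
should be judged against what could have been selected. Raw p-values are
reported alongside a BH adjustment across sets so both the classical
fixed-α reading and an FDR-controlled reading are available. Sets are read
from GMT files; database clients are out of scope.

## Synthetic data

The generator produces every input class with recoverable ground truth.
All expression is Gaussian on the log2 scale around per-gene baselines
(the workflow operates on log2 data throughout, so linear-scale simulation
is unnecessary).

* **Baselines.** Per-gene baselines are drawn once per study and shared by
  every dataset: a mixture of clearly expressed genes (N(8, 1)) and a
  background fraction (15%, N(5, 0.5)) sitting near the detection floor,
  so the presence filter removes a realistic slice. Planted genes are
  drawn from autosomal genes with baseline ≥ 7: a gene must be reliably
  detected to be discoverable at all, and the planted truth should be
  removable only by the statistics, not by the filters.
* **Knockdown pairs.** Two arms of `n_per_group` samples; planted genes
  get their signed log2 shift in the knockdown arm; residual SD defaults
  to 0.25 at an effect size of 1 (effect ≥ 4 residual SDs, the regime the
  separation property assumes).
* **Paired tumor/normal.** One normal and one tumor sample per patient
  share a patient-level random intercept (SD 1.0) that cancels exactly in
  paired differences; planted genes get their signed shift in the tumor
  sample. Default sizes (44, 19, 36, 44 patients) mirror a realistic
  four-cancer design.
* **Survival cohorts.** Event times follow a Weibull proportional-hazards
  model (shape 1.2, scale 60 months) with linear predictor
  Σ β_g z_g on cohort-standardized expression — proportional hazards is
  the structure the Cox analyses assume, and Weibull nests the exponential
  at shape 1. Censoring is the minimum of an independent exponential time
  (rate 0.008/month) and an administrative horizon (120 months), tuned to
  roughly 40% censoring at the default conditions. Clinical covariates
  (age, a binary stage indicator) are generated independently of
  expression by default.
* **Seeding.** A single master seed fans out into named sub-streams (CRC32
  of the object name), so adding one generated object never shifts
  another's draws; identical configs give byte-identical outputs.

The default full-study bundle plants 40 signature genes (half up, half
down) among 2,000, wires the same signs through both knockdown contrasts,
all four paired datasets and every survival cohort (log-hazard ±0.25 per
gene), and generates one training plus two validation cohorts (150/150/120
patients).

What the generator deliberately does *not* emulate: probe-level
summarization and hybridization noise, heavy-tailed or heteroskedastic
residuals, correlated gene modules, batch effects, platform differences
between cohorts, and covariates confounded with expression (a confounding
knob exists but defaults to off). Passing tests therefore demonstrate that
the machinery is correct and calibrated under a clean generative model,
not that any particular real dataset would yield a reproducible signature.

## Numerical choices

* Cox: Efron ties, tolerance 1e-9 on the relative partial-log-likelihood
  change, 100 iterations max, step halving, separation detection as above.
* Permutation q-values: ≥ convention on exceedance counts; exhaustive
  enumeration with a warning when fewer distinct assignments than
  requested permutations exist.
* Presence boundary inclusive within 1e-12 to guard float rounding of
  fractions like 2/3.
* Fold change computed as 2^(Δ mean log2); the significance gate uses
  max(FC, 1/FC) strictly greater than the threshold.
* Median split strict (positive ⇔ S > median); with all scores equal,
  everyone is negative.
* 95% CIs everywhere; α = 0.05 throughout.
* Demo/test problem sizes (reduced gene counts, 60–200 permutations,
  15–200 resamples) are chosen so the full suite and the acceptance script
  run in minutes on one CPU; the statistical conclusions they check are
  scale-free (calibration, recovery, identities).

## Known limitations

* Proportional-hazards diagnostics (e.g. Schoenfeld residuals) are not
  provided; the Cox analyses assume the PH structure the simulator
  generates. Time-varying covariates and competing risks are out of scope.
* Gene identity is by symbol; no ortholog or probe re-annotation.
* The enrichment module takes user-supplied gene sets; it ships no pathway
  database.
* The resampling null resamples genes, not survival labels — it answers
  "is this signature better than a random one of the same size", not "is
  there any survival signal at all".
* Raw probe-level preprocessing (background correction, normalization,
  detection calls) is explicitly out of scope; inputs are assumed to be
  summarized, normalized log2 gene-level matrices.
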