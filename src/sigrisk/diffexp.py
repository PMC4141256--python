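"""Differential-expression engines for two-group and paired designs.

Two routes are provided:

* :func:`sam` — a moderated two-sample difference statistic
  d_i = (mean2_i - mean1_i) / (s_i + s0), where s_i is the pooled standard
  error of the mean difference and s0 a small additive "fudge factor" that
  keeps low-variance genes from dominating, with a false-discovery rate
  estimated per gene (q-values) from a label-permutation null;
* :func:`paired_de` — classical paired t-tests on per-patient log2
  differences with Benjamini-Hochberg adjustment, for tumor/normal designs.

Both feed :func:`call_de`, which applies the joint significance rule:
FDR below threshold AND symmetric linear fold change above threshold.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "SAMConfig",
    "DEResult",
    "sam_statistic",
    "select_s0",
    "sam_qvalues",
    "sam",
    "paired_t",
    "paired_de",
    "bh_adjust",
    "fold_change",
    "call_de",
]


@dataclass(frozen=True)
class SAMConfig:
    """Thresholds and permutation settings for the moderated-d route.

    ``s0`` is either a non-negative value in log2-intensity units or
    ``"auto"`` for data-driven selection; ``fc_threshold`` is a linear
    fold-change ratio applied symmetrically to up- and down-regulation.
    """

    s0: float | str = "auto"
    n_permutations: int = 1000
    fdr_threshold: float = 0.05
    fc_threshold: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 != "auto" and float(self.s0) < 0:
            raise ValueError("s0 must be non-negative or 'auto'")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold is a ratio and must be >= 1")


@dataclass
class DEResult:
    """Per-gene differential-expression summary for one contrast.

    ``table`` columns: statistic, fc (linear, group2/group1 orientation),
    direction (+1/-1/0 = sign of the log2 difference), p (NaN for the
    permutation route), q (q-value or BH-adjusted p) and significant.
    """

    table: pd.DataFrame
    contrast: str = "contrast"
    method: str = "sam"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"statistic", "fc", "direction", "p", "q", "significant"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DEResult table missing columns: {sorted(missing)}")
        q = self.table["q"].to_numpy()
        if np.nanmin(q) < 0 or np.nanmax(q) > 1:
            raise ValueError("q values must lie in [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, contrast: str | None = None) -> "DEResult":
        table = pd.read_csv(path, sep="\t", index_col=0)
        table["significant"] = table["significant"].astype(bool)
        return cls(table, contrast=contrast or str(path), method="loaded")


def _group_masks(labels: pd.Series, groups: tuple | None) -> tuple[np.ndarray, np.ndarray, tuple]:
    labels = pd.Series(labels)
    if groups is None:
        found = sorted(labels.unique())
        if len(found) != 2:
            raise ValueError(f"expected exactly two groups, found {found}")
        groups = (found[0], found[1])
    g1, g2 = groups
    m1 = (labels == g1).to_numpy()
    m2 = (labels == g2).to_numpy()
    if not (m1.any() and m2.any()):
        raise ValueError(f"empty group among {groups}")
    return m1, m2, groups


def _pooled_se(values: np.ndarray, m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Tusher pooled standard error of the mean difference, per gene."""
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    ss1 = ((values[:, m1] - values[:, m1].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((values[:, m2] - values[:, m2].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    return np.sqrt(a * (ss1 + ss2))


def _d_values(values: np.ndarray, m1: np.ndarray, m2: np.ndarray, s0: float) -> np.ndarray:
    num = values[:, m2].mean(axis=1) - values[:, m1].mean(axis=1)
    se = _pooled_se(values, m1, m2)
    denom = se + s0
    if np.any(denom == 0):
        raise ZeroDivisionError(
            "zero-variance gene with s0=0; use a positive s0 (or 'auto') to floor the denominator"
        )
    return num / denom


def sam_statistic(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    s0: float = 0.0,
    groups: tuple | None = None,
) -> pd.Series:
    """Moderated difference statistic d = (mean2 - mean1) / (s + s0).

    ``groups`` orders the contrast as (reference, treatment); the default is
    the sorted pair of observed labels. Swapping the two groups negates d.
    """
    m1, m2, groups = _group_masks(labels.reindex(matrix.samples), groups)
    d = _d_values(matrix.values.to_numpy(), m1, m2, float(s0))
    return pd.Series(d, index=matrix.genes, name="d")


def select_s0(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    groups: tuple | None = None,
    n_windows: int = 100,
) -> float:
    """Data-driven fudge factor: the percentile of the per-gene standard
    errors that makes the spread of d most uniform across variance strata.

    Candidate s0 values are the 0,5,...,100th percentiles of s_i. For each
    candidate the genes are split into ``n_windows`` equal-count windows by
    s_i, the median absolute deviation of d is computed per window, and the
    candidate minimizing the coefficient of variation of these MADs wins
    (first minimum on ties, so the choice is deterministic). With fewer than
    10 genes the selection falls back to median(s_i).
    """
    m1, m2, groups = _group_masks(labels.reindex(matrix.samples), groups)
    values = matrix.values.to_numpy()
    se = _pooled_se(values, m1, m2)
    if len(se) < 10:
        return float(np.median(se))
    num = values[:, m2].mean(axis=1) - values[:, m1].mean(axis=1)

    order = np.argsort(se, kind="stable")
    n_windows = min(n_windows, max(2, len(se) // 10))
    windows = np.array_split(order, n_windows)

    alphas = np.arange(0, 101, 5)
    candidates = np.percentile(se, alphas)
    best_cv, best_s0 = np.inf, float(np.median(se))
    for s0 in candidates:
        denom = se + s0
        if np.any(denom == 0):
            continue
        d = num / denom
        mads = np.array([stats.median_abs_deviation(d[w], scale="normal") for w in windows])
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std(ddof=1) / mean
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _permutation_masks(
    n: int, n1: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean group-1 membership masks for the permutation null.

    Enumerates all distinct assignments when there are no more than
    requested; otherwise samples assignments uniformly at random.
    """
    total = math.comb(n, n1)
    if total <= n_permutations:
        warnings.warn(
            f"only {total} distinct label assignments exist; enumerating all "
            f"instead of {n_permutations} random permutations",
            stacklevel=3,
        )
        masks = np.zeros((total, n), dtype=bool)
        for b, idx in enumerate(itertools.combinations(range(n), n1)):
            masks[b, list(idx)] = True
        return masks
    masks = np.zeros((n_permutations, n), dtype=bool)
    for b in range(n_permutations):
        masks[b, rng.choice(n, size=n1, replace=False)] = True
    return masks


def sam_qvalues(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    config: SAMConfig = SAMConfig(),
    groups: tuple | None = None,
) -> DEResult:
    """Permutation-null q-values for the moderated-d statistic.

    For each gene's cutoff c = |d_i|, the false-discovery estimate is
    pi0 * median over permutations of #{null |d| >= c} divided by the
    observed count #{|d| >= c} (ties counted with >=). pi0 is the fraction
    of observed d falling inside the central 25-75% quantile band of the
    null d values, divided by 0.5, capped at 1. Estimates are monotonized so
    q never increases with |d|.
    """
    labels = pd.Series(labels).reindex(matrix.samples)
    m1, m2, groups = _group_masks(labels, groups)
    values = matrix.values.to_numpy()
    n = values.shape[1]
    n1 = int(m1.sum())

    s0 = float(select_s0(matrix, labels, groups=groups)) if config.s0 == "auto" else float(config.s0)
    d_obs = _d_values(values, m1, m2, s0)

    rng = np.random.default_rng(config.seed)
    masks = _permutation_masks(n, n1, config.n_permutations, rng)
    n_perm = masks.shape[0]
    null_d = np.empty((n_perm, len(d_obs)))
    for b in range(n_perm):
        null_d[b] = _d_values(values, masks[b], ~masks[b], s0)

    abs_obs = np.abs(d_obs)
    # observed exceedance count per gene cutoff (>= convention)
    sorted_abs = np.sort(abs_obs)
    obs_count = len(abs_obs) - np.searchsorted(sorted_abs, abs_obs, side="left")
    # per-permutation null exceedance counts, median across permutations
    null_counts = np.empty((n_perm, len(abs_obs)))
    for b in range(n_perm):
        row = np.sort(np.abs(null_d[b]))
        null_counts[b] = len(row) - np.searchsorted(row, abs_obs, side="left")
    med_null = np.median(null_counts, axis=0)

    q25, q75 = np.quantile(null_d, [0.25, 0.75])
    pi0 = min(1.0, float(np.mean((d_obs > q25) & (d_obs < q75))) / 0.5)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = pi0 * med_null / obs_count
    fdr = np.clip(fdr, 0.0, 1.0)
    # q_i = min FDR over all cutoffs no more extreme than |d_i|
    order = np.argsort(-abs_obs, kind="stable")
    q = np.empty_like(fdr)
    q[order] = np.minimum.accumulate(fdr[order][::-1])[::-1]

    fc, direction = fold_change(matrix, labels, groups=groups)
    table = pd.DataFrame(
        {
            "statistic": d_obs,
            "fc": fc,
            "direction": direction,
            "p": np.nan,
            "q": q,
            "significant": False,
        },
        index=matrix.genes,
    )
    result = DEResult(
        table,
        method="sam",
        params={
            "s0": s0,
            "n_permutations": int(n_perm),
            "pi0": pi0,
            "groups": tuple(groups),
            "fdr_threshold": config.fdr_threshold,
            "fc_threshold": config.fc_threshold,
            "seed": config.seed,
        },
    )
    return call_de(result, fdr_threshold=config.fdr_threshold, fc_threshold=config.fc_threshold)


def sam(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    config: SAMConfig = SAMConfig(),
    groups: tuple | None = None,
    contrast: str = "contrast",
) -> DEResult:
    """Full moderated-d route: statistic, permutation q-values, significance."""
    result = sam_qvalues(matrix, labels, config, groups=groups)
    result.contrast = contrast
    return result


def paired_t(matrix: ExpressionMatrix, pairing: pd.DataFrame) -> pd.DataFrame:
    """Classical paired t-test per gene on tumor-minus-normal differences.

    ``pairing`` needs 'normal' and 'tumor' columns of sample IDs, one row
    per patient. Returns a DataFrame with columns t, p (two-sided,
    df = n_pairs - 1) and mean_diff. A gene whose differences have zero
    variance gets t = +/-inf with p = 0 (or t = 0, p = 1 when the
    differences are all exactly zero).
    """
    for col in ("normal", "tumor"):
        if col not in pairing.columns:
            raise ValueError(f"pairing table requires a '{col}' column")
    if len(pairing) < 2:
        raise ValueError("need at least 2 complete pairs")
    missing = set(pairing["normal"]) | set(pairing["tumor"])
    missing -= set(matrix.samples)
    if missing:
        raise ValueError(f"pairing references samples absent from the matrix: {sorted(missing)[:5]}")

    normal = matrix.values[list(pairing["normal"])].to_numpy()
    tumor = matrix.values[list(pairing["tumor"])].to_numpy()
    diffs = tumor - normal
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t[zero_var & (mean > 0)] = np.inf
    t[zero_var & (mean < 0)] = -np.inf
    t[zero_var & (mean == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[zero_var & (mean == 0)] = 1.0

    return pd.DataFrame({"t": t, "p": p, "mean_diff": mean}, index=matrix.genes)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_de(
    matrix: ExpressionMatrix,
    pairing: pd.DataFrame,
    fdr_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    contrast: str = "paired",
) -> DEResult:
    """Paired-design differential expression: paired t + BH adjustment.

    Fold change is the linear ratio implied by the mean paired log2
    difference. By default significance is the BH-adjusted p alone
    (fc_threshold = 1); pass a larger ratio to add a fold-change gate.
    """
    tt = paired_t(matrix, pairing)
    q = bh_adjust(tt["p"].to_numpy())
    table = pd.DataFrame(
        {
            "statistic": tt["t"],
            "fc": 2.0 ** tt["mean_diff"],
            "direction": np.sign(tt["mean_diff"]).astype(int),
            "p": tt["p"],
            "q": q,
            "significant": False,
        },
        index=matrix.genes,
    )
    result = DEResult(
        table,
        contrast=contrast,
        method="paired_t",
        params={"fdr_threshold": fdr_threshold, "fc_threshold": fc_threshold, "n_pairs": len(pairing)},
    )
    return call_de(result, fdr_threshold=fdr_threshold, fc_threshold=fc_threshold)


def fold_change(
    matrix: ExpressionMatrix, labels: pd.Series, groups: tuple | None = None
) -> tuple[pd.Series, pd.Series]:
    """Linear fold change 2^(mean2 - mean1) and its direction per gene."""
    m1, m2, groups = _group_masks(pd.Series(labels).reindex(matrix.samples), groups)
    values = matrix.values.to_numpy()
    diff = values[:, m2].mean(axis=1) - values[:, m1].mean(axis=1)
    fc = pd.Series(2.0**diff, index=matrix.genes, name="fc")
    direction = pd.Series(np.sign(diff).astype(int), index=matrix.genes, name="direction")
    return fc, direction


def call_de(
    result: DEResult, fdr_threshold: float = 0.05, fc_threshold: float = 1.1
) -> DEResult:
    """Apply the joint significance rule to a DE table.

    significant <=> q below the FDR threshold AND symmetric fold change
    max(FC, 1/FC) strictly above the fold-change threshold. With
    fc_threshold = 1 the fold-change gate is inert except for exactly
    unchanged genes.
    """
    fc = result.table["fc"].to_numpy()
    with np.errstate(divide="ignore"):
        sym_fc = np.maximum(fc, 1.0 / fc)
    flag = (result.table["q"].to_numpy() < fdr_threshold) & (sym_fc > fc_threshold)
    result.table["significant"] = flag
    result.params.update({"fdr_threshold": fdr_threshold, "fc_threshold": fc_threshold})
    return result
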