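"""Survival analysis: Kaplan-Meier, log-rank, and Cox proportional hazards.

Multivariate Cox models, Kaplan-Meier curves and the log-rank test are
delegated to lifelines behind small typed result containers. Univariate Cox
fits go through a dedicated single-covariate Newton solver
(:func:`univariate_cox`) because the scoring and resampling stages fit the
same model thousands of times per run; it maximizes the Efron (or Breslow)
partial likelihood with step-halving and reports the Wald statistic from
the observed information. The two routes are cross-checked in the test
suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "UnivariateCoxFit",
    "CoxFit",
    "KMEstimate",
    "LogRankResult",
    "univariate_cox",
    "cox_score_statistic",
    "cox_fit",
    "km_estimate",
    "logrank_test",
    "stratified_analysis",
    "ConvergenceError",
]

_Z975 = stats.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    """Raised when a Cox fit fails to converge or the likelihood is monotone."""


# ---------------------------------------------------------------------------
# single-covariate Cox partial likelihood (Newton with Efron/Breslow ties)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnivariateCoxFit:
    """Result of a single-covariate Cox fit."""

    beta: float
    se: float
    n: int
    n_events: int
    ties: str
    loglik: float
    converged: bool

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - _Z975 * self.se)),
            float(np.exp(self.beta + _Z975 * self.se)),
        )

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))


def _cox1_prepare(x, time, event):
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (len(x) == len(time) == len(event)):
        raise ValueError("x, time and event must have equal length")
    if event.sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; Cox coefficient undefined")
    # descending time: the risk set at time t is a prefix of the arrays
    order = np.argsort(-time, kind="stable")
    return x[order], time[order], event[order]


def _cox1_loglik(beta: float, x, time, event, ties: str):
    """Partial log-likelihood, score and information for one covariate.

    Arrays must be sorted by descending time. Handles tied event times by
    the Efron or Breslow approximation; with no ties the two coincide.
    """
    eta = beta * x
    eta -= eta.max()  # overflow guard; partial likelihood is shift-invariant
    w = np.exp(eta)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * x)
    cwx2 = np.cumsum(w * x * x)

    # tie groups: runs of equal time
    boundaries = np.flatnonzero(np.r_[True, time[1:] != time[:-1]])
    ends = np.r_[boundaries[1:], len(time)] - 1  # inclusive last index per group

    dsum = np.add.reduceat(event.astype(float), boundaries)
    has_event = dsum > 0
    if not has_event.any():  # pragma: no cover - guarded earlier
        raise ValueError("no events")
    b = boundaries[has_event]
    e = ends[has_event]
    d = dsum[has_event]

    W = cw[e]
    S1 = cwx[e]
    S2 = cwx2[e]
    ev = (event == 1).astype(float)
    WD = np.add.reduceat(w * ev, boundaries)[has_event]
    S1D = np.add.reduceat(w * x * ev, boundaries)[has_event]
    S2D = np.add.reduceat(w * x * x * ev, boundaries)[has_event]
    xD = np.add.reduceat(x * ev, boundaries)[has_event]
    etaD = np.add.reduceat(eta * ev, boundaries)[has_event]

    ll = float(etaD.sum())
    grad = float(xD.sum())
    info = 0.0
    dmax = int(d.max())
    for l in range(dmax):
        mask = d > l
        frac = (l / d[mask]) if ties == "efron" else 0.0
        phi = W[mask] - frac * WD[mask]
        m1 = (S1[mask] - frac * S1D[mask]) / phi
        m2 = (S2[mask] - frac * S2D[mask]) / phi
        ll -= float(np.log(phi).sum())
        grad -= float(m1.sum())
        info += float((m2 - m1 * m1).sum())
    return ll, grad, info


def univariate_cox(
    x,
    time,
    event,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 100,
) -> UnivariateCoxFit:
    """Fit a Cox proportional-hazards model with a single covariate.

    Newton-Raphson on the partial likelihood with step halving;
    convergence when the relative log-likelihood change drops below ``tol``.
    A coefficient running away beyond |beta| = 50 signals a monotone
    likelihood (complete separation) and raises :class:`ConvergenceError`
    rather than returning a spurious estimate.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    xs, ts, es = _cox1_prepare(x, time, event)
    beta = 0.0
    ll, grad, info = _cox1_loglik(beta, xs, ts, es, ties)
    converged = False
    for _ in range(max_iter):
        if info <= 0:
            raise ConvergenceError("non-positive information; covariate degenerate")
        step = grad / info
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox1_loglik(new_beta, xs, ts, es, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox1_loglik(new_beta, xs, ts, es, ties)
            halvings += 1
        if abs(new_beta) > 50:
            raise ConvergenceError(
                "monotone partial likelihood (complete separation); "
                "coefficient diverges"
            )
        done = abs(new_ll - ll) < tol * (abs(ll) + 1.0)
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if done:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"Cox fit did not converge in {max_iter} iterations")
    if info <= 0:
        raise ConvergenceError("non-positive information at the optimum")
    scale = float(np.std(xs))
    if abs(beta) * scale > 10 or (1.0 / np.sqrt(info)) * scale > 50:
        # the likelihood keeps improving as |beta| grows: complete separation
        raise ConvergenceError(
            "monotone partial likelihood (complete separation); coefficient unbounded"
        )
    return UnivariateCoxFit(
        beta=float(beta),
        se=float(1.0 / np.sqrt(info)),
        n=len(xs),
        n_events=int(es.sum()),
        ties=ties,
        loglik=float(ll),
        converged=True,
    )


def cox_score_statistic(x, time, event, ties: str = "efron") -> tuple[float, float]:
    """Cox score test at beta = 0: statistic U(0)^2 / I(0) and its chi2(1) p.

    For a two-group covariate with no tied event times this equals the
    log-rank chi-square exactly.
    """
    xs, ts, es = _cox1_prepare(x, time, event)
    _, grad, info = _cox1_loglik(0.0, xs, ts, es, ties)
    statistic = grad * grad / info
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


# ---------------------------------------------------------------------------
# lifelines-backed surfaces
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Cox regression summary: one row per covariate.

    ``table`` columns: coef, se, z, hr, ci_low, ci_high, p. The 95% interval
    is exp(coef +/- 1.96 se).
    """

    table: pd.DataFrame
    n: int
    n_events: int
    ties: str
    warnings: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "covariate"
        out.to_csv(path, sep="\t", float_format="%.6g")


def cox_fit(data: pd.DataFrame, covariates=None, ties: str = "efron") -> CoxFit:
    """Fit a (possibly multivariate) Cox model on a patient-level frame.

    ``data`` needs 'time' and 'event' columns; ``covariates`` selects the
    model terms (default: every other column). Convergence problems raised
    or warned by the optimizer are re-raised as :class:`ConvergenceError`
    or recorded on the result, never silently dropped.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    for col in ("time", "event"):
        if col not in data.columns:
            raise ValueError(f"data requires a '{col}' column")
    if covariates is None:
        covariates = [c for c in data.columns if c not in ("time", "event")]
    covariates = list(covariates)
    if not covariates:
        raise ValueError("no covariates to fit")
    frame = data[["time", "event", *covariates]].copy()
    constant = [c for c in covariates if frame[c].nunique() < 2]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    if frame["event"].sum() < 1:
        raise ValueError("Cox fit requires at least one event")

    fitter = CoxPHFitter()
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fitter.fit(
                frame,
                duration_col="time",
                event_col="event",
                robust=False,
                fit_options={"step_size": 0.95},
            )
        except Exception as exc:  # lifelines ConvergenceError and friends
            raise ConvergenceError(f"Cox fit failed: {exc}") from exc
        for w in caught:
            if "converg" in str(w.message).lower() or "variance" in str(w.message).lower():
                captured.append(str(w.message))
    summ = fitter.summary
    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "se": summ["se(coef)"],
            "z": summ["z"],
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef"] - _Z975 * summ["se(coef)"]),
            "ci_high": np.exp(summ["coef"] + _Z975 * summ["se(coef)"]),
            "p": summ["p"],
        }
    )
    table.index = summ.index.get_level_values(-1)
    return CoxFit(
        table=table,
        n=len(frame),
        n_events=int(frame["event"].sum()),
        ties=ties,
        warnings=captured,
    )


@dataclass
class KMEstimate:
    """Product-limit survival curve for one group."""

    times: np.ndarray  # ordered distinct observed times
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray
    censor_times: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )

    def plot(self, ax=None, **kwargs):
        """Step plot of the survival curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.r_[0.0, self.times]
        y = np.r_[1.0, self.survival]
        ax.step(x, y, where="post", label=self.label or None, **kwargs)
        ax.set_xlabel("time (months)")
        ax.set_ylabel("recurrence-free survival")
        ax.set_ylim(0, 1.02)
        return ax


def km_estimate(times, events, group=None):
    """Kaplan-Meier estimate, overall or per group label.

    Returns a single :class:`KMEstimate` when ``group`` is None, otherwise a
    dict mapping group label to its estimate.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if group is None:
        if len(times) == 0:
            raise ValueError("empty group")
        kmf = KaplanMeierFitter()
        kmf.fit(times, events)
        surv = kmf.survival_function_["KM_estimate"]
        grid = surv.index.to_numpy()
        keep = grid > 0 if 0.0 not in times else np.ones(len(grid), bool)
        at_risk = kmf.event_table["at_risk"].reindex(grid[keep]).to_numpy()
        return KMEstimate(
            times=grid[keep],
            survival=surv.to_numpy()[keep],
            at_risk=at_risk,
            censor_times=np.sort(times[events == 0]),
        )
    group = pd.Series(np.asarray(group))
    out = {}
    for label in group.unique():
        mask = (group == label).to_numpy()
        est = km_estimate(times[mask], events[mask])
        est.label = str(label)
        out[label] = est
    return out


@dataclass
class LogRankResult:
    """Two-group log-rank test with per-group observed/expected events."""

    statistic: float
    p: float
    observed: dict
    expected: dict

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("log-rank statistic must be non-negative")


def _observed_expected(times, events, mask1):
    """Per-group observed and expected event counts over the pooled risk sets."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    o1 = e1 = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & mask1).sum()
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & mask1).sum())
        o1 += d1
        e1 += d * n1 / n
    total = int(events.sum())
    return o1, e1, total


def logrank_test(times, events, group) -> LogRankResult:
    """Standard two-group log-rank test (hypergeometric variance).

    The chi-square statistic and p-value come from lifelines; the
    per-group observed/expected decomposition is reported alongside and
    always satisfies sum(observed - expected) = 0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = pd.Series(np.asarray(group))
    labels = group.unique()
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly two groups, found {len(labels)}")
    if (group == labels[0]).sum() == 0 or (group == labels[1]).sum() == 0:
        raise ValueError("one group is empty")
    res = multivariate_logrank_test(times, group.to_numpy(), events)
    mask1 = (group == labels[0]).to_numpy()
    o1, e1, total = _observed_expected(times, events, mask1)
    observed = {labels[0]: float(o1), labels[1]: float(total - o1)}
    expected = {labels[0]: float(e1), labels[1]: float(total - e1)}
    return LogRankResult(
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        observed=observed,
        expected=expected,
    )


@dataclass
class StratumResult:
    """Risk-group analysis within one stratum of a clinical factor."""

    cox: CoxFit
    km: dict
    logrank: LogRankResult
    n: int
    n_events: int


def stratified_analysis(
    cohort,
    factor: pd.Series,
    risk_group: pd.Series,
    ties: str = "efron",
) -> tuple[dict, list]:
    """Redo the risk-group Cox/KM/log-rank analysis within each stratum.

    ``factor`` partitions the cohort (e.g. age dichotomized at 60, stage);
    ``risk_group`` carries the whole-cohort positive/negative classification
    into the strata — it is *not* re-derived per stratum. Strata in which
    either risk group has no events (or only one group is present) are
    flagged unevaluable and skipped; their labels are returned separately.
    """
    factor = pd.Series(factor).reindex(cohort.samples)
    risk = pd.Series(risk_group).reindex(cohort.samples)
    if factor.isna().any():
        raise ValueError("factor does not cover every patient in the cohort")
    results: dict = {}
    skipped: list = []
    for level in pd.unique(factor):
        mask = (factor == level).to_numpy()
        time = cohort.time.to_numpy()[mask]
        event = cohort.event.to_numpy()[mask]
        grp = risk.to_numpy()[mask]
        levels = np.unique(grp)
        if len(levels) < 2 or any(event[grp == g].sum() < 1 for g in levels):
            skipped.append(level)
            continue
        frame = pd.DataFrame(
            {"time": time, "event": event, "risk_positive": (grp == levels.max()).astype(int)}
        )
        fit = cox_fit(frame, ["risk_positive"], ties=ties)
        km = km_estimate(time, event, grp)
        lr = logrank_test(time, event, grp)
        results[level] = StratumResult(
            cox=fit, km=km, logrank=lr, n=int(mask.sum()), n_events=int(event.sum())
        )
    return results, skipped
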