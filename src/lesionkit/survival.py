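"""Survival and association statistics for cohort analysis.

Kaplan–Meier product-limit curves and the log-rank test are implemented
directly so that the exact intermediate tables (at-risk counts, observed /
expected / variance per event time) are available for auditing. Cox
proportional-hazards models are fitted with lifelines (Efron tie handling);
Spearman correlation comes from scipy. ROC analysis with the Youden-index
cutoff is implemented over all distinct-score thresholds.

P-values are two-sided and no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "CoxResult",
    "ROCResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "spearman",
    "roc_youden",
    "synergy_analysis",
]

log = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Product-limit estimate. ``median`` is the first time with S(t) <= 0.5,
    NaN when the curve never reaches 0.5."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival_prob,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


@dataclass
class CoxResult:
    """Per-covariate partial-likelihood estimates (log HR scale)."""

    covariates: list[str]
    coef: np.ndarray
    hazard_ratio: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hazard_ratio,
                "se": self.se,
                "p": self.p_value,
                "HR_ci_lower": self.ci_lower,
                "HR_ci_upper": self.ci_upper,
            },
            index=self.covariates,
        )


@dataclass
class ROCResult:
    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_cutoff: float
    youden_index: float
    p_value: float = field(default=np.nan)


def _clean(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1D arrays of equal length")
    if t.size < 1:
        raise ValueError("need at least one subject")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    return t, e


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator.

    With no censoring the curve equals the empirical survival function. An
    all-censored sample yields S identically 1 and an undefined median.
    """
    t, e = _clean(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = t.size
    surv, at_risk, deaths = [], [], []
    s = 1.0
    for tj in event_times:
        nj = int((t >= tj).sum())
        dj = int(((t == tj) & e).sum())
        s *= 1.0 - dj / nj
        surv.append(s)
        at_risk.append(nj)
        deaths.append(dj)
    surv = np.asarray(surv)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(event_times[below[0]]) if below.size else float("nan")
    return SurvivalCurve(
        event_times=event_times,
        survival_prob=surv,
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(deaths),
        median=median,
    )


def logrank_test(times, events, group, return_table: bool = False):
    """K-sample log-rank test.

    At each distinct event time the observed deaths per group are compared
    with their hypergeometric expectation; the chi-square statistic uses the
    full covariance of the first K-1 groups and K-1 degrees of freedom.
    ``return_table=True`` additionally returns the per-event-time O/E/V table.
    """
    t, e = _clean(times, events)
    g = np.asarray(group)
    if g.shape != t.shape:
        raise ValueError("group must align with times")
    levels, gidx = np.unique(g, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")

    event_times = np.unique(t[e])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    rows = []
    for tj in event_times:
        at_risk = t >= tj
        nj = int(at_risk.sum())
        dj = int((e & (t == tj)).sum())
        njg = np.bincount(gidx[at_risk], minlength=k).astype(float)
        djg = np.bincount(gidx[e & (t == tj)], minlength=k).astype(float)
        O += djg
        ej = dj * njg / nj
        E += ej
        if nj > 1:
            frac = njg / nj
            vj = dj * (nj - dj) / (nj - 1) * (np.diag(frac) - np.outer(frac, frac))
            V += vj
        rows.append({"time": tj, "n_at_risk": nj, "n_events": dj,
                     **{f"O_{lv}": djg[i] for i, lv in enumerate(levels)},
                     **{f"E_{lv}": ej[i] for i, lv in enumerate(levels)}})

    d = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(d @ np.linalg.solve(Vsub, d))
    except np.linalg.LinAlgError:
        chi2 = float(d @ np.linalg.pinv(Vsub) @ d)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    if return_table:
        return chi2, p, pd.DataFrame(rows)
    return chi2, p


def cox_fit(covariates, times, events, alpha: float = 0.05) -> CoxResult:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    ``covariates`` is a DataFrame (or dict / 2D array) of one or more
    columns; constant columns and samples with fewer than 2 events are
    rejected, as is complete separation (monotone likelihood).
    """
    t, e = _clean(times, events)
    X = pd.DataFrame(covariates)
    if X.shape[0] != t.size:
        raise ValueError("covariates must have one row per subject")
    if int(e.sum()) < 2:
        raise ValueError("Cox model needs at least 2 events")
    for col in X.columns:
        if X[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant")
    df = X.copy()
    df["_time"] = t
    df["_event"] = e.astype(int)
    fitter = CoxPHFitter(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fitter.fit(df, duration_col="_time", event_col="_event", show_progress=False)
        except Exception as exc:
            raise ValueError(f"Cox fit failed (possible complete separation): {exc}") from exc
    coef = fitter.params_.to_numpy()
    if np.any(np.abs(coef) > 15):
        raise ValueError("monotone partial likelihood (complete separation): coefficient diverges")
    summ = fitter.summary
    return CoxResult(
        covariates=[str(c) for c in X.columns],
        coef=coef,
        hazard_ratio=np.exp(coef),
        se=summ["se(coef)"].to_numpy(),
        p_value=summ["p"].to_numpy(),
        ci_lower=np.exp(summ["coef lower 95%"].to_numpy()),
        ci_upper=np.exp(summ["coef upper 95%"].to_numpy()),
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def roc_youden(score, label) -> ROCResult:
    """ROC curve over all distinct-score thresholds with the Youden cutoff.

    A positive call is ``score > cutoff`` (strict). AUC is the trapezoidal
    area under (1 - specificity, sensitivity); the cutoff maximizes
    sensitivity + specificity - 1, ties broken toward the smallest cutoff.
    The p-value is the two-sided normal approximation of the Mann-Whitney
    test of AUC = 0.5.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(label).astype(bool)
    if s.shape != y.shape:
        raise ValueError("score and label must align")
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes present")

    # candidate cutoffs: one below all scores, then every distinct score
    uniq = np.unique(s)
    cutoffs = np.concatenate(([uniq[0] - 1.0], uniq))
    sens = np.array([(s[y] > c).mean() for c in cutoffs])
    spec = np.array([(s[~y] <= c).mean() for c in cutoffs])
    # ROC points ordered by (fpr, sens) so tie groups trace the staircase
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec - 1.0
    best = int(np.nonzero(j == j.max())[0][0])  # ties -> smallest cutoff
    u = stats.mannwhitneyu(s[y], s[~y], alternative="two-sided")
    return ROCResult(
        auc=auc,
        thresholds=cutoffs,
        sensitivity=sens,
        specificity=spec,
        youden_cutoff=float(cutoffs[best]),
        youden_index=float(j[best]),
        p_value=float(u.pvalue),
    )


def synergy_analysis(df: pd.DataFrame, time_col: str = "pfs_days", event_col: str = "pfs_event",
                     group_col: str = "synergy_group"):
    """Stratified KM curves and the two pairwise log-rank comparisons for the
    neither / either / both grouping (both-vs-either and neither-vs-either).

    Returns (curves, comparisons): a dict of SurvivalCurve per stratum and a
    DataFrame of pairwise chi-square / p-values. Empty strata skip their
    comparison with a warning.
    """
    curves: dict[str, SurvivalCurve] = {}
    for name, sub in df.groupby(group_col):
        curves[str(name)] = km_estimate(sub[time_col], sub[event_col])
    rows = []
    for a, b in (("both", "either"), ("neither", "either")):
        sub = df[df[group_col].isin([a, b])]
        if sub[group_col].nunique() < 2:
            warnings.warn(f"stratum missing for comparison {a} vs {b}; skipped", stacklevel=2)
            continue
        chi2, p = logrank_test(sub[time_col], sub[event_col], sub[group_col])
        rows.append({"comparison": f"{a}_vs_{b}", "chi_square": chi2, "p": p})
    if not rows:
        warnings.warn("all patients fall in one synergy group; no comparisons", stacklevel=2)
    return curves, pd.DataFrame(rows, columns=["comparison", "chi_square", "p"])
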