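"""ROC analysis with DeLong inference, Youden cut-offs, and Kaplan-Meier
survival stratification.

The AUC is the Mann-Whitney kernel (ties counted half); its standard error
follows DeLong's structural-component decomposition.  The operating
cut-off maximizes the Youden index J = sensitivity + specificity - 1 over
the observed score values, with the scoring direction chosen so that the
AUC is at least 0.5 (a prognostic feature may be elevated in the deceased,
like SUVpeak, or depressed, like GLRLM_LRLGE).  Kaplan-Meier estimation
uses the product-limit estimator with Greenwood variance; groups are
compared with the log-rank test, and the reported risk ratio is the
log-rank observed/expected hazard ratio ``(O1/E1)/(O2/E2)`` with the
standard log-scale confidence interval ``exp(log RR +/- 1.96 sqrt(1/E1 +
1/E2))`` — the estimator MedCalc-style Kaplan-Meier reports, labelled
``risk_ratio_oe`` to avoid confusion with a Cox hazard ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

log = logging.getLogger(__name__)

GREATER = "greater-is-positive"
LESSER = "lesser-is-positive"


@dataclass
class RocResult:
    thresholds: np.ndarray  # sorted ascending, observed score values
    sensitivity: np.ndarray  # P(score >= t | positive)
    specificity: np.ndarray  # P(score <  t | negative)
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    p_vs_half: float
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    direction: str
    youden_j: float


@dataclass
class KmCurve:
    event_times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    greenwood_var: np.ndarray
    median: float  # inf if not reached
    median_ci: tuple[float, float]
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time ``t``."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalComparison:
    logrank_chi2: float
    p_value: float
    risk_ratio_oe: float
    rr_ci95: tuple[float, float]
    observed: tuple[float, float]
    expected: tuple[float, float]
    curves: dict[str, KmCurve]


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size for p in pos])
    v01 = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / pos.size for n in neg])
    return v10, v01


def roc_delong(scores, labels) -> RocResult:
    """Empirical ROC with DeLong AUC standard error (greater-is-positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.size != labels.size:
        raise ValueError("scores and labels lengths differ")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both label classes must be present")

    v10, v01 = _delong_components(pos, neg)
    auc = float(v10.mean())
    if pos.size > 1 and neg.size > 1:
        var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    else:
        var = 0.0
    se = float(np.sqrt(var))
    lo, hi = auc - 1.96 * se, auc + 1.96 * se
    ci = (max(0.0, lo), min(1.0, hi))
    if se > 0:
        z = (auc - 0.5) / se
        p_half = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p_half = 1.0 if auc == 0.5 else 0.0

    thresholds = np.unique(scores)
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_se=se,
        ci95=ci,
        p_vs_half=p_half,
        scores=scores,
        labels=labels,
    )


def youden_cutoff(roc: RocResult) -> CutoffResult:
    """Cut-off maximizing J = sens + spec - 1 over observed score values.

    The direction is chosen so the effective AUC is >= 0.5.  Ties in J are
    broken toward higher specificity, then toward the smaller cut-off.
    """
    if roc.scores is None:
        raise ValueError("RocResult lacks raw scores")
    direction = GREATER if roc.auc >= 0.5 else LESSER
    pos = roc.scores[roc.labels == 1]
    neg = roc.scores[roc.labels == 0]
    best = None
    for t in np.unique(roc.scores):
        if direction == GREATER:
            sens = (pos >= t).mean()
            spec = (neg < t).mean()
        else:
            sens = (pos <= t).mean()
            spec = (neg > t).mean()
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12), -t)  # higher J, higher spec, smaller t
        if best is None or key > best[0]:
            best = (key, float(t), float(sens), float(spec), float(j))
    _, cutoff, sens, spec, j = best
    return CutoffResult(
        cutoff=cutoff,
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        direction=direction,
        youden_j=j,
    )


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    t = ev.index.to_numpy(dtype=float)
    d = ev["observed"].to_numpy(dtype=float)
    n = ev["at_risk"].to_numpy(dtype=float)
    if t.size:
        surv = kmf.survival_function_at_times(t).to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            terms = np.where(n > d, d / (n * (n - d)), np.inf)
        # where S has hit 0 the Greenwood product is 0 by convention
        gw = np.where(surv > 0, surv**2 * np.cumsum(terms), 0.0)
    else:
        surv = np.array([])
        gw = np.array([])
    median = float(kmf.median_survival_time_)
    ci_df = median_survival_times(kmf.confidence_interval_)
    lo, hi = (float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1]))
    return KmCurve(
        event_times=t,
        at_risk=n,
        deaths=d,
        survival=surv,
        greenwood_var=gw,
        median=median,
        median_ci=(lo, hi),
        n=int(times.size),
    )


def _observed_expected(times, events, mask1):
    """Log-rank observed and expected event counts per group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    o1 = e1 = o2 = e2 = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n1 = float((at_risk & mask1).sum())
        n2 = float((at_risk & ~mask1).sum())
        d = float(((times == t) & (events == 1)).sum())
        d1 = float(((times == t) & (events == 1) & mask1).sum())
        nj = n1 + n2
        o1 += d1
        o2 += d - d1
        e1 += d * n1 / nj
        e2 += d * n2 / nj
    return o1, e1, o2, e2


def compare_groups(times, events, group_labels) -> SurvivalComparison:
    """Log-rank test and O/E risk ratio between two groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(group_labels)
    uniq = sorted(pd.unique(groups).tolist())
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {uniq}")
    m1 = groups == uniq[0]
    if m1.all() or (~m1).all():
        raise ValueError("both groups must be non-empty")

    lr = logrank_test(times[m1], times[~m1], events[m1], events[~m1])
    o1, e1, o2, e2 = _observed_expected(times, events, m1)
    if e1 == 0 or e2 == 0 or o1 == 0 or o2 == 0:
        log.warning("zero observed/expected events in a group; risk ratio degenerate")
        rr = np.inf if (o2 == 0 or e1 == 0) else 0.0
        if o1 == 0 and o2 == 0:
            rr = 1.0
        ci = (0.0, np.inf)
    else:
        rr = (o1 / e1) / (o2 / e2)
        half = 1.96 * np.sqrt(1.0 / e1 + 1.0 / e2)
        ci = (float(rr * np.exp(-half)), float(rr * np.exp(half)))
    curves = {
        str(uniq[0]): km_estimate(times[m1], events[m1]),
        str(uniq[1]): km_estimate(times[~m1], events[~m1]),
    }
    return SurvivalComparison(
        logrank_chi2=float(lr.test_statistic),
        p_value=float(lr.p_value),
        risk_ratio_oe=float(rr),
        rr_ci95=ci,
        observed=(o1, o2),
        expected=(e1, e2),
        curves=curves,
    )


def stratify_by_cutoff(
    cohort: pd.DataFrame,
    feature: str,
    cutoff: float,
    direction: str = GREATER,
    time_col: str = "time_days",
    event_col: str = "event",
) -> SurvivalComparison:
    """Dichotomize a cohort at ``cutoff`` and compare survival of the strata.

    The 'high-risk' stratum holds values >= cutoff for greater-is-positive
    scores and <= cutoff otherwise.
    """
    if feature not in cohort.columns:
        raise ValueError(f"feature {feature!r} missing from cohort table")
    vals = cohort[feature].to_numpy(dtype=float)
    if direction == GREATER:
        high = vals >= cutoff
    elif direction == LESSER:
        high = vals <= cutoff
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if high.all() or not high.any():
        raise ValueError(f"cutoff {cutoff} leaves an empty stratum for {feature!r}")
    groups = np.where(high, "high_risk", "low_risk")
    return compare_groups(
        cohort[time_col].to_numpy(dtype=float),
        cohort[event_col].to_numpy(),
        groups,
    )
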