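"""Univariate feature screening and redundancy pruning.

Each feature is compared between survivors and deceased with a two-sided
Mann-Whitney U test (exact null distribution for small tie-free samples,
normal approximation with tie and continuity corrections otherwise);
features with p < alpha (default 0.05, no multiplicity correction) are
kept and then pruned greedily by Spearman rank correlation: walking the
screened features in order of ascending p (ties broken by name), a feature
is retained only if |rho| < rho_max (default 0.85) against every feature
already retained.  Dropped features record the blocking partner, so the
pruning is fully auditable and deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class UTestResult:
    u_statistic: float  # U for group 2 ranking above group 1
    p_value: float
    auc_equivalent: float  # U / (n1 * n2): P(group2 > group1) + 0.5 P(tie)
    median_1: float
    median_2: float
    iqr_1: tuple[float, float]
    iqr_2: tuple[float, float]
    n_1: int
    n_2: int


@dataclass
class ScreenedFeature:
    name: str
    result: UTestResult


@dataclass
class SelectionReport:
    screened: list[ScreenedFeature]
    correlation_matrix: pd.DataFrame
    retained: list[str]
    dropped: list[dict] = field(default_factory=list)
    alpha: float = 0.05
    rho_max: float = 0.85


def mann_whitney(x, y) -> UTestResult:
    """Two-sided Mann-Whitney U test of group 1 (``x``) vs group 2 (``y``).

    ``auc_equivalent`` is the probability that a random group-2 value
    exceeds a random group-1 value (ties counted half) — identical to the
    ROC AUC of the pooled scores against the group label.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        log.info("all values identical across both groups; p set to 1")
        u_y = n1 * n2 / 2.0
        return UTestResult(
            u_statistic=u_y, p_value=1.0, auc_equivalent=0.5,
            median_1=float(np.median(x)), median_2=float(np.median(y)),
            iqr_1=_iqr(x), iqr_2=_iqr(y), n_1=n1, n_2=n2,
        )

    method = "exact" if (n1 * n2 <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(y, x, alternative="two-sided", method=method)
    u_y = float(res.statistic)
    return UTestResult(
        u_statistic=u_y,
        p_value=float(res.pvalue),
        auc_equivalent=u_y / (n1 * n2),
        median_1=float(np.median(x)),
        median_2=float(np.median(y)),
        iqr_1=_iqr(x),
        iqr_2=_iqr(y),
        n_1=n1,
        n_2=n2,
    )


def _iqr(v: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(v, [25, 75])
    return (float(q1), float(q3))


def univariate_screen(
    features: pd.DataFrame, event: pd.Series | np.ndarray, alpha: float = 0.05
) -> list[ScreenedFeature]:
    """Mann-Whitney screen of every feature column against the outcome.

    ``event`` is 1 for deceased, 0 for survivors.  Features with strictly
    p < ``alpha`` are returned sorted by ascending p (ties by name); no
    multiple-testing correction is applied.
    """
    ev = np.asarray(event).astype(int)
    if len(ev) != len(features):
        raise ValueError("event vector and feature table lengths differ")
    if (ev == 1).sum() < 2 or (ev == 0).sum() < 2:
        raise ValueError("need at least 2 patients in each outcome group")
    out = []
    for name in features.columns:
        col = features[name].to_numpy(dtype=float)
        res = mann_whitney(col[ev == 0], col[ev == 1])
        if res.p_value < alpha:
            out.append(ScreenedFeature(name=name, result=res))
    out.sort(key=lambda f: (f.result.p_value, f.name))
    return out


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in ranks; Spearman rho undefined", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def correlation_matrix(features: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    """Spearman correlation matrix over the named feature columns."""
    sub = features[names]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mat = sub.corr(method="spearman")
    return mat


def redundancy_filter(
    screened: list[ScreenedFeature],
    corr: pd.DataFrame,
    rho_max: float = 0.85,
    alpha: float = 0.05,
) -> SelectionReport:
    """Greedy redundancy pruning at |rho| < ``rho_max``.

    Features are visited by ascending screening p-value (name as
    tie-break); a feature is retained iff its |rho| against every
    already-retained feature is strictly below ``rho_max``.
    """
    order = sorted(screened, key=lambda f: (f.result.p_value, f.name))
    retained: list[str] = []
    dropped: list[dict] = []
    for feat in order:
        blocker = None
        for kept in retained:
            rho = float(corr.loc[feat.name, kept])
            if np.isnan(rho) or abs(rho) >= rho_max:
                blocker = (kept, rho)
                break
        if blocker is None:
            retained.append(feat.name)
        else:
            dropped.append(
                {
                    "feature": feat.name,
                    "reason": "correlated with retained feature",
                    "partner": blocker[0],
                    "rho": blocker[1],
                }
            )
    return SelectionReport(
        screened=order,
        correlation_matrix=corr,
        retained=retained,
        dropped=dropped,
        alpha=alpha,
        rho_max=rho_max,
    )


def select_features(
    features: pd.DataFrame,
    event,
    alpha: float = 0.05,
    rho_max: float = 0.85,
) -> SelectionReport:
    """Screen then prune in one call."""
    screened = univariate_screen(features, event, alpha=alpha)
    names = [f.name for f in screened]
    if not names:
        return SelectionReport(
            screened=[],
            correlation_matrix=pd.DataFrame(),
            retained=[],
            alpha=alpha,
            rho_max=rho_max,
        )
    corr = correlation_matrix(features, names)
    return redundancy_filter(screened, corr, rho_max=rho_max, alpha=alpha)
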