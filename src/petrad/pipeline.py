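"""End-to-end study orchestration: cohort summary, screening, ROC and KM.

``run_study`` takes a feature table and a clinical table (read from CSV,
passed in memory, or synthesized), excludes patients with incomplete rows
(logging each exclusion with its reason), summarizes the cohort, screens
features, prunes redundant ones, and computes ROC/cut-off/Kaplan-Meier
results for every retained feature.  The report is a plain JSON-able dict;
all percentages are recomputed from counts at report time, never stored.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import selection, survival
from .synthetic import CohortSpec, make_cohort

log = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("time_days", "event")


@dataclass
class RunConfig:
    features_csv: str | None = None
    clinical_csv: str | None = None
    synthetic: CohortSpec | None = None
    alpha: float = 0.05
    rho_max: float = 0.85
    segmentation_fraction: float = 0.40
    horizon_days: float = 730.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.rho_max <= 1):
            raise ValueError("rho_max must lie in (0, 1]")
        if not (0 < self.segmentation_fraction < 1):
            raise ValueError("segmentation fraction must lie in (0, 1)")


def read_clinical(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="patient_id")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required columns {missing}")
    return df


def read_features(path: str) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")


def summarize_cohort(clinical: pd.DataFrame) -> dict:
    """Counts, percentages and numeric summaries of the clinical table.

    Percentages are always count / total * 100 of the rows actually present
    — never copied from an input column.
    """
    if clinical.empty:
        raise ValueError("empty clinical table")
    n = len(clinical)
    n_dead = int(clinical["event"].sum())
    n_alive = n - n_dead
    out = {
        "n": n,
        "survivors": {"count": n_alive, "percent": 100.0 * n_alive / n},
        "deaths": {"count": n_dead, "percent": 100.0 * n_dead / n},
        "followup_days_median": float(clinical["time_days"].median()),
    }
    for col in clinical.columns:
        if col in CLINICAL_COLUMNS:
            continue
        series = clinical[col]
        if series.dtype.kind in "if":
            out[col] = {"mean": float(series.mean()), "sd": float(series.std())}
        else:
            counts = series.value_counts().sort_index()
            out[col] = {
                str(level): {"count": int(c), "percent": 100.0 * int(c) / n}
                for level, c in counts.items()
            }
    return out


def _exclude_incomplete(features: pd.DataFrame, clinical: pd.DataFrame):
    """Drop patients with missing rows or NaNs; return tables + exclusion log."""
    exclusions = []
    common = features.index.intersection(clinical.index)
    for pid in features.index.difference(clinical.index):
        exclusions.append({"patient_id": str(pid), "reason": "no clinical record"})
    for pid in clinical.index.difference(features.index):
        exclusions.append({"patient_id": str(pid), "reason": "no feature record"})
    f = features.loc[common]
    c = clinical.loc[common]
    bad = f.index[f.isna().any(axis=1)].union(c.index[c[list(CLINICAL_COLUMNS)].isna().any(axis=1)])
    for pid in bad:
        exclusions.append({"patient_id": str(pid), "reason": "missing values"})
    keep = common.difference(bad)
    for ex in exclusions:
        log.info("excluding patient %s: %s", ex["patient_id"], ex["reason"])
    return features.loc[keep], clinical.loc[keep], exclusions


def run_study(cfg: RunConfig):
    """Run screening, redundancy pruning and survival analysis end to end."""
    if cfg.synthetic is not None:
        features, clinical, _ = make_cohort(
            dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        )
    else:
        if cfg.features_csv is None or cfg.clinical_csv is None:
            raise ValueError("provide features_csv and clinical_csv, or a synthetic spec")
        features = read_features(cfg.features_csv)
        clinical = read_clinical(cfg.clinical_csv)

    features, clinical, exclusions = _exclude_incomplete(features, clinical)
    event = clinical["event"].astype(int)
    if (event == 1).sum() < 2 or (event == 0).sum() < 2:
        raise ValueError("fewer than 2 patients per outcome group after exclusions")

    report = {
        "config": {
            "alpha": cfg.alpha,
            "rho_max": cfg.rho_max,
            "segmentation_fraction": cfg.segmentation_fraction,
            "horizon_days": cfg.horizon_days,
            "seed": cfg.seed,
            "synthetic": dataclasses.asdict(cfg.synthetic) if cfg.synthetic else None,
        },
        "exclusions": exclusions,
        "cohort": summarize_cohort(clinical),
    }

    sel = selection.select_features(features, event, alpha=cfg.alpha, rho_max=cfg.rho_max)
    report["screening"] = [
        {
            "feature": f.name,
            "p_value": f.result.p_value,
            "u_statistic": f.result.u_statistic,
            "auc_equivalent": f.result.auc_equivalent,
            "median_survivors": f.result.median_1,
            "iqr_survivors": list(f.result.iqr_1),
            "median_deceased": f.result.median_2,
            "iqr_deceased": list(f.result.iqr_2),
        }
        for f in sel.screened
    ]
    report["selection"] = {"retained": sel.retained, "dropped": sel.dropped}

    cohort = features.join(clinical[["time_days", "event"]])
    per_feature = {}
    for name in sel.retained:
        roc = survival.roc_delong(features[name].to_numpy(), event.to_numpy())
        cut = survival.youden_cutoff(roc)
        try:
            comp = survival.stratify_by_cutoff(
                cohort, name, cut.cutoff,
                direction=cut.direction,
            )
            km = {
                g: {
                    "n": c.n,
                    "median_days": c.median,
                    "median_ci": list(c.median_ci),
                    "survival_at_horizon": c.survival_at(cfg.horizon_days),
                }
                for g, c in comp.curves.items()
            }
            comp_d = {
                "logrank_chi2": comp.logrank_chi2,
                "logrank_p": comp.p_value,
                "risk_ratio_oe": comp.risk_ratio_oe,
                "rr_ci95": list(comp.rr_ci95),
                "km": km,
            }
        except ValueError as err:
            comp_d = {"error": str(err)}
        per_feature[name] = {
            "auc": roc.auc,
            # AUC in the discriminating direction (as ROC curves are reported)
            "auc_directed": max(roc.auc, 1.0 - roc.auc),
            "auc_se": roc.auc_se,
            "auc_ci95": list(roc.ci95),
            "p_vs_half": roc.p_vs_half,
            "cutoff": cut.cutoff,
            "sensitivity_pct": cut.sensitivity,
            "specificity_pct": cut.specificity,
            "direction": cut.direction,
            "survival": comp_d,
        }
    report["prognostic"] = per_feature

    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        with open(os.path.join(cfg.out_dir, "study_report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return str(obj)
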