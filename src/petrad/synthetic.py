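"""Synthetic PET phantoms and prognostic cohorts.

Because no patient scans are distributed with the study design this
package implements, every pipeline stage is exercised on synthetic data:

* ``make_phantom`` builds a tumour-bearing PET volume on a realistic
  whole-body-PET grid (default 4.07 x 4.07 x 5.0 mm voxels): a low-uptake
  background with Gaussian noise and an ellipsoidal lesion whose uptake
  falls off radially from a controllable peak SUV.  Intratumoral
  heterogeneity is modelled as a correlated Gaussian random field added
  inside the lesion (clipped at zero) — the simplest knob whose effect on
  run-length/zone texture is predictably monotone in the correlation
  length — with an optional two-compartment necrotic core.

* ``make_cohort`` builds a two-group cohort table mirroring the study
  conditions this pipeline targets: 47 patients of whom 11 die within a
  730-day horizon, a designated prognostic feature separating the groups
  at a designed AUC (default 0.74), strongly correlated nuisance blocks
  (|rho| > 0.85 within block) to exercise redundancy pruning, independent
  null features, and survival times from an exponential model with
  administrative censoring at the horizon.

Both generators are pure functions of their spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .imaging import SUV, Volume, VoiMask

#: FIGO stage composition emulated by default (counts for a 47-patient cohort).
FIGO_COUNTS_47 = {"IB2": 2, "II": 4, "III": 21, "IV": 20}


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (48, 48, 40)
    spacing: tuple[float, float, float] = (4.07, 4.07, 5.0)
    background_suv: float = 1.0
    noise_sd: float = 0.05
    lesion_center_mm: tuple[float, float, float] | None = None  # grid centre if None
    semi_axes_mm: tuple[float, float, float] = (22.0, 18.0, 16.0)
    peak_suv: float = 12.0
    falloff: str = "gaussian"  # "gaussian" radial profile or "uniform" uptake
    heterogeneity: str = "gaussian_field"  # "none" | "gaussian_field" | "necrotic_core"
    corr_length_mm: float = 8.0
    texture_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_suv <= self.background_suv:
            raise ValueError("lesion peak SUV must exceed background")
        if self.heterogeneity not in ("none", "gaussian_field", "necrotic_core"):
            raise ValueError(f"unknown heterogeneity model {self.heterogeneity!r}")
        if self.falloff not in ("gaussian", "uniform"):
            raise ValueError(f"unknown falloff model {self.falloff!r}")


def make_phantom(spec: PhantomSpec) -> tuple[Volume, VoiMask, dict]:
    """Deterministic tumour phantom; returns volume, true lesion mask, truth record."""
    rng = np.random.default_rng(spec.seed)
    sp = np.asarray(spec.spacing, dtype=float)
    shape = np.asarray(spec.shape)
    if spec.lesion_center_mm is not None:
        center = np.asarray(spec.lesion_center_mm, dtype=float)
    else:
        # snap to the voxel centre nearest the grid midpoint, so the analytic
        # peak is actually sampled and truth records align with the grid
        center = np.round((shape - 1) / 2.0) * sp
    axes_mm = [np.arange(n) * s for n, s in zip(spec.shape, sp)]
    xx, yy, zz = np.meshgrid(*axes_mm, indexing="ij")
    semi = np.asarray(spec.semi_axes_mm, dtype=float)
    lo = center - semi
    hi = center + semi
    extent = (shape - 1) * sp
    if (lo < 0).any() or (hi > extent).any():
        raise ValueError("lesion extends outside the grid")

    rho2 = (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    )
    lesion = rho2 <= 1.0

    if spec.falloff == "uniform":
        profile = np.full_like(rho2, spec.peak_suv)
    else:
        # radial Gaussian falloff in normalized ellipsoid radius; ~exp(-2) at the rim
        sigma_rho = 0.5
        profile = spec.background_suv + (spec.peak_suv - spec.background_suv) * np.exp(
            -rho2 / (2.0 * sigma_rho**2)
        )
    noiseless = np.where(lesion, profile, spec.background_suv)

    img = noiseless + rng.normal(0.0, spec.noise_sd, size=tuple(spec.shape))
    if spec.heterogeneity in ("gaussian_field", "necrotic_core"):
        white = rng.normal(0.0, 1.0, size=tuple(spec.shape))
        field_ = gaussian_filter(white, sigma=spec.corr_length_mm / sp)
        fsd = field_.std()
        if fsd > 0:
            field_ = field_ / fsd * spec.texture_sd
        img = np.where(lesion, img + field_, img)
    if spec.heterogeneity == "necrotic_core":
        core = rho2 <= 0.35**2
        img = np.where(core, 0.3 * img, img)
    img = np.clip(img, 0.0, None)

    threshold = 0.40 * spec.peak_suv
    truth = {
        "spec": spec,
        "lesion_mask": lesion,
        "noiseless": noiseless,
        "threshold_40pct": threshold,
        "superlevel_40pct": noiseless >= threshold,
    }
    vol = Volume(data=img, spacing=tuple(sp), units=SUV)
    return vol, VoiMask(mask=lesion, spacing=tuple(sp)), truth


@dataclass
class CohortSpec:
    n_total: int = 47
    n_deaths: int = 11
    horizon_days: float = 730.0
    prognostic_feature: str = "SUVpeak"
    designed_auc: float = 0.74
    direction: str = "greater"  # deceased have higher values ("greater") or lower
    texture_block_size: int = 13
    texture_auc: float = 0.74  # discrimination of the texture latent (deaths lower)
    n_null_features: int = 10
    block_noise_sd: float = 0.18  # within-block noise; keeps pairwise |rho| > 0.85
    survival_model: str = "fixed_split"  # or "exponential"
    baseline_hazard_per_day: float = 0.35 / 730.0  # exponential-model rate
    beta: float = 0.0  # log hazard ratio on the group indicator (exponential model)
    death_mean_days: float = 400.0  # fixed-split death-time scale before truncation
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_deaths < self.n_total):
            raise ValueError("need 0 < n_deaths < n_total")
        if not (0.5 < self.designed_auc < 1.0):
            raise ValueError("designed AUC must lie in (0.5, 1)")
        if self.survival_model not in ("fixed_split", "exponential"):
            raise ValueError(f"unknown survival model {self.survival_model!r}")


def _auc_shift(auc: float) -> float:
    """Binormal mean shift delta with unit variances giving P(X2 > X1) = auc."""
    return float(np.sqrt(2.0) * stats.norm.ppf(auc))


def _figo_stages(n: int, rng: np.random.Generator) -> np.ndarray:
    counts = np.array(list(FIGO_COUNTS_47.values()), dtype=float)
    stages = list(FIGO_COUNTS_47.keys())
    scaled = counts / counts.sum() * n
    base = np.floor(scaled).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(scaled - base))  # largest remainder first
    for k in range(rem):
        base[order[k % len(base)]] += 1
    out = np.repeat(stages, base)
    rng.shuffle(out)
    return out


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Synthesize feature and clinical tables with feature-linked survival."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_total

    if spec.survival_model == "exponential":
        z = np.zeros(n)  # group assignment emerges from the hazards below
        group_death = None
    else:
        group_death = np.zeros(n, dtype=bool)
        group_death[rng.choice(n, size=spec.n_deaths, replace=False)] = True
        z = group_death.astype(float)

    # --- survival times -------------------------------------------------
    if spec.survival_model == "exponential":
        lam = spec.baseline_hazard_per_day * np.exp(spec.beta * z)
        t_raw = rng.exponential(1.0 / lam)
        event = (t_raw < spec.horizon_days).astype(int)
        time_days = np.minimum(t_raw, spec.horizon_days)
        group_death = event.astype(bool)
    else:
        # designated deaths die before the horizon (truncated exponential);
        # survivors are administratively censored at the horizon
        u = rng.uniform(size=n)
        lam_d = 1.0 / spec.death_mean_days
        p_h = 1.0 - np.exp(-lam_d * spec.horizon_days)
        t_death = -np.log(1.0 - u * p_h) / lam_d
        time_days = np.where(group_death, t_death, spec.horizon_days)
        event = group_death.astype(int)
    time_days = np.maximum(time_days, 1.0)

    # --- features -------------------------------------------------------
    delta = _auc_shift(spec.designed_auc)
    sign = 1.0 if spec.direction == "greater" else -1.0
    latent_suv = rng.normal(0.0, 1.0, n) + sign * delta * z

    feats: dict[str, np.ndarray] = {}
    # prognostic SUV metric on a SUVpeak-like scale, plus a correlated block
    feats[spec.prognostic_feature] = 10.9 + 2.2 * latent_suv
    feats["SUVmax"] = 12.8 + 2.6 * (latent_suv + rng.normal(0, spec.block_noise_sd, n))
    feats["SUVmean"] = 7.7 + 1.5 * (latent_suv + rng.normal(0, spec.block_noise_sd, n))

    # texture latent: deceased have LOWER values (homogeneous low-uptake runs
    # shrink in aggressive lesions); 13 near-duplicate positive-scale features
    delta_tex = _auc_shift(spec.texture_auc)
    latent_tex = rng.normal(0.0, 1.0, n) - delta_tex * z
    texture_names = [
        "GLRLM_LRLGE", "GLRLM_LGRE", "GLRLM_SRLGE", "GLRLM_HGRE", "GLRLM_SRHGE",
        "GLRLM_LRHGE", "GLZLM_SZE", "GLZLM_LGZE", "GLZLM_HGZE", "GLZLM_SZLGE",
        "GLZLM_SZHGE", "GLCM_ContrastVariance", "GLCM_Dissimilarity",
    ][: spec.texture_block_size]
    for k, name in enumerate(texture_names):
        noisy = latent_tex + rng.normal(0, spec.block_noise_sd, n)
        # monotone positive transform to a 1e-3-ish texture scale
        feats[name] = 1.2e-3 * np.exp(0.6 * noisy + 0.02 * k)

    # independent null features (no outcome link)
    null_names = ["MTV", "TLG", "HISTO_Skewness", "HISTO_Kurtosis", "SHAPE_Sphericity",
                  "SHAPE_Compacity", "GLCM_Homogeneity", "GLCM_Energy",
                  "NGLDM_Coarseness", "NGLDM_Busyness"][: spec.n_null_features]
    for k, name in enumerate(null_names):
        feats[name] = rng.normal(30.0 + 5.0 * k, 10.0, n)

    ids = [f"P{k + 1:03d}" for k in range(n)]
    features = pd.DataFrame(feats, index=pd.Index(ids, name="patient_id"))
    clinical = pd.DataFrame(
        {
            "time_days": time_days,
            "event": event,
            "figo_stage": _figo_stages(n, rng),
        },
        index=pd.Index(ids, name="patient_id"),
    )

    truth = {
        "spec": spec,
        "group_death": group_death,
        "prognostic_feature": spec.prognostic_feature,
        "designed_auc": spec.designed_auc,
        "direction": spec.direction,
        "texture_block": texture_names,
        "null_features": null_names,
        "delta": delta,
    }
    return features, clinical, truth
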