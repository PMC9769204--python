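"""Full per-patient feature extraction.

Conventional SUV metrics are computed on the native grid; histogram, shape
and texture features on the 4 mm-resampled, 0.25-SUV-binned grid.  The
result is a named feature vector in a stable order plus a provenance
record (configurations and a hash of the mask).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import pandas as pd

from ..imaging import Volume, VoiMask
from .conventional import conventional_features
from .discretize import DiscretizationConfig, discretize
from .firstorder import histogram_features, shape_features
from .matrices import build_texture_matrices
from .resample import ResampleConfig, resample_isotropic
from .texture_features import (
    glcm_features,
    glrlm_features,
    glzlm_features,
    ngldm_features,
)

#: Stable export order of the full feature registry (52 features).
FEATURE_NAMES: tuple[str, ...] = (
    "SUVmin", "SUVmean", "SUVstd", "SUVmax", "SUVpeak",
    "SUVq1", "SUVmedian", "SUVq3", "MTV", "TLG",
    "SHAPE_VolumeML", "SHAPE_Voxels", "SHAPE_SurfaceMM2",
    "SHAPE_Sphericity", "SHAPE_Compacity",
    "HISTO_Skewness", "HISTO_Kurtosis", "HISTO_Entropy_log2",
    "HISTO_Entropy_log10", "HISTO_Energy",
    "GLCM_Homogeneity", "GLCM_Energy", "GLCM_ContrastVariance",
    "GLCM_Correlation", "GLCM_Entropy_log2", "GLCM_Entropy_log10",
    "GLCM_Dissimilarity",
    "GLRLM_SRE", "GLRLM_LRE", "GLRLM_LGRE", "GLRLM_HGRE",
    "GLRLM_SRLGE", "GLRLM_SRHGE", "GLRLM_LRLGE", "GLRLM_LRHGE",
    "GLRLM_GLNU", "GLRLM_RLNU", "GLRLM_RP",
    "NGLDM_Coarseness", "NGLDM_Contrast", "NGLDM_Busyness",
    "GLZLM_SZE", "GLZLM_LZE", "GLZLM_LGZE", "GLZLM_HGZE",
    "GLZLM_SZLGE", "GLZLM_SZHGE", "GLZLM_LZLGE", "GLZLM_LZHGE",
    "GLZLM_GLNU", "GLZLM_ZLNU", "GLZLM_ZP",
)


@dataclass
class ExtractionResult:
    features: dict[str, float]
    provenance: dict = field(default_factory=dict)


def extract_all(
    vol: Volume,
    voi: VoiMask,
    resample_cfg: ResampleConfig | None = None,
    discretization_cfg: DiscretizationConfig | None = None,
) -> ExtractionResult:
    """Compute the full named feature vector for one patient."""
    resample_cfg = resample_cfg or ResampleConfig()
    discretization_cfg = discretization_cfg or DiscretizationConfig()

    feats: dict[str, float] = {}
    feats.update(conventional_features(vol, voi))

    rvol, rvoi = resample_isotropic(vol, voi, resample_cfg)
    disc = discretize(rvol, rvoi, discretization_cfg)

    feats.update(shape_features(rvoi))
    feats.update(histogram_features(disc))

    mats = build_texture_matrices(disc)
    feats.update(glcm_features(mats))
    feats.update(glrlm_features(mats))
    feats.update(ngldm_features(mats))
    feats.update(glzlm_features(mats))

    ordered = {name: feats[name] for name in FEATURE_NAMES}
    provenance = {
        "resample": asdict(resample_cfg),
        "discretization": asdict(discretization_cfg),
        "mask_sha1": hashlib.sha1(voi.mask.tobytes()).hexdigest(),
        "n_voxels_native": voi.voxel_count,
        "n_voxels_resampled": rvoi.voxel_count,
        "n_grey_levels": disc.n_levels,
    }
    return ExtractionResult(features=ordered, provenance=provenance)


def features_to_frame(per_patient: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Stack per-patient feature dicts into a table (rows = patients)."""
    df = pd.DataFrame.from_dict(per_patient, orient="index")
    df.index.name = "patient_id"
    return df[list(FEATURE_NAMES)]
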