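"""Scalar texture features from the grey-level matrices.

Emphasis-style features share one algebra: with count matrix ``m(i, j)``
(``i`` = grey level, ``j`` = run length or zone size) and ``N = sum(m)``,
a feature is ``sum(m * w(i, j)) / N`` for a weight such as ``1/j^2`` (short
emphasis), ``j^2`` (long emphasis), ``1/i^2`` (low grey level) or products
thereof.  GLZLM features reuse the GLRLM algebra with zones in place of
runs.  Run percentage divides the number of runs by the number of
voxel-run memberships (13 directions x VOI voxels); zone percentage
divides zones by voxels.
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrices


def _emphasis_features(m: np.ndarray, prefix: str, length_label: str) -> dict[str, float]:
    g, r = m.shape
    i = np.arange(1, g + 1, dtype=np.float64)[:, None]
    j = np.arange(1, r + 1, dtype=np.float64)[None, :]
    n = m.sum()
    if n == 0:
        raise ValueError(f"empty {prefix} matrix")

    def agg(w):
        return float((m * w).sum() / n)

    short, long_ = ("SRE", "LRE") if length_label == "run" else ("SZE", "LZE")
    low, high = ("LGRE", "HGRE") if length_label == "run" else ("LGZE", "HGZE")
    sl, sh = ("SRLGE", "SRHGE") if length_label == "run" else ("SZLGE", "SZHGE")
    ll, lh = ("LRLGE", "LRHGE") if length_label == "run" else ("LZLGE", "LZHGE")
    nonu = "RLNU" if length_label == "run" else "ZLNU"
    return {
        f"{prefix}_{short}": agg(1.0 / j**2),
        f"{prefix}_{long_}": agg(j**2),
        f"{prefix}_{low}": agg(1.0 / i**2),
        f"{prefix}_{high}": agg(i**2),
        f"{prefix}_{sl}": agg(1.0 / (i**2 * j**2)),
        f"{prefix}_{sh}": agg(i**2 / j**2),
        f"{prefix}_{ll}": agg(j**2 / i**2),
        f"{prefix}_{lh}": agg(i**2 * j**2),
        f"{prefix}_GLNU": float((m.sum(axis=1) ** 2).sum() / n),
        f"{prefix}_{nonu}": float((m.sum(axis=0) ** 2).sum() / n),
    }


def glrlm_features(m: TextureMatrices) -> dict[str, float]:
    out = _emphasis_features(m.glrlm, "GLRLM", "run")
    out["GLRLM_RP"] = float(m.glrlm.sum() / (13.0 * m.n_voxels))
    return out


def glzlm_features(m: TextureMatrices) -> dict[str, float]:
    out = _emphasis_features(m.glzlm, "GLZLM", "zone")
    out["GLZLM_ZP"] = float(m.glzlm.sum() / m.n_voxels)
    return out


def glcm_features(m: TextureMatrices) -> dict[str, float]:
    p = m.glcm_p
    g = p.shape[0]
    i = np.arange(1, g + 1, dtype=np.float64)[:, None]
    j = np.arange(1, g + 1, dtype=np.float64)[None, :]
    diff = np.abs(i - j)
    px = p.sum(axis=1)
    lv = np.arange(1, g + 1, dtype=np.float64)
    mu = float((lv * px).sum())
    var = float(((lv - mu) ** 2 * px).sum())
    if var > 0:
        corr = float(((i - mu) * (j - mu) * p).sum() / var)
    else:
        # single grey level: correlation undefined, 0 by convention
        corr = 0.0
    nz = p[p > 0]
    return {
        "GLCM_Homogeneity": float((p / (1.0 + diff)).sum()),
        "GLCM_Energy": float((p**2).sum()),
        "GLCM_ContrastVariance": float((p * (i - j) ** 2).sum()),
        "GLCM_Correlation": corr,
        "GLCM_Entropy_log2": float(-(nz * np.log2(nz)).sum()),
        "GLCM_Entropy_log10": float(-(nz * np.log10(nz)).sum()),
        "GLCM_Dissimilarity": float((p * diff).sum()),
    }


def ngldm_features(m: TextureMatrices) -> dict[str, float]:
    """Coarseness, contrast and busyness from the neighbourhood-difference summary.

    With level probabilities ``p_i = n_i / N`` and per-level difference sums
    ``s_i`` (sum over voxels of level ``i`` of |i - mean 26-neighbour level|):
    coarseness = 1 / sum(p_i s_i); contrast =
    [sum_{i,j} p_i p_j (i-j)^2 / (Np (Np-1))] * [sum s_i / N] over the Np
    levels present; busyness = sum(p_i s_i) / sum_{i,j} |i p_i - j p_j|.
    Degenerate single-level VOIs give contrast and busyness 0 and a capped
    coarseness.
    """
    n_i = m.ngtdm_n
    s_i = m.ngtdm_s
    n_total = n_i.sum()
    p_i = n_i / n_total
    present = p_i > 0
    n_p = int(present.sum())
    lv = np.arange(1, len(p_i) + 1, dtype=np.float64)

    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if n_p > 1:
        pi = p_i[present][:, None]
        pj = p_i[present][None, :]
        li = lv[present][:, None]
        lj = lv[present][None, :]
        contrast = float(
            (pi * pj * (li - lj) ** 2).sum()
            / (n_p * (n_p - 1))
            * (s_i.sum() / n_total)
        )
        denom = float(np.abs(li * pi - lj * pj).sum())
        busyness = ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    return {
        "NGLDM_Coarseness": coarseness,
        "NGLDM_Contrast": contrast,
        "NGLDM_Busyness": busyness,
    }
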