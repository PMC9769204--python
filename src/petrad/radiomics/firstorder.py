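"""First-order histogram features and voxel-based shape features.

Histogram features are computed on the discretized grey levels of the VOI
(skewness and excess kurtosis of the level distribution, Shannon entropy of
the level probabilities in bits and in decimal logs, and energy = sum of
squared probabilities).  Shape features use the voxelized mask: surface
area by face counting (every exposed voxel face contributes its physical
area), sphericity = (36 pi V^2)^(1/3) / A, and compacity = V / (sqrt(pi) *
A^(3/2)) with V in mm^3 and A in mm^2.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from ..imaging import VoiMask
from .discretize import DiscretizedVOI

log = logging.getLogger(__name__)


def histogram_features(d: DiscretizedVOI) -> dict[str, float]:
    vals = d.voi_levels.astype(float)
    if vals.size == 0:
        raise ValueError("empty VOI")
    _, counts = np.unique(vals, return_counts=True)
    p = counts / counts.sum()
    if vals.size < 2 or np.ptp(vals) == 0:
        # zero-variance VOI: moments undefined, reported as 0 by convention
        log.info("degenerate histogram (single grey level): skewness/kurtosis set to 0")
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(vals, bias=True))
        kurt = float(stats.kurtosis(vals, fisher=True, bias=True))
    return {
        "HISTO_Skewness": skew,
        "HISTO_Kurtosis": kurt,
        "HISTO_Entropy_log2": float(-(p * np.log2(p)).sum()),
        "HISTO_Entropy_log10": float(-(p * np.log10(p)).sum()),
        "HISTO_Energy": float((p**2).sum()),
    }


def surface_area_mm2(voi: VoiMask) -> float:
    """Surface area of the voxelized mask by face counting."""
    m = voi.mask
    sx, sy, sz = voi.spacing
    face_area = (sy * sz, sx * sz, sx * sy)
    total = 0.0
    for ax, area in enumerate(face_area):
        diff = np.diff(m.astype(np.int8), axis=ax) != 0
        boundary = int(diff.sum())
        # faces on the grid border are exposed too
        first = np.take(m, 0, axis=ax).sum()
        last = np.take(m, -1, axis=ax).sum()
        total += (boundary + int(first) + int(last)) * area
    return float(total)


def shape_features(voi: VoiMask) -> dict[str, float]:
    if not voi.mask.any():
        raise ValueError("empty VOI")
    n = voi.voxel_count
    sx, sy, sz = voi.spacing
    v_mm3 = n * sx * sy * sz
    a_mm2 = surface_area_mm2(voi)
    sphericity = (36.0 * np.pi * v_mm3**2) ** (1.0 / 3.0) / a_mm2
    compacity = v_mm3 / (np.sqrt(np.pi) * a_mm2**1.5)
    return {
        "SHAPE_VolumeML": voi.volume_ml,
        "SHAPE_Voxels": float(n),
        "SHAPE_SurfaceMM2": a_mm2,
        "SHAPE_Sphericity": float(sphericity),
        "SHAPE_Compacity": float(compacity),
    }
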