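"""Conventional SUV metrics: SUVmax/mean/peak/quartiles, MTV and TLG.

These are computed on the native (pre-resampling) grid.  SUVpeak is the
maximum, over spheres of 1 mL (radius 6.2035 mm) centred at each VOI voxel,
of the mean SUV of the voxels whose centres fall inside the sphere; spheres
may extend beyond the VOI but are clipped at the image border (clipping is
logged).  MTV is the VOI volume in mL and TLG = SUVmean x MTV.
"""

from __future__ import annotations

import logging

import numpy as np

from .. import imaging
from ..imaging import Volume, VoiMask

log = logging.getLogger(__name__)

#: Radius of a 1 mL sphere, mm: (3/(4 pi))^(1/3) * 10.
PEAK_SPHERE_RADIUS_MM = 6.2035


def _sphere_offsets(spacing: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    """Integer voxel offsets whose centres lie within ``radius_mm`` of the origin."""
    sp = np.asarray(spacing, dtype=float)
    reach = np.floor(radius_mm / sp).astype(int)
    ax = [np.arange(-r, r + 1) for r in reach]
    grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    dist2 = ((grid * sp) ** 2).sum(axis=1)
    return grid[dist2 <= radius_mm**2]


def suv_peak(vol: Volume, voi: VoiMask, radius_mm: float = PEAK_SPHERE_RADIUS_MM) -> float:
    """Maximum 1 mL-sphere mean SUV over sphere centres at VOI voxels."""
    offsets = _sphere_offsets(vol.spacing, radius_mm)
    shape = vol.shape
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.int64)
    clipped = False
    for off in offsets:
        src = []
        dst = []
        inside = True
        for ax in range(3):
            o = int(off[ax])
            n = shape[ax]
            if o >= n or -o >= n:
                inside = False
                break
            # dst[i] accumulates data[i + o]
            if o >= 0:
                dst.append(slice(0, n - o))
                src.append(slice(o, n))
            else:
                dst.append(slice(-o, n))
                src.append(slice(0, n + o))
        if not inside:
            clipped = True
            continue
        if any(s.stop - s.start < shape[k] for k, s in enumerate(dst)):
            clipped = True
        acc[tuple(dst)] += vol.data[tuple(src)]
        cnt[tuple(dst)] += 1
    if clipped and (cnt[voi.mask] < len(offsets)).any():
        log.info("SUVpeak sphere clipped at the image border for some VOI voxels")
    means = acc[voi.mask] / cnt[voi.mask]
    return float(means.max())


def conventional_features(vol: Volume, voi: VoiMask) -> dict[str, float]:
    """SUV statistics, MTV (mL) and TLG (= SUVmean x MTV) over the VOI."""
    if vol.units != imaging.SUV:
        raise ValueError("conventional features require SUV units")
    if voi.mask.shape != vol.shape:
        raise ValueError("mask and volume grids differ")
    if not voi.mask.any():
        raise ValueError("empty VOI")
    vals = vol.data[voi.mask]
    mtv = voi.volume_ml
    suv_mean = float(vals.mean())
    q1, q2, q3 = np.percentile(vals, [25, 50, 75])
    return {
        "SUVmin": float(vals.min()),
        "SUVmean": suv_mean,
        "SUVstd": float(vals.std()),
        "SUVmax": float(vals.max()),
        "SUVpeak": suv_peak(vol, voi),
        "SUVq1": float(q1),
        "SUVmedian": float(q2),
        "SUVq3": float(q3),
        "MTV": float(mtv),
        "TLG": suv_mean * float(mtv),
    }
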