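"""Isotropic resampling of volume and mask onto a common texture grid.

Texture features are computed on a 4 mm isotropic grid (resampled from the
native, typically 4.07 x 4.07 x 5.0 mm, reconstruction grid); intensities
are interpolated trilinearly and the mask with nearest-neighbour, then
re-binarized.  The resampled grid shares the native origin: voxel ``i`` of
the new grid sits at physical position ``origin + i * target_spacing``, so
a volume already on the target grid passes through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .. import imaging
from ..imaging import Volume, VoiMask


@dataclass
class ResampleConfig:
    target_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self) -> None:
        self.target_spacing = tuple(float(s) for s in self.target_spacing)
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError(f"target spacing must be positive, got {self.target_spacing}")


def resample_isotropic(
    vol: Volume, voi: VoiMask, cfg: ResampleConfig | None = None
) -> tuple[Volume, VoiMask]:
    """Regrid volume (trilinear) and mask (nearest-neighbour) to ``target_spacing``."""
    if vol.units != imaging.SUV:
        raise ValueError("resampling for feature extraction requires SUV units")
    if not voi.mask.any():
        raise ValueError("empty VOI")
    if voi.mask.shape != vol.shape:
        raise ValueError("mask and volume grids differ")
    cfg = cfg or ResampleConfig()

    old_sp = np.asarray(vol.spacing, dtype=float)
    new_sp = np.asarray(cfg.target_spacing, dtype=float)
    old_shape = np.asarray(vol.shape)
    new_shape = np.maximum(1, np.ceil(old_shape * old_sp / new_sp).astype(int))

    # new voxel i maps to fractional old index i * new_sp / old_sp per axis
    axes = [np.arange(n) * new_sp[k] / old_sp[k] for k, n in enumerate(new_shape)]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"))

    new_data = map_coordinates(vol.data, coords, order=1, mode="nearest")
    new_mask = map_coordinates(voi.mask.astype(np.uint8), coords, order=0, mode="nearest") > 0

    if not new_mask.any():
        raise ValueError("VOI lost in resampling")

    spacing = tuple(new_sp)
    return (
        Volume(data=new_data, spacing=spacing, origin=vol.origin, units=imaging.SUV),
        VoiMask(mask=new_mask, spacing=spacing, origin=vol.origin),
    )
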