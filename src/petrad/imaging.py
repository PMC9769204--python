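"""PET volume I/O and SUV conversion.

Volumes are 3-D scalar grids with voxel spacing in millimetres; axis order
is (x, y, z) with voxel (0, 0, 0) centred at the header origin, and the
physical position of voxel ``(i, j, k)`` is ``origin + index * spacing``.
Masks live on exactly the same grid as their companion volume — no
resampling happens at I/O time.

Voxel values are either body-weight standardized uptake values (SUV,
dimensionless) or activity concentration in Bq/mL; the ``units`` tag records
which, and every downstream feature computation requires SUV.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

SUV = "SUV"
BQ_PER_ML = "BqPerML"

#: Physical half-life of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.77


@dataclass
class Volume:
    """A 3-D scalar image with spacing (mm), origin (mm) and a units tag."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = SUV

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D payload")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive on all axes, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if np.isnan(self.data).any():
            raise ValueError("volume contains NaN voxels")
        if self.units not in (SUV, BQ_PER_ML):
            raise ValueError(f"unknown units tag {self.units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (spacing product / 1000)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0


@dataclass
class VoiMask:
    """A boolean tumour mask congruent with a :class:`Volume` grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"expected 3-D mask, got {self.mask.ndim}-D payload")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return self.voxel_count * sx * sy * sz / 1000.0


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | os.PathLike, units: str = SUV) -> Volume:
    """Read a NIfTI-1 file into a :class:`Volume`.

    Spacing is taken from the header ``pixdim``, the origin from the affine
    translation.  The payload must be a 3-D scalar grid with no NaNs.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {img.ndim}-D payload in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive pixdim in NIfTI header of {path}: {zooms}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    origin = tuple(float(x) for x in np.asarray(img.affine)[:3, 3])
    return Volume(data=data, spacing=tuple(float(z) for z in zooms), origin=origin, units=units)


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    """Write a :class:`Volume` as NIfTI-1; round-trips bit-exactly."""
    if os.path.exists(path):
        log.info("overwriting existing file %s", path)
    img = nib.Nifti1Image(vol.data, _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> VoiMask:
    """Read a binary NIfTI mask; any non-zero voxel is inside the VOI."""
    vol = read_volume(path, units=SUV)
    return VoiMask(mask=vol.data > 0, spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: VoiMask, path: str | os.PathLike) -> None:
    if os.path.exists(path):
        log.info("overwriting existing file %s", path)
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def to_suv(
    vol: Volume,
    injected_activity_mbq: float,
    body_weight_kg: float,
    decay_minutes: float | None = None,
) -> Volume:
    """Convert an activity-concentration volume (Bq/mL) to body-weight SUV.

    SUV = concentration / (injected dose per gram of body weight), with
    tissue density taken as 1 g/mL, i.e. each voxel ``v`` becomes
    ``v / (A_inj * 1e6 / (w * 1e3))`` for dose ``A_inj`` in MBq and weight
    ``w`` in kg.  The injected dose is assumed already decay-corrected to
    scan start; pass ``decay_minutes`` to decay it explicitly with the
    fluorine-18 half-life (off by default).
    """
    if vol.units == SUV:
        raise ValueError("volume is already in SUV")
    if injected_activity_mbq <= 0:
        raise ValueError("injected activity must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    dose_bq = injected_activity_mbq * 1e6
    if decay_minutes is not None:
        dose_bq *= 2.0 ** (-decay_minutes / F18_HALF_LIFE_MIN)
    dose_per_gram = dose_bq / (body_weight_kg * 1e3)
    return Volume(
        data=vol.data / dose_per_gram,
        spacing=vol.spacing,
        origin=vol.origin,
        units=SUV,
    )
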