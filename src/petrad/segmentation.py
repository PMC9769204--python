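"""Semi-automatic lesion delineation by a fixed fraction of SUVmax.

The operator supplies a coarse region around the cervical lesion (a voxel
box or a precursor mask, standing in for a manual 3-D outline); the tumour
VOI is then the set of voxels inside that region whose SUV reaches a fixed
fraction (default 40%) of the region's maximum SUV, restricted to the
single 26-connected component that contains the hottest voxel.  Keeping
only that component discards satellite nodal uptake accidentally caught in
the seed box.  The threshold comparison is inclusive (``>=``) so a
degenerate single-voxel lesion keeps its own maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import SUV, Volume, VoiMask

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SeedRegion:
    """Inclusive voxel-index bounds of an axis-aligned seed box."""

    lower_corner: tuple[int, int, int]
    upper_corner: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lower_corner)
        hi = tuple(int(v) for v in self.upper_corner)
        if any(l > u for l, u in zip(lo, hi)):
            raise ValueError(f"seed box lower corner {lo} exceeds upper corner {hi}")
        self.lower_corner, self.upper_corner = lo, hi

    def to_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Rasterize the box onto a grid, clipped to the grid bounds."""
        lo = [max(0, l) for l in self.lower_corner]
        hi = [min(s - 1, u) for s, u in zip(shape, self.upper_corner)]
        if any(l > u for l, u in zip(lo, hi)):
            raise ValueError("seed box does not intersect the volume grid")
        m = np.zeros(shape, dtype=bool)
        m[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
        return m


@dataclass
class SegmentationResult:
    voi: VoiMask
    suv_max_in_seed: float
    threshold_suv: float
    fraction: float


def segment_fixed_threshold(
    vol: Volume,
    seed: SeedRegion | VoiMask | np.ndarray,
    fraction: float = 0.40,
) -> SegmentationResult:
    """Threshold the seed region at ``fraction`` x SUVmax and keep the hot component.

    The threshold is ``fraction * max(SUV within seed)``; the VOI is the
    26-connected component of ``{voxel in seed : SUV >= threshold}`` that
    contains the maximum voxel (ties broken toward the lowest linear index).
    """
    if vol.units != SUV:
        raise ValueError("segmentation requires a volume in SUV units")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")

    if isinstance(seed, SeedRegion):
        seed_mask = seed.to_mask(vol.shape)
    elif isinstance(seed, VoiMask):
        seed_mask = seed.mask
    else:
        seed_mask = np.asarray(seed).astype(bool)
    if seed_mask.shape != vol.shape:
        raise ValueError(f"seed mask shape {seed_mask.shape} != volume shape {vol.shape}")
    if not seed_mask.any():
        raise ValueError("empty seed region")

    masked = np.where(seed_mask, vol.data, -np.inf)
    suv_max = float(masked.max())
    if suv_max <= 0:
        raise ValueError("no uptake in seed")
    # argmax on the flattened array returns the lowest linear index on ties
    hot_idx = np.unravel_index(int(np.argmax(masked)), vol.shape)

    threshold = fraction * suv_max
    candidate = seed_mask & (vol.data >= threshold)
    labels, _ = ndimage.label(candidate, structure=_CONN26)
    voi = labels == labels[hot_idx]

    return SegmentationResult(
        voi=VoiMask(mask=voi, spacing=vol.spacing, origin=vol.origin),
        suv_max_in_seed=suv_max,
        threshold_suv=threshold,
        fraction=float(fraction),
    )
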