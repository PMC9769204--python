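"""Fixed-bin-width intensity discretization (absolute SUV bins).

Grey level of a voxel with uptake ``v`` is ``floor((v - lower) / width) + 1``
with a default bin width of 0.25 SUV and lower bound 0 — absolute bins
anchored at SUV 0, so levels are comparable across patients.  A bin-count
scheme (fixed number of bins over the VOI range) is deliberately not the
default; see the package docs for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import imaging
from ..imaging import Volume, VoiMask


@dataclass
class DiscretizationConfig:
    bin_width: float = 0.25
    lower_bound: float = 0.0
    max_levels: int | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if self.lower_bound < 0:
            raise ValueError("lower bound must be >= 0")


@dataclass
class DiscretizedVOI:
    """Integer grey levels over the VOI (0 outside), plus binning metadata."""

    levels: np.ndarray  # int grid, 1..G inside the VOI, 0 outside
    mask: np.ndarray  # bool grid
    n_levels: int  # G: highest level present (or the configured cap)
    spacing: tuple[float, float, float]
    config: DiscretizationConfig

    @property
    def voi_levels(self) -> np.ndarray:
        """Flat array of grey levels of the VOI voxels."""
        return self.levels[self.mask]


def discretize(
    vol: Volume, voi: VoiMask, cfg: DiscretizationConfig | None = None
) -> DiscretizedVOI:
    """Recode VOI voxel SUVs into integer grey levels 1..G."""
    if vol.units != imaging.SUV:
        raise ValueError("discretization requires SUV units")
    if voi.mask.shape != vol.shape:
        raise ValueError("mask and volume grids differ")
    if not voi.mask.any():
        raise ValueError("empty VOI")
    cfg = cfg or DiscretizationConfig()

    vals = vol.data[voi.mask]
    if (vals < cfg.lower_bound).any():
        raise ValueError(
            f"VOI voxel below discretization lower bound {cfg.lower_bound}"
        )
    lv = np.floor((vals - cfg.lower_bound) / cfg.bin_width).astype(np.int64) + 1
    if cfg.max_levels is not None:
        lv = np.minimum(lv, cfg.max_levels)
    levels = np.zeros(vol.shape, dtype=np.int64)
    levels[voi.mask] = lv
    n_levels = int(cfg.max_levels) if cfg.max_levels is not None else int(lv.max())
    return DiscretizedVOI(
        levels=levels,
        mask=voi.mask.copy(),
        n_levels=n_levels,
        spacing=vol.spacing,
        config=cfg,
    )
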