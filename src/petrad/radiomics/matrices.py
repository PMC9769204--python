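"""Grey-level texture matrices on the discretized VOI.

Four matrix families are built from the integer grey-level grid, treating
voxels outside the VOI as absent (they never pair, never extend runs and
never join zones):

* GLCM  — co-occurrence counts of level pairs at the 13 unique 3-D offsets
  of the 26-neighbourhood at Chebyshev distance 1, symmetrized and merged
  into a single matrix, then normalized to probabilities.
* GLRLM — maximal runs of equal level along each of the 13 directions,
  merged into one (level x run-length) count matrix.
* NGLDM — for each VOI voxel, the number of its 26-neighbours inside the
  VOI with exactly the same level (tolerance 0): a (level x 0..26
  dependence-count) matrix.
* GLZLM — 26-connected iso-level zones, counted by (level, zone size).

An auxiliary neighbourhood-difference summary (per-level sums of
|level - mean neighbour level|) is kept alongside the NGLDM; the
coarseness / contrast / busyness features are computed from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedVOI

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: The 13 unique direction offsets of the 3-D 26-neighbourhood (one per +/- pair),
#: closed under the octahedral group once both signs are restored.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: All 26 neighbour offsets.
OFFSETS_26: tuple[tuple[int, int, int], ...] = DIRECTIONS_13 + tuple(
    (-a, -b, -c) for a, b, c in DIRECTIONS_13
)


@dataclass
class TextureMatrices:
    glcm_counts: np.ndarray  # G x G symmetric pair counts (merged over 13 offsets)
    glcm_p: np.ndarray  # normalized to probabilities
    glrlm: np.ndarray  # G x R run counts (merged over 13 directions)
    ngldm: np.ndarray  # G x 27 dependence counts
    ngtdm_s: np.ndarray  # per-level sum of |level - mean 26-neighbour level|
    ngtdm_n: np.ndarray  # per-level voxel counts
    glzlm: np.ndarray  # G x Z zone counts (26-connected)
    n_voxels: int
    n_levels: int


def _pair_slices(shape, off):
    """Slices (s1, s2) such that grid[s1] pairs element-wise with grid[s2] at +off."""
    s1, s2 = [], []
    for ax in range(3):
        o, n = int(off[ax]), shape[ax]
        if abs(o) >= n:
            return None
        if o >= 0:
            s1.append(slice(0, n - o))
            s2.append(slice(o, n))
        else:
            s1.append(slice(-o, n))
            s2.append(slice(0, n + o))
    return tuple(s1), tuple(s2)


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    for off in DIRECTIONS_13:
        sl = _pair_slices(levels.shape, off)
        if sl is None:
            continue
        s1, s2 = sl
        both = mask[s1] & mask[s2]
        i = levels[s1][both] - 1
        j = levels[s2][both] - 1
        np.add.at(counts, (i, j), 1.0)
        np.add.at(counts, (j, i), 1.0)
    total = counts.sum()
    p = counts / total if total > 0 else counts.copy()
    return counts, p


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    shape = levels.shape
    runs: list[tuple[int, int]] = []  # (level, length)
    max_len = 1
    for off in DIRECTIONS_13:
        starts = mask.copy()
        sl = _pair_slices(shape, off)
        if sl is not None:
            s_prev, s_here = sl
            # a voxel continues a run if its predecessor (at -off) is in the
            # VOI with the same level; such voxels do not start runs
            cont = mask[s_prev] & mask[s_here] & (levels[s_prev] == levels[s_here])
            starts[s_here] &= ~cont
        d = np.asarray(off)
        for idx in np.argwhere(starts):
            g = levels[tuple(idx)]
            length = 1
            pos = idx + d
            while (
                (pos >= 0).all()
                and (pos < shape).all()
                and mask[tuple(pos)]
                and levels[tuple(pos)] == g
            ):
                length += 1
                pos = pos + d
            runs.append((int(g), length))
            max_len = max(max_len, length)
    glrlm = np.zeros((n_levels, max_len), dtype=np.float64)
    for g, length in runs:
        glrlm[g - 1, length - 1] += 1.0
    return glrlm


def ngldm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        sl = _pair_slices(levels.shape, off)
        if sl is None:
            continue
        s1, s2 = sl
        eq = mask[s1] & mask[s2] & (levels[s1] == levels[s2])
        dep[s1] += eq
    out = np.zeros((n_levels, 27), dtype=np.float64)
    np.add.at(out, (levels[mask] - 1, dep[mask]), 1.0)
    return out


def ngtdm_components(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level sums s_i of |i - mean in-VOI 26-neighbour level| and counts n_i."""
    lv = np.where(mask, levels, 0).astype(np.float64)
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        sl = _pair_slices(levels.shape, off)
        if sl is None:
            continue
        s1, s2 = sl
        nb_sum[s1] += lv[s2] * mask[s2]
        nb_cnt[s1] += mask[s2]
    s = np.zeros(n_levels, dtype=np.float64)
    n = np.zeros(n_levels, dtype=np.float64)
    idx = levels[mask] - 1
    has_nb = nb_cnt[mask] > 0
    diff = np.zeros(idx.shape, dtype=np.float64)
    diff[has_nb] = np.abs(
        levels[mask][has_nb] - nb_sum[mask][has_nb] / nb_cnt[mask][has_nb]
    )
    np.add.at(s, idx, diff)
    np.add.at(n, idx, 1.0)
    return s, n


def glzlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    zones: list[tuple[int, int]] = []
    max_size = 1
    for g in np.unique(levels[mask]):
        lab, nz = ndimage.label(levels == g, structure=_CONN26)
        if nz == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            zones.append((int(g), int(sz)))
            max_size = max(max_size, int(sz))
    out = np.zeros((n_levels, max_size), dtype=np.float64)
    for g, sz in zones:
        out[g - 1, sz - 1] += 1.0
    return out


def build_texture_matrices(d: DiscretizedVOI) -> TextureMatrices:
    levels, mask, g = d.levels, d.mask, d.n_levels
    if not mask.any():
        raise ValueError("empty VOI")
    counts, p = glcm_matrix(levels, mask, g)
    s, n = ngtdm_components(levels, mask, g)
    return TextureMatrices(
        glcm_counts=counts,
        glcm_p=p,
        glrlm=glrlm_matrix(levels, mask, g),
        ngldm=ngldm_matrix(levels, mask, g),
        ngtdm_s=s,
        ngtdm_n=n,
        glzlm=glzlm_matrix(levels, mask, g),
        n_voxels=int(mask.sum()),
        n_levels=g,
    )
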