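"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plainly as possible (triple loops, flood
fills, exhaustive enumeration) and deliberately shares no code with the
package internals.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

# all 26 neighbour offsets, written out independently of the package
ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
# one representative per +/- pair
HALF_13 = [o for o in ALL_26 if o > (0, 0, 0)]


def _in_grid(p, shape):
    return all(0 <= p[k] < shape[k] for k in range(3))


def brute_glcm(levels, mask, n_levels):
    """Symmetrized merged co-occurrence counts at Chebyshev distance 1."""
    counts = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for p in np.ndindex(shape):
        if not mask[p]:
            continue
        for off in ALL_26:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if _in_grid(q, shape) and mask[q]:
                counts[levels[p] - 1, levels[q] - 1] += 1
    return counts


def brute_glrlm(levels, mask, n_levels):
    """Maximal equal-level runs along 13 directions, merged."""
    shape = levels.shape
    runs = []
    for d in HALF_13:
        for p in np.ndindex(shape):
            if not mask[p]:
                continue
            prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
            if _in_grid(prev, shape) and mask[prev] and levels[prev] == levels[p]:
                continue  # not a run start
            g = levels[p]
            length = 0
            q = p
            while _in_grid(q, shape) and mask[q] and levels[q] == g:
                length += 1
                q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
            runs.append((g, length))
    r_max = max(length for _, length in runs)
    out = np.zeros((n_levels, r_max))
    for g, length in runs:
        out[g - 1, length - 1] += 1
    return out


def brute_ngldm(levels, mask, n_levels):
    """Counts of voxels by (level, number of equal-level 26-neighbours in VOI)."""
    shape = levels.shape
    out = np.zeros((n_levels, 27))
    for p in np.ndindex(shape):
        if not mask[p]:
            continue
        dep = 0
        for off in ALL_26:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if _in_grid(q, shape) and mask[q] and levels[q] == levels[p]:
                dep += 1
        out[levels[p] - 1, dep] += 1
    return out


def brute_glzlm(levels, mask, n_levels):
    """26-connected iso-level zones by flood fill, counted by (level, size)."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in np.ndindex(shape):
        if not mask[p] or seen[p]:
            continue
        g = levels[p]
        stack = [p]
        seen[p] = True
        size = 0
        while stack:
            q = stack.pop()
            size += 1
            for off in ALL_26:
                r = (q[0] + off[0], q[1] + off[1], q[2] + off[2])
                if _in_grid(r, shape) and mask[r] and not seen[r] and levels[r] == g:
                    seen[r] = True
                    stack.append(r)
        zones.append((g, size))
    s_max = max(s for _, s in zones)
    out = np.zeros((n_levels, s_max))
    for g, s in zones:
        out[g - 1, s - 1] += 1
    return out


def brute_suv_peak(data, mask, spacing, radius_mm):
    """Exhaustive sphere-centre scan: mean over voxel centres within radius."""
    shape = data.shape
    sp = np.asarray(spacing, float)
    reach = [int(np.floor(radius_mm / s)) for s in sp]
    best = -np.inf
    for p in np.argwhere(mask):
        vals = []
        for dx in range(-reach[0], reach[0] + 1):
            for dy in range(-reach[1], reach[1] + 1):
                for dz in range(-reach[2], reach[2] + 1):
                    q = (p[0] + dx, p[1] + dy, p[2] + dz)
                    if not _in_grid(q, shape):
                        continue
                    dist2 = (dx * sp[0]) ** 2 + (dy * sp[1]) ** 2 + (dz * sp[2]) ** 2
                    if dist2 <= radius_mm**2:
                        vals.append(data[q])
        best = max(best, float(np.mean(vals)))
    return best


def pairwise_auc(neg, pos):
    """AUC by exhaustive pair counting: wins + half ties over all pairs."""
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def jackknife_auc_variance(neg, pos):
    """Grouped delete-one jackknife variance of the AUC.

    Algebraically identical to DeLong's structural-component estimator, but
    computed by literally recomputing the AUC with each observation removed.
    """
    neg = list(neg)
    pos = list(pos)
    m, n = len(pos), len(neg)
    auc_minus_pos = [pairwise_auc(neg, pos[:i] + pos[i + 1 :]) for i in range(m)]
    auc_minus_neg = [pairwise_auc(neg[:j] + neg[j + 1 :], pos) for j in range(n)]
    vp = (m - 1) / m * np.sum((np.array(auc_minus_pos) - np.mean(auc_minus_pos)) ** 2)
    vn = (n - 1) / n * np.sum((np.array(auc_minus_neg) - np.mean(auc_minus_neg)) ** 2)
    return vp + vn


def exact_mw_pvalue(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(pooled)
    m = len(y)

    def u_stat(y_vals, x_vals):
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0 for a in y_vals for b in x_vals
        )

    u_obs = u_stat(y, x)
    center = len(x) * len(y) / 2.0
    dev = abs(u_obs - center)
    total = extreme = 0
    for idx in combinations(range(n), m):
        yy = [pooled[i] for i in idx]
        xx = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if abs(u_stat(yy, xx) - center) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def hand_km(times, events):
    """Product-limit estimator computed with an explicit loop."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = []
    s = 1.0
    for t in np.unique(times[events == 1]):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= (n_at_risk - d) / n_at_risk
        out.append((float(t), float(s)))
    return out
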