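"""Brute-force reference implementations used only to check the fast paths.

Everything here is written for clarity, not speed: explicit loops over voxel
pairs, breadth-first flood fills and full line scans. These stay independent
of the implementations in tnbcpet.features / tnbcpet.segmentation.
"""

from collections import deque

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

HALF_DIRECTIONS_13 = [d for d in NEIGHBORS_26 if d > (0, 0, 0)]


def bfs_components(mask):
    """26-connected components of a binary mask as a set of frozensets."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        comp = {start}
        while queue:
            v = queue.popleft()
            for d in NEIGHBORS_26:
                w = tuple(np.add(v, d))
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    comp.add(w)
                    queue.append(w)
        comps.append(frozenset(comp))
    return set(comps)


def glcm_bruteforce(labels, levels):
    """Pair-enumeration GLCM: every voxel pair at each of the 13 offsets, both
    orders, normalized."""
    labels = np.asarray(labels)
    counts = np.zeros((levels, levels), dtype=float)
    for v in map(tuple, np.argwhere(labels > 0)):
        for d in HALF_DIRECTIONS_13:
            w = tuple(np.add(v, d))
            if all(0 <= w[i] < labels.shape[i] for i in range(3)) and labels[w] > 0:
                a, b = labels[v] - 1, labels[w] - 1
                counts[a, b] += 1
                counts[b, a] += 1
    return counts / counts.sum()


def glrlm_bruteforce(labels, levels):
    """Line-scan GLRLM: walk every full grid line of every direction, split
    into maximal equal-level runs (level 0 breaks runs)."""
    labels = np.asarray(labels)
    runs = []
    for d in HALF_DIRECTIONS_13:
        d = np.asarray(d)
        for start in map(tuple, np.argwhere(np.ones(labels.shape, dtype=bool))):
            prev = tuple(np.asarray(start) - d)
            if all(0 <= prev[i] < labels.shape[i] for i in range(3)):
                continue  # not the head of a line
            line = []
            v = np.asarray(start)
            while all(0 <= v[i] < labels.shape[i] for i in range(3)):
                line.append(labels[tuple(v)])
                v = v + d
            run_level, run_len = 0, 0
            for lab in line + [0]:
                if lab == run_level and lab > 0:
                    run_len += 1
                else:
                    if run_level > 0:
                        runs.append((run_level, run_len))
                    run_level, run_len = lab, 1
    rmax = max(r[1] for r in runs)
    mat = np.zeros((levels, rmax), dtype=int)
    for lev, length in runs:
        mat[lev - 1, length - 1] += 1
    return mat


def glszm_bruteforce(labels, levels):
    """Flood-fill GLSZM: 26-connected equal-level zones per level."""
    labels = np.asarray(labels)
    zones = []
    for g in range(1, levels + 1):
        for comp in bfs_components(labels == g):
            zones.append((g, len(comp)))
    zmax = max(z[1] for z in zones)
    mat = np.zeros((levels, zmax), dtype=int)
    for lev, size in zones:
        mat[lev - 1, size - 1] += 1
    return mat


def peak_sphere_mean(grid, spacing, center, radius_mm=6.2035):
    """Exhaustive voxel-center sphere membership over the whole grid."""
    grid = np.asarray(grid, dtype=float)
    total, count = 0.0, 0
    for v in np.ndindex(grid.shape):
        d2 = sum(((v[i] - center[i]) * spacing[i]) ** 2 for i in range(3))
        if d2 <= radius_mm**2:
            total += grid[v]
            count += 1
    return total / count, count
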