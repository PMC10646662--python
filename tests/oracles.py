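"""Independent brute-force oracles used by the test suite.

Every function here is written as plain nested loops over voxels, pairs,
runs and zones -- deliberately naive and structurally unrelated to the
vectorised implementations in ``petrep.features`` / ``petrep.repstats``.
"""

from __future__ import annotations

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
DIRS_13 = [o for o in OFFSETS_26 if o > (0, 0, 0)]


def _in_bounds(p, shape):
    return all(0 <= p[a] < shape[a] for a in range(3))


def glcm_bruteforce(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Count every ordered in-mask voxel pair at distance 1 (26-nbhd)."""
    P = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                for off in OFFSETS_26:
                    q = (x + off[0], y + off[1], z + off[2])
                    if _in_bounds(q, shape) and levels[q] > 0:
                        P[g - 1, levels[q] - 1] += 1
    return P


def gldm_bruteforce(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts per voxel; column = count of dependent neighbours."""
    shape = levels.shape
    entries = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                d = 0
                for off in OFFSETS_26:
                    q = (x + off[0], y + off[1], z + off[2])
                    if _in_bounds(q, shape) and levels[q] > 0 and abs(levels[q] - g) <= alpha:
                        d += 1
                entries.append((g, d))
    dmax = max(d for _, d in entries) + 1
    P = np.zeros((n_levels, dmax))
    for g, d in entries:
        P[g - 1, d] += 1
    return P


def glrlm_bruteforce(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Enumerate maximal runs along all 13 directions by walking."""
    shape = levels.shape
    runs = []
    for off in DIRS_13:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    g = levels[x, y, z]
                    if g == 0:
                        continue
                    prev = (x - off[0], y - off[1], z - off[2])
                    if _in_bounds(prev, shape) and levels[prev] == g:
                        continue  # not a run start
                    length = 1
                    cur = (x + off[0], y + off[1], z + off[2])
                    while _in_bounds(cur, shape) and levels[cur] == g:
                        length += 1
                        cur = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                    runs.append((g, length))
    rmax = max(l for _, l in runs)
    P = np.zeros((n_levels, rmax))
    for g, l in runs:
        P[g - 1, l - 1] += 1
    return P


def glszm_bruteforce(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zones by hand-rolled BFS flood fill over the 26-neighbourhood."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for off in OFFSETS_26:
                        q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
                        if _in_bounds(q, shape) and not seen[q] and levels[q] == g:
                            seen[q] = True
                            stack.append(q)
                zones.append((g, size))
    smax = max(s for _, s in zones)
    P = np.zeros((n_levels, smax))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def ngtdm_bruteforce(levels: np.ndarray, n_levels: int):
    """Per-level |level - neighbourhood mean| sums and counts."""
    shape = levels.shape
    s = np.zeros(n_levels)
    n = np.zeros(n_levels, dtype=int)
    nv = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                nb = []
                for off in OFFSETS_26:
                    q = (x + off[0], y + off[1], z + off[2])
                    if _in_bounds(q, shape) and levels[q] > 0:
                        nb.append(levels[q])
                if nb:
                    s[g - 1] += abs(g - sum(nb) / len(nb))
                    n[g - 1] += 1
                    nv += 1
    return s, n, nv


def icc_a1_anova_oracle(y1: np.ndarray, y2: np.ndarray) -> float:
    """ICC(A,1) from explicitly accumulated sums of squares."""
    n = len(y1)
    k = 2
    grand = (sum(y1) + sum(y2)) / (n * k)
    ss_rows = 0.0
    for i in range(n):
        row_mean = (y1[i] + y2[i]) / 2.0
        ss_rows += k * (row_mean - grand) ** 2
    col1 = sum(y1) / n
    col2 = sum(y2) / n
    ss_cols = n * ((col1 - grand) ** 2 + (col2 - grand) ** 2)
    ss_err = 0.0
    for i in range(n):
        row_mean = (y1[i] + y2[i]) / 2.0
        ss_err += (y1[i] - row_mean - col1 + grand) ** 2
        ss_err += (y2[i] - row_mean - col2 + grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Rank (with tie-averaged ranks) then Pearson."""

    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
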