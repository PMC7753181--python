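"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(idx, shape) -> bool:
    return all(0 <= idx[k] < shape[k] for k in range(3))


def brute_glcm(bins: np.ndarray, n_levels: int, d) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction, both orientations."""
    m = np.zeros((n_levels, n_levels), dtype=np.int64)
    for idx in np.ndindex(bins.shape):
        if bins[idx] < 0:
            continue
        for sgn in (1, -1):
            j = tuple(idx[k] + sgn * d[k] for k in range(3))
            if _inside(j, bins.shape) and bins[j] >= 0:
                m[bins[idx], bins[j]] += 1
    return m


def brute_glrlm(bins: np.ndarray, d) -> dict[tuple[int, int], int]:
    """Run counts {(level, length): count} along one direction."""
    runs: dict[tuple[int, int], int] = {}
    for idx in np.ndindex(bins.shape):
        if bins[idx] < 0:
            continue
        prev = tuple(idx[k] - d[k] for k in range(3))
        if _inside(prev, bins.shape) and bins[prev] == bins[idx]:
            continue  # not a run start
        length = 0
        cur = idx
        while _inside(cur, bins.shape) and bins[cur] == bins[idx]:
            length += 1
            cur = tuple(cur[k] + d[k] for k in range(3))
        key = (int(bins[idx]), length)
        runs[key] = runs.get(key, 0) + 1
    return runs


def brute_zones(bins: np.ndarray) -> dict[tuple[int, int], int]:
    """Zone counts {(level, size): count} by 26-connected flood fill."""
    seen: set[tuple] = set()
    zones: dict[tuple[int, int], int] = {}
    for idx in np.ndindex(bins.shape):
        if bins[idx] < 0 or idx in seen:
            continue
        g = int(bins[idx])
        stack = [idx]
        seen.add(idx)
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFSETS_26:
                nb = tuple(cur[k] + off[k] for k in range(3))
                if _inside(nb, bins.shape) and nb not in seen and bins[nb] == g:
                    seen.add(nb)
                    stack.append(nb)
        zones[(g, size)] = zones.get((g, size), 0) + 1
    return zones


def brute_ngtdm(bins: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level |level - mean(26-neighbourhood)| sums and valid-voxel counts."""
    s = np.zeros(n_levels)
    n = np.zeros(n_levels, dtype=np.int64)
    for idx in np.ndindex(bins.shape):
        if bins[idx] < 0:
            continue
        vals = []
        for off in OFFSETS_26:
            nb = tuple(idx[k] + off[k] for k in range(3))
            if _inside(nb, bins.shape) and bins[nb] >= 0:
                vals.append(bins[nb])
        if vals:
            s[bins[idx]] += abs(bins[idx] - float(np.mean(vals)))
            n[bins[idx]] += 1
    return s, n


def brute_ngldm(bins: np.ndarray, n_levels: int, alpha: int) -> np.ndarray:
    """Dependence matrix (levels x 27); count includes the centre voxel."""
    m = np.zeros((n_levels, 27), dtype=np.int64)
    for idx in np.ndindex(bins.shape):
        if bins[idx] < 0:
            continue
        c = 0
        for off in OFFSETS_26:
            nb = tuple(idx[k] + off[k] for k in range(3))
            if _inside(nb, bins.shape) and bins[nb] >= 0 and abs(int(bins[nb]) - int(bins[idx])) <= alpha:
                c += 1
        m[bins[idx], c] += 1
    return m


def brute_expand(mask: np.ndarray, spacing, r: float) -> np.ndarray:
    """All-pairs Euclidean voxel-center distance expansion."""
    fg = np.argwhere(mask).astype(np.float64) * np.asarray(spacing)
    out = np.zeros_like(mask, dtype=bool)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx, dtype=np.float64) * np.asarray(spacing)
        d2 = ((fg - p) ** 2).sum(axis=1)
        out[idx] = bool((d2 <= r * r + 1e-9).any())
    return out


def brute_contract(mask: np.ndarray, spacing, r: float) -> np.ndarray:
    """Foreground voxels farther than r from every background voxel center."""
    bg = np.argwhere(~mask).astype(np.float64) * np.asarray(spacing)
    out = np.zeros_like(mask, dtype=bool)
    for idx in np.argwhere(mask):
        p = idx.astype(np.float64) * np.asarray(spacing)
        if bg.size == 0:
            out[tuple(idx)] = True
            continue
        d2 = ((bg - p) ** 2).sum(axis=1)
        out[tuple(idx)] = bool((d2 > r * r + 1e-9).all())
    return out


def brute_auc(y: np.ndarray, score: np.ndarray) -> float:
    """Concordant-pair fraction over all positive/negative pairs."""
    pos = score[y == 1]
    neg = score[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def brute_wilcoxon_two_sided(a, b) -> float:
    """Exact two-sided rank-sum p by enumeration of all rank assignments."""
    pooled = sorted(list(a) + list(b))
    n, m = len(a), len(b)
    ranks = {v: i for i, v in enumerate(pooled)}

    def u_stat(group_idx):
        # U for the group holding positions group_idx among sorted pooled values
        r_sum = sum(group_idx) + len(group_idx)  # 1-based ranks
        return r_sum - n * (n + 1) / 2

    obs_idx = sorted(ranks[v] for v in a)
    u_obs = u_stat(obs_idx)
    us = []
    for combo in itertools.combinations(range(n + m), n):
        us.append(u_stat(combo))
    us = np.asarray(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))
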