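"""Independent per-voxel brute-force oracles.

Every function here recomputes a statistic with explicit Python loops
over voxels, independently of the package's vectorised implementations.
Intended for small grids (<= 16^3).
"""

from __future__ import annotations

import numpy as np


def o_volume(mask) -> int:
    count = 0
    for p in range(mask.shape[0]):
        for r in range(mask.shape[1]):
            for c in range(mask.shape[2]):
                if mask[p, r, c]:
                    count += 1
    return count


def o_intersection(a, b) -> int:
    count = 0
    for p in range(a.shape[0]):
        for r in range(a.shape[1]):
            for c in range(a.shape[2]):
                if a[p, r, c] and b[p, r, c]:
                    count += 1
    return count


def o_union(a, b) -> int:
    count = 0
    for p in range(a.shape[0]):
        for r in range(a.shape[1]):
            for c in range(a.shape[2]):
                if a[p, r, c] or b[p, r, c]:
                    count += 1
    return count


def o_jaccard(a, b) -> float:
    union = o_union(a, b)
    if union == 0:
        return 0.0
    return o_intersection(a, b) / union


def o_occupancy(masks) -> np.ndarray:
    shape = masks[0].shape
    counts = np.zeros(shape, dtype=int)
    for p in range(shape[0]):
        for r in range(shape[1]):
            for c in range(shape[2]):
                n = 0
                for m in masks:
                    if m[p, r, c]:
                        n += 1
                counts[p, r, c] = n
    return counts


def o_unique_voxels(masks) -> list[int]:
    """Per-gene count of voxels where that gene alone is expressed."""
    occ = o_occupancy(masks)
    out = []
    for m in masks:
        count = 0
        for p in range(m.shape[0]):
            for r in range(m.shape[1]):
                for c in range(m.shape[2]):
                    if m[p, r, c] and occ[p, r, c] == 1:
                        count += 1
        out.append(count)
    return out


def o_zero_voxels(masks, embryo) -> int:
    occ = o_occupancy(masks)
    count = 0
    for p in range(embryo.shape[0]):
        for r in range(embryo.shape[1]):
            for c in range(embryo.shape[2]):
                if embryo[p, r, c] and occ[p, r, c] == 0:
                    count += 1
    return count


def o_combination_counts(masks, embryo) -> dict[tuple[int, ...], int]:
    """Voxel count per presence/absence pattern, over embryo-mask voxels."""
    out: dict[tuple[int, ...], int] = {}
    for p in range(embryo.shape[0]):
        for r in range(embryo.shape[1]):
            for c in range(embryo.shape[2]):
                if not embryo[p, r, c]:
                    continue
                pattern = tuple(1 if m[p, r, c] else 0 for m in masks)
                out[pattern] = out.get(pattern, 0) + 1
    return out


def o_region_profile(query, masks) -> list[tuple[int, float, float]]:
    """Per gene: (voxels in query, fraction of query, fraction of gene)."""
    qvox = o_volume(query)
    out = []
    for m in masks:
        inter = o_intersection(query, m)
        gvox = o_volume(m)
        out.append((inter, inter / qvox, inter / gvox if gvox else 0.0))
    return out


def o_coverage_outside(a, others) -> float:
    count = 0
    avox = 0
    for p in range(a.shape[0]):
        for r in range(a.shape[1]):
            for c in range(a.shape[2]):
                if a[p, r, c]:
                    avox += 1
                    if not any(o[p, r, c] for o in others):
                        count += 1
    return count / avox


def o_anatomy_fraction(mask, structure) -> float:
    svox = o_volume(structure)
    if svox == 0:
        return 0.0
    return o_intersection(mask, structure) / svox


def o_topk_threshold(values: np.ndarray, k: int) -> float:
    """Exhaustive scan over all distinct off-diagonal JI values: the largest
    threshold at which >= k genes keep at least one edge."""
    n = values.shape[0]
    candidates = sorted(
        {float(values[i, j]) for i in range(n) for j in range(n) if i != j},
        reverse=True,
    )
    best = candidates[-1]
    for tau in candidates:
        connected = 0
        for g in range(n):
            if any(values[g, j] >= tau for j in range(n) if j != g):
                connected += 1
        if connected >= k:
            best = tau
            break
    return best
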