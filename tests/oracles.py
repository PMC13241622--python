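"""Independent brute-force oracles used to check the production code paths.

These deliberately use the slowest, most literal formulation of each
operation and share no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def oracle_fraction_mask(pixels: np.ndarray, analyzed: np.ndarray, fraction: float) -> np.ndarray:
    """Scan every candidate intensity threshold; return the minimal-coverage
    mask (largest threshold) whose intensity sum reaches fraction * total."""
    vals = pixels[analyzed].astype(np.int64)
    total = vals.sum()
    assert total > 0
    best = None
    for t in sorted(np.unique(vals))[::-1]:
        mask = analyzed & (pixels >= t)
        if pixels[mask].astype(np.int64).sum() >= fraction * total:
            best = mask
            break
    assert best is not None
    return best


def oracle_label(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Flood-fill connected components; returns a list of pixel-index sets."""
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                comp = set()
                while stack:
                    ci, cj = stack.pop()
                    comp.add((ci, cj))
                    for di, dj in steps:
                        ni, nj = ci + di, cj + dj
                        if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] and not seen[ni, nj]:
                            seen[ni, nj] = True
                            stack.append((ni, nj))
                comps.append(frozenset(comp))
    return comps


def oracle_pairwise_edge_nm(pixel_sets: list[np.ndarray], pixel_size_nm: float) -> np.ndarray:
    """O(n^2 * pixels^2) exhaustive pixel-pair scan of edge-to-edge distances."""
    n = len(pixel_sets)
    dist = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            best = np.inf
            for pi in pixel_sets[i]:
                for pj in pixel_sets[j]:
                    d = np.hypot(pi[0] - pj[0], pi[1] - pj[1])
                    if d < best:
                        best = d
            dist[i, j] = dist[j, i] = best * pixel_size_nm
    return dist


def oracle_nnd_nm(pixel_sets: list[np.ndarray], pixel_size_nm: float) -> np.ndarray:
    dist = oracle_pairwise_edge_nm(pixel_sets, pixel_size_nm)
    return dist.min(axis=1)


def oracle_cru_partition(distances: np.ndarray, eligible: np.ndarray, threshold_nm: float) -> list[frozenset]:
    """Union-find over the full pairwise matrix on eligible indices; edges are
    strict < threshold."""
    idx = list(np.flatnonzero(eligible))
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in idx:
        for b in idx:
            if a < b and distances[a, b] < threshold_nm:
                parent[find(a)] = find(b)
    groups: dict[int, set] = {}
    for i in idx:
        groups.setdefault(find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=min)


def oracle_point_in_polygon(vertices: np.ndarray, x: float, y: float) -> bool:
    """Ray casting, independent of shapely."""
    inside = False
    n = len(vertices)
    for k in range(n):
        x1, y1 = vertices[k]
        x2, y2 = vertices[(k + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside
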