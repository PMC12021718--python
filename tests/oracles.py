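"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by the most transparent method
available (priority-queue Dijkstra, breadth-first flood fill, exhaustive
enumeration, brute-force pairwise scans) so the package code is checked
against logic that shares nothing with it.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np


def dijkstra_egd(image: np.ndarray, spacing, seeds, alpha: float, lam: float) -> np.ndarray:
    """Priority-queue Dijkstra on the 6-connected voxel graph with the
    mixed spatial/intensity edge weight, exponentialized."""
    shape = image.shape
    dist = np.full(shape, np.inf)
    heap = []
    for s in seeds:
        s = tuple(int(v) for v in s)
        if dist[s] > 0.0:
            dist[s] = 0.0
            heapq.heappush(heap, (0.0, s))
    neighbors = []
    for axis in range(3):
        for step in (-1, 1):
            d = [0, 0, 0]
            d[axis] = step
            neighbors.append((tuple(d), axis))
    while heap:
        d0, u = heapq.heappop(heap)
        if d0 > dist[u]:
            continue
        for (dx, dy, dz), axis in neighbors:
            v = (u[0] + dx, u[1] + dy, u[2] + dz)
            if not (0 <= v[0] < shape[0] and 0 <= v[1] < shape[1] and 0 <= v[2] < shape[2]):
                continue
            di = image[v] - image[u]
            w = np.sqrt((1.0 - lam) * float(spacing[axis]) ** 2 + lam * di * di)
            nd = d0 + w
            if nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return np.exp(-alpha * dist)


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components by explicit breadth-first flood fill."""
    offsets = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        if connectivity == 6 and sum(abs(v) for v in d) != 1:
            continue
        offsets.append(d)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask > 0)):
        if seen[start]:
            continue
        comp = set()
        queue = [start]
        seen[start] = True
        while queue:
            u = queue.pop()
            comp.add(u)
            for d in offsets:
                v = tuple(a + b for a, b in zip(u, d))
                if all(0 <= c < n for c, n in zip(v, mask.shape)) and mask[v] and not seen[v]:
                    seen[v] = True
                    queue.append(v)
        comps.append(comp)
    return comps


def brute_force_transverse_diameter(mask: np.ndarray, spacing) -> float:
    """Max pairwise in-plane distance over transverse slices, all pairs."""
    sx, sy = spacing[0], spacing[1]
    best = 0.0
    for z in range(mask.shape[2]):
        pts = np.argwhere(mask[:, :, z] > 0)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                dx = (pts[i, 0] - pts[j, 0]) * sx
                dy = (pts[i, 1] - pts[j, 1]) * sy
                best = max(best, float(np.hypot(dx, dy)))
    return best


def enumerate_wilcoxon_p(x, y) -> float:
    """Two-sided signed-rank p by enumerating every sign assignment."""
    from scipy.stats import rankdata

    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return float("nan")
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product((False, True), repeat=n)
    ]
    ws = np.asarray(ws)
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def brute_force_extremes(mask: np.ndarray, axis: int, side: str) -> int:
    """Extreme foreground coordinate along an axis by full scan."""
    coords = np.argwhere(mask > 0)[:, axis]
    return int(coords.min() if side == "min" else coords.max())
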