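"""Independent brute-force oracles, deliberately not using the package's
cost-accumulation code paths."""

from __future__ import annotations

import heapq
import math

import numpy as np

SQRT2 = math.sqrt(2.0)

_OFFSETS = [
    (dr, dc)
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    if (dr, dc) != (0, 0)
]


def dijkstra_tc(friction: np.ndarray, sources: list[tuple[int, int]], cell_edge_km: float) -> np.ndarray:
    """Accumulated least-cost distance on the 8-connected grid graph where a
    step a->b costs mean(friction_a, friction_b) * step_length * cell_edge."""
    n_rows, n_cols = friction.shape
    dist = np.full((n_rows, n_cols), np.inf)
    heap = []
    for r, c in sources:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                continue
            length = SQRT2 if dr and dc else 1.0
            nd = d + (friction[r, c] + friction[rr, cc]) / 2.0 * length * cell_edge_km
            if nd < dist[rr, cc]:
                dist[rr, cc] = nd
                heapq.heappush(heap, (nd, rr, cc))
    return dist


def dijkstra_path(
    friction: np.ndarray, sources: list[tuple[int, int]], target: tuple[int, int], cell_edge_km: float
) -> tuple[list[tuple[int, int]], float]:
    """Least-cost path from the cheapest source to ``target`` (predecessor walk)."""
    n_rows, n_cols = friction.shape
    dist = np.full((n_rows, n_cols), np.inf)
    prev: dict[tuple[int, int], tuple[int, int]] = {}
    heap = []
    for r, c in sources:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        if (r, c) == target:
            break
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                continue
            length = SQRT2 if dr and dc else 1.0
            nd = d + (friction[r, c] + friction[rr, cc]) / 2.0 * length * cell_edge_km
            if nd < dist[rr, cc] - 1e-15:
                dist[rr, cc] = nd
                prev[(rr, cc)] = (r, c)
                heapq.heappush(heap, (nd, rr, cc))
    path = [target]
    while path[-1] in prev:
        path.append(prev[path[-1]])
    path.reverse()
    return path, float(dist[target])


def greedy_allocation(cells, capacity: float):
    """Exhaustive-sort greedy harvest oracle.

    ``cells`` is a list of (row, col, rent, harvestable_m3); returns a list of
    (row, col, removed_m3) in harvest order.
    """
    ranked = sorted(
        (c for c in cells if c[2] > 0 and c[3] > 0), key=lambda c: (-c[2], c[0], c[1])
    )
    out = []
    remaining = capacity
    for r, c, _rent, avail in ranked:
        if remaining <= 0:
            break
        take = min(avail, remaining)
        out.append((r, c, take))
        remaining -= take
    return out
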