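"""Logging-center capacity evolution, shutdown, and emergence of new centers."""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .landscape import LandscapeGrid, LoggingCenter, SimulationParams

__all__ = ["update_capacity", "spawn_center", "profitable_volume_window"]


def update_capacity(capacity: float, profitable_volume: float, max_growth: float) -> float:
    """Next-year capacity given the profitable volume in the area of influence.

    Demand-limited growth: when more profitable volume than capacity exists,
    capacity grows by at most ``max_growth`` per year (never beyond the
    available volume); otherwise capacity declines to track the available
    volume.  A result of 0 means the center shuts down.
    """
    if capacity < 0 or profitable_volume < 0 or max_growth < 0:
        raise ValueError("update_capacity requires non-negative inputs")
    if profitable_volume > capacity:
        return min(capacity * (1.0 + max_growth), profitable_volume)
    return profitable_volume


def _disk_kernel(radius_cells: float) -> np.ndarray:
    r = max(int(np.floor(radius_cells)), 0)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx <= radius_cells * radius_cells).astype(float)


def profitable_volume_window(
    profitable_m3: np.ndarray, radius_km: float, cell_edge_km: float
) -> np.ndarray:
    """Sum of profitable volume (m3) within a disk window around each cell."""
    radius_cells = radius_km / cell_edge_km
    kernel = _disk_kernel(radius_cells)
    out = fftconvolve(profitable_m3, kernel, mode="same")
    return np.maximum(out, 0.0)


def spawn_center(
    grid: LandscapeGrid,
    profitable_m3: np.ndarray,
    centers: list[LoggingCenter],
    params: SimulationParams,
    rng: np.random.Generator,
) -> LoggingCenter | None:
    """Try to create a new center after a shutdown.

    Candidate cells must carry profitable volume in a local window and lie
    between min_spawn_distance and max_spawn_distance (straight-line km) from
    the nearest active center.  The candidate with the largest windowed
    profitable volume wins; exact ties are broken by the seeded RNG.  The new
    center starts at ``newborn_capacity`` and inherits price and harvest cost
    from the nearest existing center.  Returns None when no candidate exists.
    """
    edge = grid.cell_edge_km
    windowed = profitable_volume_window(profitable_m3, params.spawn_window_km, edge)

    active = [c for c in centers if c.active]
    rows, cols = np.indices(grid.shape)
    if active:
        d2 = np.full(grid.shape, np.inf)
        for c in active:
            d2 = np.minimum(d2, (rows - c.row) ** 2.0 + (cols - c.col) ** 2.0)
        dist_km = np.sqrt(d2) * edge
        band = (dist_km >= params.min_spawn_distance) & (dist_km <= params.max_spawn_distance)
    else:
        band = np.ones(grid.shape, dtype=bool)

    candidates = band & (windowed > 0) & (profitable_m3 > 0)
    if not candidates.any():
        return None
    score = np.where(candidates, windowed, -np.inf)
    best = score.max()
    ties = np.argwhere(score >= best * (1 - 1e-12))
    pick = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
    row, col = int(pick[0]), int(pick[1])

    nearest = min(centers, key=lambda c: (c.row - row) ** 2 + (c.col - col) ** 2)
    new_id = max(c.id for c in centers) + 1 if centers else 0
    return LoggingCenter(
        id=new_id,
        row=row,
        col=col,
        capacity=params.newborn_capacity,
        price=nearest.price,
        harvest_cost=nearest.harvest_cost,
    )
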