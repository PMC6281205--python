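"""FMU/APU management partition, harvest-mode assignment, and the annual
profitability-driven harvest allocation.

RIL (reduced-impact logging) cells belong to a management partition: the
RIL-zoned region is tiled into management blocks (FMUs), each subdivided into
one annual production unit (APU) per cycle year.  An APU is entered exactly
once per cycle and the removal is capped per hectare.  CL (conventional
logging) cells have no partition, no cap, and may be re-entered.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np

from .landscape import LandscapeGrid, RegistrationError, SchemaError, Zoning

__all__ = [
    "HarvestMode",
    "ManagementPartition",
    "HarvestEvent",
    "ConfigurationError",
    "ConsistencyError",
    "max_ril_removal",
    "partition_fmus",
    "assign_modes",
    "eligible_cells",
    "allocate_harvest",
    "apply_harvest",
]

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


class ConsistencyError(RuntimeError):
    pass


class HarvestMode(enum.IntEnum):
    NONE = 0
    RIL = 1
    CL = 2


@dataclass
class ManagementPartition:
    """FMU/APU bookkeeping over the RIL-zoned region.

    fmu_id is -1 off the RIL region; apu_index is 0 off the region and in
    1..cycle_years on it; harvested_flag marks RIL cells already entered
    this cycle (single-entry rule).
    """

    fmu_id: np.ndarray
    apu_index: np.ndarray
    harvested_flag: np.ndarray
    cycle_years: int

    def copy(self) -> "ManagementPartition":
        return ManagementPartition(
            self.fmu_id.copy(), self.apu_index.copy(), self.harvested_flag.copy(), self.cycle_years
        )


@dataclass(frozen=True)
class HarvestEvent:
    row: int
    col: int
    center: int
    mode: HarvestMode
    volume_m3: float
    rent_brl: float


def max_ril_removal(max_intensity: float, cycle_years: float) -> float:
    """Per-cell, per-cycle RIL removal cap, m3/ha (intensity x cycle length)."""
    if max_intensity < 0 or cycle_years < 0:
        raise ValueError("max_ril_removal requires non-negative inputs")
    return max_intensity * cycle_years


def _block_shape(n_cells: int) -> tuple[int, int]:
    """Most-square (rows, cols) factorization of n_cells."""
    best = (1, n_cells)
    for h in range(1, int(math.isqrt(n_cells)) + 1):
        if n_cells % h == 0:
            best = (h, n_cells // h)
    return best


def partition_fmus(
    ril_mask: np.ndarray,
    fmu_area: float,
    cycle_years: int,
    cell_area: float,
    seed: int = 0,
) -> ManagementPartition:
    """Tile the RIL region into FMU blocks and subdivide each into APUs.

    FMUs are rectangular blocks laid out row-major over the grid; blocks
    clipped by the grid edge or the RIL mask become truncated FMUs with
    proportionally smaller APUs.  Where the APU size is a perfect square
    that tiles the block, APUs are contiguous sub-blocks; otherwise cells
    are dealt round-robin in scan order.  Deterministic for a fixed seed.
    """
    fmu_cells = max(1, round(fmu_area / cell_area))
    apu_cells = fmu_cells // cycle_years
    if apu_cells < 1:
        raise ConfigurationError(
            f"APU smaller than one cell: {fmu_cells} FMU cells / {cycle_years} years"
        )
    bh, bw = _block_shape(fmu_cells)

    n_rows, n_cols = ril_mask.shape
    fmu_id = np.full(ril_mask.shape, -1, dtype=np.int32)
    apu_index = np.zeros(ril_mask.shape, dtype=np.int16)

    s = math.isqrt(apu_cells)
    subblocks = s * s == apu_cells and bh % s == 0 and bw % s == 0

    next_fmu = 0
    for r0 in range(0, n_rows, bh):
        for c0 in range(0, n_cols, bw):
            r1, c1 = min(r0 + bh, n_rows), min(c0 + bw, n_cols)
            block = ril_mask[r0:r1, c0:c1]
            n_in = int(block.sum())
            if n_in == 0:
                continue
            fid = next_fmu
            next_fmu += 1
            fmu_id[r0:r1, c0:c1][block] = fid
            complete = n_in == fmu_cells and (r1 - r0) == bh and (c1 - c0) == bw
            if n_in < fmu_cells:
                logger.warning(
                    "truncated FMU %d: %d of %d cells; APUs will be smaller", fid, n_in, fmu_cells
                )
            if complete and subblocks:
                # contiguous s x s APU sub-blocks, scan order within the block
                rr, cc = np.nonzero(block)
                k = (rr // s) * (bw // s) + (cc // s)
                apu_index[r0:r1, c0:c1][block] = (k % cycle_years) + 1
            else:
                # round-robin over scan-ordered cells: sizes differ by <= 1
                apu_index[r0:r1, c0:c1][block] = (np.arange(n_in) % cycle_years + 1).astype(
                    np.int16
                )
    return ManagementPartition(
        fmu_id=fmu_id,
        apu_index=apu_index,
        harvested_flag=np.zeros(ril_mask.shape, dtype=bool),
        cycle_years=cycle_years,
    )


def assign_modes(zoning: np.ndarray, scenario) -> np.ndarray:
    """Per-cell harvest mode from the scenario's zoning-category map."""
    mode_map = np.full(zoning.shape, -1, dtype=np.int16)
    for z in np.unique(zoning):
        cat = Zoning(int(z))
        if cat not in scenario.category_mode:
            raise ConfigurationError(f"scenario {scenario.name!r} has no mode for {cat.name}")
        mode_map[zoning == z] = int(scenario.category_mode[cat])
    return mode_map


def eligible_cells(
    grid: LandscapeGrid,
    partition: ManagementPartition,
    mode_map: np.ndarray,
    year: int,
) -> np.ndarray:
    """Boolean mask of cells that may be harvested in cycle-year ``year``.

    RIL: the cell's APU must be on rotation this year and not yet entered.
    CL: any remaining volume makes the cell eligible (re-entry allowed).
    """
    if not 1 <= year <= partition.cycle_years:
        raise ValueError(f"year {year} outside 1..{partition.cycle_years}")
    if mode_map.shape != grid.shape:
        raise RegistrationError("mode_map misregistered with grid")
    ril = (mode_map == HarvestMode.RIL) & (partition.apu_index == year) & ~partition.harvested_flag
    cl = (mode_map == HarvestMode.CL) & (grid.volume > 0)
    return ril | cl


def allocate_harvest(
    center_id: int,
    eligible: np.ndarray,
    rent: np.ndarray,
    harvestable_m3: np.ndarray,
    capacity: float,
    mode_map: np.ndarray,
) -> list[HarvestEvent]:
    """Greedy allocation: take positive-rent eligible cells in decreasing
    rent order (ties by (row, col)) until capacity is exhausted.

    The last cell may be taken partially; its recorded rent is pro-rated by
    the fraction of its harvestable volume removed.
    """
    if capacity < 0:
        raise ValueError("capacity must be >= 0")
    events: list[HarvestEvent] = []
    if capacity == 0:
        return events
    take = eligible & (rent > 0) & (harvestable_m3 > 0)
    rows, cols = np.nonzero(take)
    if rows.size == 0:
        return events
    order = np.lexsort((cols, rows, -rent[rows, cols]))
    remaining = float(capacity)
    for i in order:
        if remaining <= 0:
            break
        r, c = int(rows[i]), int(cols[i])
        avail = float(harvestable_m3[r, c])
        removed = min(avail, remaining)
        events.append(
            HarvestEvent(
                row=r,
                col=c,
                center=center_id,
                mode=HarvestMode(int(mode_map[r, c])),
                volume_m3=removed,
                rent_brl=float(rent[r, c]) * removed / avail,
            )
        )
        remaining -= removed
    return events


def apply_harvest(
    grid: LandscapeGrid,
    events: list[HarvestEvent],
    partition: ManagementPartition,
) -> None:
    """Decrement standing volume and update RIL single-entry flags in place."""
    for ev in events:
        if ev.mode == HarvestMode.NONE:
            raise ConsistencyError(f"harvest event on a no-harvest cell {(ev.row, ev.col)}")
        per_ha = ev.volume_m3 / grid.cell_area
        remaining = grid.volume[ev.row, ev.col]
        if per_ha > remaining + 1e-9:
            raise ConsistencyError(
                f"removal {per_ha} m3/ha exceeds remaining {remaining} at {(ev.row, ev.col)}"
            )
        grid.volume[ev.row, ev.col] = max(remaining - per_ha, 0.0)
        if ev.mode == HarvestMode.RIL:
            if partition.harvested_flag[ev.row, ev.col]:
                raise ConsistencyError(f"RIL cell {(ev.row, ev.col)} entered twice in one cycle")
            partition.harvested_flag[ev.row, ev.col] = True
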