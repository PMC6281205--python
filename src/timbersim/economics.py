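"""Friction surfaces, accumulated transport cost, and per-cell net rent.

Friction is a per-cell traversal cost in R$/m3/km.  Accumulated transport
cost to the cheapest logging center is computed as a least-cost path on the
8-connected grid graph where a step between adjacent cells costs the mean of
the two cells' frictions times the step length (diagonals scaled by sqrt 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.graph import MCP_Geometric

from .harvest import HarvestMode, max_ril_removal
from .landscape import (
    BARRIER_ZONES,
    LandCover,
    LandscapeGrid,
    LoggingCenter,
    RegistrationError,
    RoadClass,
    SchemaError,
    SimulationParams,
    Zoning,
)

__all__ = [
    "BARRIER_FRICTION",
    "ROAD_FRICTION",
    "COVER_FRICTION",
    "SOFT_ZONE_FRICTION",
    "PROV_BARRIER",
    "PROV_ROAD",
    "PROV_COVER",
    "PROV_ZONING",
    "FrictionSurface",
    "CostSurface",
    "StateError",
    "build_friction_surface",
    "cost_distance",
    "unit_total_cost",
    "net_rent_map",
    "harvestable_volume",
]

#: Sentinel friction for zoning barrier classes — prohibitive, not infinite.
BARRIER_FRICTION = 5000.0

ROAD_FRICTION = {
    RoadClass.PAVED: 0.3,
    RoadClass.UNPAVED: 0.5,
    RoadClass.DUPLICATED: 0.2,
    RoadClass.NAVIGABLE_RIVER: 0.1,
    RoadClass.SEASONALLY_NAVIGABLE_RIVER: 1.0,
}

COVER_FRICTION = {
    LandCover.DEFORESTED: 0.7,
    LandCover.GRASSLAND: 0.7,
    LandCover.FOREST: 0.8,
    LandCover.NON_NAVIGABLE_WATER: 2.0,
}

#: Sustainable-use and undesignated public forest traversal value; applies
#: only where no road or land-cover rule is cheaper.
SOFT_ZONE_FRICTION = 0.8
_SOFT_ZONES = (Zoning.SUSTAINABLE_USE_OTHER, Zoning.UNDESIGNATED_FEDERAL, Zoning.UNDESIGNATED_STATE)

# provenance codes: which rule set each cell's friction
PROV_COVER = 1
PROV_ZONING = 2
PROV_ROAD = 3
PROV_BARRIER = 4


class StateError(RuntimeError):
    """Operation requires simulation state that is absent (e.g. no centers)."""


@dataclass
class FrictionSurface:
    friction: np.ndarray  # R$/m3/km
    provenance: np.ndarray  # PROV_* code per cell

    def __post_init__(self) -> None:
        if self.friction.shape != self.provenance.shape:
            raise RegistrationError("friction/provenance misregistered")
        if np.any(self.friction <= 0):
            raise SchemaError("friction must be positive everywhere")


@dataclass
class CostSurface:
    """Accumulated transport cost TC (R$/m3) and nearest-center allocation."""

    tc: np.ndarray
    allocation: np.ndarray  # center id per cell, -1 where unreachable


def build_friction_surface(grid: LandscapeGrid) -> FrictionSurface:
    """Per-cell friction by precedence: zoning barriers > roads > land cover.

    Sustainable-use / undesignated zoning contributes 0.8 where neither a
    road nor the land-cover class is cheaper.
    """
    friction = np.empty(grid.shape, dtype=float)
    provenance = np.full(grid.shape, PROV_COVER, dtype=np.int8)

    for cover, value in COVER_FRICTION.items():
        friction[grid.land_cover == cover] = value

    soft = np.isin(grid.zoning, [int(z) for z in _SOFT_ZONES])
    zoning_cheaper = soft & (SOFT_ZONE_FRICTION < friction)
    friction[zoning_cheaper] = SOFT_ZONE_FRICTION
    provenance[zoning_cheaper] = PROV_ZONING

    for road, value in ROAD_FRICTION.items():
        on = grid.roads == road
        friction[on] = value
        provenance[on] = PROV_ROAD

    barrier = np.isin(grid.zoning, [int(z) for z in BARRIER_ZONES])
    friction[barrier] = BARRIER_FRICTION
    provenance[barrier] = PROV_BARRIER

    return FrictionSurface(friction=friction, provenance=provenance)


def cost_distance(
    friction: FrictionSurface,
    centers: list[LoggingCenter],
    cell_edge_km: float,
) -> CostSurface:
    """Least-cost accumulated transport cost to the cheapest active center.

    Ties between centers resolve to the lowest center id.
    """
    active = sorted((c for c in centers if c.active), key=lambda c: c.id)
    if not active:
        raise StateError("cost_distance requires at least one active center")
    step_cost = friction.friction * cell_edge_km
    stack = np.empty((len(active),) + step_cost.shape, dtype=float)
    for k, c in enumerate(active):
        mcp = MCP_Geometric(step_cost, fully_connected=True)
        cum, _ = mcp.find_costs([(c.row, c.col)])
        stack[k] = cum
    best = np.argmin(stack, axis=0)
    tc = np.take_along_axis(stack, best[None], axis=0)[0]
    ids = np.array([c.id for c in active])
    allocation = ids[best]
    allocation = np.where(np.isfinite(tc), allocation, -1)
    return CostSurface(tc=tc, allocation=allocation)


def unit_total_cost(hc, tc, interest_rate):
    """Total unit cost: (harvest cost + transport cost) x (1 + interest rate)."""
    hc = np.asarray(hc, dtype=float)
    tc = np.asarray(tc, dtype=float)
    if np.any(hc < 0) or np.any(tc[np.isfinite(tc)] < 0) or interest_rate < 0:
        raise ValueError("unit_total_cost requires non-negative inputs")
    out = (hc + tc) * (1.0 + interest_rate)
    return float(out) if out.ndim == 0 else out


def harvestable_volume(
    grid: LandscapeGrid,
    mode_map: np.ndarray,
    params: SimulationParams,
    harvested_flag: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell harvestable volume (m3/ha) under the assigned mode.

    RIL cells are capped at max_intensity x cycle_years per cycle and yield
    nothing after their single entry; CL cells expose all remaining volume.
    """
    if mode_map.shape != grid.shape:
        raise RegistrationError("mode_map misregistered with grid")
    cap = max_ril_removal(params.max_intensity, params.cycle_years)
    v = np.zeros(grid.shape)
    ril = mode_map == HarvestMode.RIL
    cl = mode_map == HarvestMode.CL
    v[ril] = np.minimum(grid.volume[ril], cap)
    v[cl] = grid.volume[cl]
    if harvested_flag is not None:
        v[ril & harvested_flag] = 0.0
    return v


def net_rent_map(
    grid: LandscapeGrid,
    cost_surface: CostSurface,
    params: SimulationParams,
    mode_map: np.ndarray,
    harvested_flag: np.ndarray | None = None,
) -> np.ndarray:
    """Net rent per cell, R$: harvestable volume x (price - total unit cost).

    Cells with rent <= 0, no harvest mode, or no allocation are unprofitable
    (rent clamped to the computed value; callers treat <= 0 as "do not take").
    Unreachable cells get rent 0.
    """
    v = harvestable_volume(grid, mode_map, params, harvested_flag)
    utc = unit_total_cost(
        grid.harvest_cost, np.where(np.isfinite(cost_surface.tc), cost_surface.tc, 0.0),
        params.interest_rate,
    )
    rent = v * grid.cell_area * (grid.price - utc)
    rent[~np.isfinite(cost_surface.tc)] = 0.0
    rent[cost_surface.allocation < 0] = 0.0
    return rent
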