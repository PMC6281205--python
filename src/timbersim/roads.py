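"""Annual construction of unpaved roads reaching newly harvested cells.

Each harvested cell not already on the transport network is connected to its
cheapest network attachment (existing road, waterway, or a center cell)
along the least-cost path on the current friction surface.  Newly built
cells become unpaved road and immediately cheapen subsequent paths, so
within a year paths are processed in decreasing order of target-cell rent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.graph import MCP_Geometric

from .economics import BARRIER_FRICTION, ROAD_FRICTION, FrictionSurface, PROV_ROAD
from .harvest import HarvestEvent
from .landscape import BARRIER_ZONES, LandscapeGrid, LoggingCenter, RoadClass

__all__ = ["RoadBuildLog", "extend_roads"]

logger = logging.getLogger(__name__)

_UNPAVED = ROAD_FRICTION[RoadClass.UNPAVED]


@dataclass
class RoadBuildLog:
    """Paths built so far: one (year, list of path cells) entry per new road."""

    entries: list[tuple[int, list[tuple[int, int]]]] = field(default_factory=list)


def extend_roads(
    grid: LandscapeGrid,
    events: list[HarvestEvent],
    friction: FrictionSurface,
    centers: list[LoggingCenter],
    year: int = 0,
    build_log: RoadBuildLog | None = None,
) -> RoadBuildLog:
    """Connect this year's harvested cells to the network; mutates ``grid.roads``
    and ``friction`` in place.

    Zoning-barrier cells are never converted to road even when a least-cost
    path crosses them (a warning is logged and the path cost simply reflects
    barrier traversal).  Existing road cells keep their class.
    """
    if build_log is None:
        build_log = RoadBuildLog()
    network = grid.roads != RoadClass.NONE
    for c in centers:
        network[c.row, c.col] = True
    barrier = np.isin(grid.zoning, [int(z) for z in BARRIER_ZONES])

    order = sorted(events, key=lambda e: (-e.rent_brl, e.row, e.col))
    targets = [(ev.row, ev.col) for ev in order if not network[ev.row, ev.col]]
    if not targets:
        return build_log

    # One least-cost propagation from the whole pre-existing network per
    # year; tracebacks walked target-to-network are truncated as soon as
    # they meet a road built earlier this year, so higher-rent targets lay
    # the trunks that cheaper ones reuse.
    edge = grid.cell_edge_km
    mcp = MCP_Geometric(friction.friction * edge, fully_connected=True)
    mcp.find_costs(np.argwhere(network), ends=targets)
    for rc in targets:
        if network[rc]:
            continue
        full = [tuple(p) for p in mcp.traceback(rc)]
        path: list[tuple[int, int]] = []
        for r, c in reversed(full):  # walk from the target toward the network
            path.append((r, c))
            if network[r, c]:
                break
        path.reverse()
        if any(friction.friction[r, c] >= BARRIER_FRICTION for r, c in path):
            logger.warning("year %d: road to %s forced across a barrier", year, rc)
        for r, c in path:
            if network[r, c] or barrier[r, c]:
                continue
            grid.roads[r, c] = RoadClass.UNPAVED
            network[r, c] = True
            if _UNPAVED < friction.friction[r, c]:
                friction.friction[r, c] = _UNPAVED
                friction.provenance[r, c] = PROV_ROAD
        build_log.entries.append((year, path))
    return build_log
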