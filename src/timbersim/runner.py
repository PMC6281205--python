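"""The annual simulation loop and the built-in LEGAL / ILLEGAL scenarios.

Each simulated year: (1) rebuild friction, accumulated transport cost and
areas of influence, (2) assign price and harvest-cost layers per allocation,
(3) compute net rent, (4) determine eligibility, (5) allocate and apply
harvest per center under its capacity, (6) extend the road network to the
newly harvested cells, (7) update center capacities, shut down exhausted
centers and possibly spawn replacements, (8) append to the ledger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import economics, harvest, industry, roads
from .harvest import HarvestMode
from .landscape import (
    BARRIER_ZONES,
    HARVESTABLE_ZONES,
    LandscapeGrid,
    LoggingCenter,
    SimulationParams,
    Zoning,
)
from .ledger import AnnualLedger

__all__ = ["ScenarioConfig", "run_scenario", "run_pair"]

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Zoning-category -> harvest-mode map plus global parameters.

    The built-in LEGAL scenario applies RIL everywhere harvest is allowed;
    ILLEGAL keeps RIL in national forests and other sustainable-use lands
    but allows CL on private and undesignated lands.  Strictly protected,
    indigenous and military lands are closed to harvest in both.
    """

    name: str
    category_mode: dict[Zoning, HarvestMode]
    params: SimulationParams = field(default_factory=SimulationParams)

    def __post_init__(self) -> None:
        for z in BARRIER_ZONES:
            if self.category_mode.get(z, HarvestMode.NONE) != HarvestMode.NONE:
                raise harvest.ConfigurationError(f"{z.name} must be closed to harvest")
            self.category_mode.setdefault(z, HarvestMode.NONE)

    @classmethod
    def legal(cls, params: SimulationParams | None = None) -> "ScenarioConfig":
        modes = {z: HarvestMode.RIL for z in HARVESTABLE_ZONES}
        modes.update({z: HarvestMode.NONE for z in BARRIER_ZONES})
        return cls("LEGAL", modes, params or SimulationParams())

    @classmethod
    def illegal(cls, params: SimulationParams | None = None) -> "ScenarioConfig":
        modes = {
            Zoning.PRIVATE_NONPROTECTED: HarvestMode.CL,
            Zoning.UNDESIGNATED_FEDERAL: HarvestMode.CL,
            Zoning.UNDESIGNATED_STATE: HarvestMode.CL,
            Zoning.NATIONAL_FOREST: HarvestMode.RIL,
            Zoning.SUSTAINABLE_USE_OTHER: HarvestMode.RIL,
        }
        modes.update({z: HarvestMode.NONE for z in BARRIER_ZONES})
        return cls("ILLEGAL", modes, params or SimulationParams())


def _baseline_table(grid: LandscapeGrid) -> pd.DataFrame:
    rows = []
    for z in Zoning:
        mask = grid.zoning == z
        rows.append(
            {
                "category": z.name.lower(),
                "stock_m3": float(grid.volume[mask].sum() * grid.cell_area),
                "area_ha": float(mask.sum() * grid.cell_area),
            }
        )
    return pd.DataFrame(rows)


def _assign_price_layers(
    grid: LandscapeGrid, centers: list[LoggingCenter], allocation: np.ndarray
) -> None:
    """Rewrite per-cell price and harvest cost from the area-of-influence owner."""
    price = np.zeros(grid.shape)
    hc = np.zeros(grid.shape)
    for c in centers:
        if not c.active:
            continue
        mask = allocation == c.id
        price[mask] = c.price
        hc[mask] = c.harvest_cost
    grid.price = price
    grid.harvest_cost = hc


def _profitable_by_center(
    grid, params, mode_map, partition, cost_surface
) -> tuple[dict[int, float], np.ndarray]:
    """Positive-rent harvestable volume (m3) summed per center, plus the map."""
    rent = economics.net_rent_map(grid, cost_surface, params, mode_map, partition.harvested_flag)
    hv = economics.harvestable_volume(grid, mode_map, params, partition.harvested_flag)
    profitable = np.where(rent > 0, hv * grid.cell_area, 0.0)
    totals: dict[int, float] = {}
    for cid in np.unique(cost_surface.allocation):
        if cid < 0:
            continue
        totals[int(cid)] = float(profitable[cost_surface.allocation == cid].sum())
    return totals, profitable


def run_scenario(
    grid: LandscapeGrid,
    centers: list[LoggingCenter],
    scenario: ScenarioConfig,
    years: int | None = None,
) -> AnnualLedger:
    """Run one scenario for ``years`` annual steps (default: one full cycle).

    Inputs are copied, never mutated.  Deterministic for a fixed
    ``scenario.params.rng_seed``.
    """
    params = scenario.params
    if years is None:
        years = params.cycle_years
    grid = grid.copy()
    centers = [LoggingCenter(**vars(c)) for c in centers]
    for c in centers:
        c.check_on_grid(grid.shape)
    rng = np.random.default_rng(params.rng_seed)

    baseline = _baseline_table(grid)
    mode_map = harvest.assign_modes(grid.zoning, scenario)
    partition = harvest.partition_fmus(
        mode_map == HarvestMode.RIL,
        params.fmu_area,
        params.cycle_years,
        grid.cell_area,
        seed=params.rng_seed,
    )
    first_logged = np.zeros(grid.shape, dtype=bool)
    build_log = roads.RoadBuildLog()
    records: list[dict] = []

    for year in range(1, years + 1):
        active = [c for c in centers if c.active]
        if not active:
            logger.info("%s year %d: no active centers left, stopping", scenario.name, year)
            break
        friction = economics.build_friction_surface(grid)
        cs = economics.cost_distance(friction, centers, grid.cell_edge_km)
        _assign_price_layers(grid, centers, cs.allocation)
        rent = economics.net_rent_map(grid, cs, params, mode_map, partition.harvested_flag)
        hv_m3 = (
            economics.harvestable_volume(grid, mode_map, params, partition.harvested_flag)
            * grid.cell_area
        )
        cycle_year = (year - 1) % params.cycle_years + 1
        eligible = harvest.eligible_cells(grid, partition, mode_map, cycle_year)

        year_events: list[harvest.HarvestEvent] = []
        for c in sorted(active, key=lambda c: c.id):
            own = eligible & (cs.allocation == c.id)
            events = harvest.allocate_harvest(c.id, own, rent, hv_m3, c.capacity, mode_map)
            harvest.apply_harvest(grid, events, partition)
            year_events.extend(events)

        # ledger rows: aggregate this year's events per (center, category)
        agg: dict[tuple[int, str, str], list[float]] = {}
        for ev in year_events:
            cat = Zoning(int(grid.zoning[ev.row, ev.col])).name.lower()
            key = (ev.center, cat, ev.mode.name)
            tot = agg.setdefault(key, [0.0, 0.0, 0.0])
            tot[0] += ev.volume_m3
            tot[2] += ev.rent_brl
            if not first_logged[ev.row, ev.col]:
                tot[1] += grid.cell_area
                first_logged[ev.row, ev.col] = True
        for (cid, cat, mode), (vol, area, rnt) in sorted(agg.items()):
            records.append(
                {
                    "year": year,
                    "center": cid,
                    "category": cat,
                    "mode": mode,
                    "volume_m3": vol,
                    "area_ha": area,
                    "rent_brl": rnt,
                }
            )

        roads.extend_roads(grid, year_events, friction, active, year=year, build_log=build_log)

        # capacity reacts to post-harvest profitable volume (same cost surface)
        profitable, profitable_map = _profitable_by_center(
            grid, params, mode_map, partition, cs
        )
        shutdowns = 0
        for c in sorted(active, key=lambda c: c.id):
            new_cap = industry.update_capacity(
                c.capacity, profitable.get(c.id, 0.0), params.max_capacity_growth
            )
            c.capacity = new_cap
            if new_cap == 0:
                c.active = False
                shutdowns += 1
        for _ in range(shutdowns):
            born = industry.spawn_center(grid, profitable_map, centers, params, rng)
            if born is None:
                break
            born.check_on_grid(grid.shape)
            centers.append(born)
            logger.info("%s year %d: new center %d at %s", scenario.name, year, born.id, born.location)

    ledger = AnnualLedger(
        records=pd.DataFrame(records) if records else AnnualLedger().records,
        baseline=baseline,
        scenario=scenario.name,
        rasters={
            "remaining_volume": grid.volume,
            "logged_mask": first_logged,
            "roads": grid.roads,
            "harvested_flag": partition.harvested_flag,
        },
    )
    ledger.rasters["centers"] = centers
    ledger.rasters["build_log"] = build_log
    return ledger


def run_pair(
    grid: LandscapeGrid,
    centers: list[LoggingCenter],
    params: SimulationParams | None = None,
    years: int | None = None,
) -> tuple[AnnualLedger, AnnualLedger]:
    """Run LEGAL and ILLEGAL from identical initial state and seed."""
    params = params or SimulationParams()
    legal = run_scenario(grid, centers, ScenarioConfig.legal(params), years=years)
    illegal = run_scenario(grid, centers, ScenarioConfig.illegal(params), years=years)
    return legal, illegal
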