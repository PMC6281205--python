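"""Core domain types: the raster landscape, logging centers, and global parameters.

All layers of a :class:`LandscapeGrid` are co-registered numpy arrays of the
same shape, indexed ``(row, col)`` with row 0 at the top.  Categorical layers
use small integer codes defined by the enums in this module.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LandCover",
    "Zoning",
    "RoadClass",
    "BARRIER_ZONES",
    "HARVESTABLE_ZONES",
    "LandscapeGrid",
    "LoggingCenter",
    "SimulationParams",
    "RegistrationError",
    "SchemaError",
    "PlacementError",
]


class RegistrationError(ValueError):
    """Raster layers do not share shape / registration."""


class SchemaError(ValueError):
    """A layer contains an unknown category code, or a table is malformed."""


class PlacementError(ValueError):
    """A logging center does not fall inside the grid."""


class LandCover(enum.IntEnum):
    FOREST = 1
    DEFORESTED = 2
    GRASSLAND = 3
    NON_NAVIGABLE_WATER = 4


class Zoning(enum.IntEnum):
    PRIVATE_NONPROTECTED = 1
    SUSTAINABLE_USE_OTHER = 2
    NATIONAL_FOREST = 3
    UNDESIGNATED_FEDERAL = 4
    UNDESIGNATED_STATE = 5
    STRICTLY_PROTECTED = 6
    INDIGENOUS = 7
    MILITARY = 8


class RoadClass(enum.IntEnum):
    NONE = 0
    PAVED = 1
    UNPAVED = 2
    DUPLICATED = 3
    NAVIGABLE_RIVER = 4
    SEASONALLY_NAVIGABLE_RIVER = 5


#: Zoning categories that are closed to harvest and act as transit barriers.
BARRIER_ZONES = (Zoning.STRICTLY_PROTECTED, Zoning.INDIGENOUS, Zoning.MILITARY)

#: Zoning categories where some harvest mode may be assigned.
HARVESTABLE_ZONES = (
    Zoning.PRIVATE_NONPROTECTED,
    Zoning.SUSTAINABLE_USE_OTHER,
    Zoning.NATIONAL_FOREST,
    Zoning.UNDESIGNATED_FEDERAL,
    Zoning.UNDESIGNATED_STATE,
)


def _check_codes(layer: np.ndarray, enum_cls, name: str) -> None:
    valid = np.array([int(m) for m in enum_cls])
    bad = ~np.isin(layer, valid)
    if bad.any():
        codes = sorted(np.unique(layer[bad]).tolist())
        raise SchemaError(f"{name} layer contains unknown codes {codes}")


@dataclass
class LandscapeGrid:
    """Co-registered raster stack describing one landscape.

    Parameters
    ----------
    volume : commercial wood volume, m3/ha; forced to 0 on non-forest cells.
    land_cover, zoning, roads : categorical layers coded by the module enums.
    price, harvest_cost : R$/m3 layers, assigned per area of influence
        (may start as zeros; the simulation loop rewrites them every year).
    cell_area : hectares per cell (default 100 ha, i.e. a 1 km x 1 km cell).
    """

    volume: np.ndarray
    land_cover: np.ndarray
    zoning: np.ndarray
    roads: np.ndarray
    price: np.ndarray | None = None
    harvest_cost: np.ndarray | None = None
    cell_area: float = 100.0

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.land_cover = np.asarray(self.land_cover, dtype=np.int16)
        self.zoning = np.asarray(self.zoning, dtype=np.int16)
        self.roads = np.asarray(self.roads, dtype=np.int16)
        shape = self.volume.shape
        if self.volume.ndim != 2:
            raise RegistrationError("layers must be 2-D rasters")
        for name in ("land_cover", "zoning", "roads"):
            if getattr(self, name).shape != shape:
                raise RegistrationError(
                    f"{name} shape {getattr(self, name).shape} != volume shape {shape}"
                )
        if self.price is None:
            self.price = np.zeros(shape)
        if self.harvest_cost is None:
            self.harvest_cost = np.zeros(shape)
        self.price = np.asarray(self.price, dtype=float)
        self.harvest_cost = np.asarray(self.harvest_cost, dtype=float)
        for name in ("price", "harvest_cost"):
            if getattr(self, name).shape != shape:
                raise RegistrationError(f"{name} layer misregistered")
        _check_codes(self.land_cover, LandCover, "land_cover")
        _check_codes(self.zoning, Zoning, "zoning")
        _check_codes(self.roads, RoadClass, "roads")
        if np.any(self.volume < 0):
            raise SchemaError("volume layer has negative values")
        if self.cell_area <= 0:
            raise SchemaError("cell_area must be positive")
        # Baseline deforestation masking: no commercial volume off forest.
        self.volume = np.where(self.land_cover == LandCover.FOREST, self.volume, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.volume.shape

    @property
    def n_rows(self) -> int:
        return self.volume.shape[0]

    @property
    def n_cols(self) -> int:
        return self.volume.shape[1]

    @property
    def cell_edge_km(self) -> float:
        """Edge length of one (square) cell, km; 100 ha -> 1 km."""
        return math.sqrt(self.cell_area / 100.0)

    def copy(self) -> "LandscapeGrid":
        return replace(
            self,
            volume=self.volume.copy(),
            land_cover=self.land_cover.copy(),
            zoning=self.zoning.copy(),
            roads=self.roads.copy(),
            price=self.price.copy(),
            harvest_cost=self.harvest_cost.copy(),
        )

    def total_stock_m3(self) -> float:
        """Standing commercial stock, m3."""
        return float(self.volume.sum() * self.cell_area)


@dataclass
class LoggingCenter:
    """A milling / demand hub with an annual processing capacity."""

    id: int
    row: int
    col: int
    capacity: float  # m3/yr
    price: float  # R$/m3
    harvest_cost: float  # R$/m3
    active: bool = True

    def __post_init__(self) -> None:
        if self.capacity < 0:
            raise SchemaError(f"center {self.id}: capacity must be >= 0")
        if self.price <= 0:
            raise SchemaError(f"center {self.id}: price must be > 0")
        if self.harvest_cost < 0:
            raise SchemaError(f"center {self.id}: harvest cost must be >= 0")
        if not self.active and self.capacity != 0:
            raise SchemaError(f"center {self.id}: inactive centers must have capacity 0")

    @property
    def location(self) -> tuple[int, int]:
        return (self.row, self.col)

    def check_on_grid(self, shape: tuple[int, int]) -> None:
        if not (0 <= self.row < shape[0] and 0 <= self.col < shape[1]):
            raise PlacementError(
                f"center {self.id} at {(self.row, self.col)} outside grid {shape}"
            )


@dataclass
class SimulationParams:
    """Global simulation parameters (annual timestep, one harvest cycle)."""

    cycle_years: int = 30
    max_intensity: float = 0.86  # m3/ha/yr cap in RIL mode
    fmu_area: float = 27_000.0  # ha
    apu_area: float = 900.0  # ha
    newborn_capacity: float = 50_000.0  # m3/yr
    max_capacity_growth: float = 0.20  # fraction/yr
    min_spawn_distance: float = 200.0  # km
    max_spawn_distance: float = 500.0  # km
    spawn_window_km: float = 50.0  # radius of the "nearby volume" search window
    interest_rate: float = 0.05  # fraction/yr
    price_drift: float = 0.0  # fraction/yr (held at 0)
    exchange_rate: float = 1.995  # BRL per USD
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_intensity",
            "fmu_area",
            "apu_area",
            "newborn_capacity",
            "max_capacity_growth",
            "interest_rate",
            "price_drift",
        ):
            if getattr(self, name) < 0:
                raise SchemaError(f"{name} must be >= 0")
        if self.cycle_years < 1:
            raise SchemaError("cycle_years must be >= 1")
        if not self.min_spawn_distance < self.max_spawn_distance:
            raise SchemaError("min_spawn_distance must be < max_spawn_distance")
        if self.exchange_rate <= 0:
            raise SchemaError("exchange_rate must be > 0")
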