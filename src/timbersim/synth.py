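"""Seeded generator of synthetic landscapes, zoning mosaics, road networks
and logging-center tables.

The generator emulates the statistical structure the simulation assumes:
a spatially autocorrelated commercial-volume field with a configurable
forest-cell mean, a contiguous zoning mosaic hitting target area fractions,
a sparse road skeleton connecting all centers, and center capacities,
prices and harvest costs drawn from configurable ranges.  Everything is
deterministic for a fixed (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import minimum_spanning_tree
from skimage.draw import line as draw_line

from .landscape import (
    LandCover,
    LandscapeGrid,
    LoggingCenter,
    RoadClass,
    SchemaError,
    Zoning,
)

__all__ = ["LandscapeSpec", "SpecError", "CatalogueError", "generate_landscape", "generate_fixture", "FIXTURES"]


class SpecError(ValueError):
    pass


class CatalogueError(KeyError):
    pass


def _default_fractions() -> dict[Zoning, float]:
    # Calibrated to an Amazon-like zoning composition (share of total area).
    return {
        Zoning.PRIVATE_NONPROTECTED: 0.417,
        Zoning.SUSTAINABLE_USE_OTHER: 0.110,
        Zoning.NATIONAL_FOREST: 0.028,
        Zoning.UNDESIGNATED_FEDERAL: 0.077,
        Zoning.UNDESIGNATED_STATE: 0.073,
        Zoning.STRICTLY_PROTECTED: 0.100,
        Zoning.INDIGENOUS: 0.181,
        Zoning.MILITARY: 0.014,
    }


@dataclass
class LandscapeSpec:
    """Parameters for one synthetic landscape."""

    n_rows: int = 100
    n_cols: int = 100
    cell_area: float = 100.0  # ha
    mean_forest_volume: float = 16.0  # m3/ha over forest cells
    volume_sill: float = 0.5  # lognormal sigma of the volume field
    correlation_range: float = 5.0  # autocorrelation length, km
    forest_fraction: float = 0.75
    grassland_fraction: float = 0.03
    water_fraction: float = 0.02
    category_fractions: dict[Zoning, float] = field(default_factory=_default_fractions)
    n_centers: int = 3
    capacity_range: tuple[float, float] = (50_000.0, 300_000.0)
    price_range: tuple[float, float] = (80.0, 120.0)  # R$/m3
    harvest_cost_range: tuple[float, float] = (20.0, 40.0)  # R$/m3
    price_floor: float | None = None  # outlier draws below this are replaced by the mean
    road_density: float = 0.0  # extra road segments per 100 grid cells of perimeter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise SpecError("grid must be at least 1x1")
        if self.mean_forest_volume <= 0:
            raise SpecError("mean_forest_volume must be > 0")
        total = sum(self.category_fractions.values())
        if any(f < 0 for f in self.category_fractions.values()) or abs(total - 1.0) > 1e-6:
            raise SpecError(f"category fractions must be >= 0 and sum to 1 (got {total})")
        for name in ("capacity_range", "price_range", "harvest_cost_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SpecError(f"{name} is empty: {(lo, hi)}")
        covers = self.forest_fraction + self.grassland_fraction + self.water_fraction
        if not 0 < self.forest_fraction <= 1 or covers > 1 + 1e-9:
            raise SpecError("land-cover fractions must fit in [0, 1]")
        if self.n_centers < 1:
            raise SpecError("need at least one center")
        if self.n_centers > self.n_rows * self.n_cols // 4:
            raise SpecError("grid too small for the requested number of centers")


def _quotas(fractions: dict[Zoning, float], n_cells: int) -> dict[Zoning, int]:
    """Largest-remainder apportionment of cells to categories."""
    raw = {z: f * n_cells for z, f in fractions.items() if f > 0}
    quotas = {z: int(np.floor(v)) for z, v in raw.items()}
    short = n_cells - sum(quotas.values())
    for z in sorted(raw, key=lambda z: raw[z] - quotas[z], reverse=True)[:short]:
        quotas[z] += 1
    return {z: q for z, q in quotas.items() if q > 0}


_NEIGHBORS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _grow_mosaic(shape: tuple[int, int], quotas: dict[Zoning, int], rng: np.random.Generator) -> np.ndarray:
    """Seeded region growing: each category expands from random seeds until
    its cell quota is met, yielding contiguous patches."""
    n_rows, n_cols = shape
    zon = np.full(shape, -1, dtype=np.int16)
    cats = sorted(quotas, key=int)
    counts = {z: 0 for z in cats}
    frontiers: dict[Zoning, list[tuple[int, int]]] = {z: [] for z in cats}
    unassigned = n_rows * n_cols

    def claim(z: Zoning, r: int, c: int) -> None:
        nonlocal unassigned
        zon[r, c] = int(z)
        counts[z] += 1
        unassigned -= 1
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and zon[rr, cc] < 0:
                frontiers[z].append((rr, cc))

    while unassigned > 0:
        deficits = np.array([quotas[z] - counts[z] for z in cats], dtype=float)
        open_cats = deficits > 0
        if not open_cats.any():  # rounding slack: grow the largest category
            open_cats = np.array([quotas[z] > 0 for z in cats])
        p = np.where(open_cats, np.maximum(deficits, 1.0), 0.0)
        z = cats[rng.choice(len(cats), p=p / p.sum())]
        placed = False
        while frontiers[z]:
            i = rng.integers(len(frontiers[z]))
            r, c = frontiers[z].pop(i)
            if zon[r, c] < 0:
                claim(z, r, c)
                placed = True
                break
        if not placed:  # seed (or re-seed) at a random free cell
            free = np.argwhere(zon < 0)
            r, c = free[rng.integers(len(free))]
            claim(z, int(r), int(c))
    return zon


def _volume_field(spec: LandscapeSpec, rng: np.random.Generator) -> np.ndarray:
    """Non-negative autocorrelated field with unit mean, scaled to the target."""
    sigma_cells = max(spec.correlation_range / np.sqrt(spec.cell_area / 100.0), 0.5)
    z = gaussian_filter(rng.standard_normal((spec.n_rows, spec.n_cols)), sigma=sigma_cells)
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    s = spec.volume_sill
    return spec.mean_forest_volume * np.exp(s * z - s * s / 2.0)


def _land_cover(spec: LandscapeSpec, rng: np.random.Generator) -> np.ndarray:
    """Contiguous cover classes from quantiles of a smoothed noise field."""
    g = gaussian_filter(rng.standard_normal((spec.n_rows, spec.n_cols)), sigma=2.0)
    g = g + rng.standard_normal(g.shape) * 1e-9  # break ties on tiny grids
    cover = np.full(g.shape, int(LandCover.DEFORESTED), dtype=np.int16)
    q_forest = np.quantile(g, 1.0 - spec.forest_fraction)
    cover[g >= q_forest] = int(LandCover.FOREST)
    if spec.water_fraction > 0:
        cover[g < np.quantile(g, spec.water_fraction)] = int(LandCover.NON_NAVIGABLE_WATER)
    if spec.grassland_fraction > 0:
        lo = np.quantile(g, spec.water_fraction)
        hi = np.quantile(g, spec.water_fraction + spec.grassland_fraction)
        cover[(g >= lo) & (g < hi)] = int(LandCover.GRASSLAND)
    return cover


def _place_centers(spec: LandscapeSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    min_sep = max(2.0, min(spec.n_rows, spec.n_cols) / (2.0 * spec.n_centers))
    spots: list[tuple[int, int]] = []
    for _ in range(10_000):
        r = int(rng.integers(spec.n_rows))
        c = int(rng.integers(spec.n_cols))
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_sep**2 for rr, cc in spots):
            spots.append((r, c))
            if len(spots) == spec.n_centers:
                return spots
    raise SpecError("could not place centers with the required separation")


def _road_skeleton(spec: LandscapeSpec, spots: list[tuple[int, int]], rng: np.random.Generator) -> np.ndarray:
    """Unpaved-road raster: a spanning tree over the centers plus optional
    extra random segments controlled by road_density."""
    roads = np.full((spec.n_rows, spec.n_cols), int(RoadClass.NONE), dtype=np.int16)

    def stroke(a: tuple[int, int], b: tuple[int, int]) -> None:
        rr, cc = draw_line(a[0], a[1], b[0], b[1])
        roads[rr, cc] = int(RoadClass.UNPAVED)

    if len(spots) > 1:
        pts = np.array(spots, dtype=float)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        mst = minimum_spanning_tree(d).toarray()
        for i, j in zip(*np.nonzero(mst)):
            stroke(spots[i], spots[j])
    n_extra = int(spec.road_density * (spec.n_rows + spec.n_cols) / 100.0)
    for _ in range(n_extra):
        a = (int(rng.integers(spec.n_rows)), int(rng.integers(spec.n_cols)))
        b = spots[rng.integers(len(spots))]
        stroke(a, b)
    return roads


def generate_landscape(spec: LandscapeSpec) -> tuple[LandscapeGrid, list[LoggingCenter]]:
    """Generate one landscape and its center table from ``spec`` (seeded)."""
    rng = np.random.default_rng(spec.seed)
    zoning = _grow_mosaic((spec.n_rows, spec.n_cols), _quotas(spec.category_fractions, spec.n_rows * spec.n_cols), rng)
    land_cover = _land_cover(spec, rng)
    volume = _volume_field(spec, rng)
    spots = _place_centers(spec, rng)
    roads = _road_skeleton(spec, spots, rng)

    capacities = rng.uniform(*spec.capacity_range, size=spec.n_centers)
    prices = rng.uniform(*spec.price_range, size=spec.n_centers)
    costs = rng.uniform(*spec.harvest_cost_range, size=spec.n_centers)
    if spec.price_floor is not None:
        low = prices < spec.price_floor
        if low.any():  # below-threshold draws are outliers: replace by the mean
            prices[low] = prices.mean()

    centers = [
        LoggingCenter(
            id=k,
            row=spots[k][0],
            col=spots[k][1],
            capacity=float(capacities[k]),
            price=float(prices[k]),
            harvest_cost=float(costs[k]),
        )
        for k in range(spec.n_centers)
    ]
    # center cells host mills, not standing forest
    for c in centers:
        land_cover[c.row, c.col] = int(LandCover.DEFORESTED)
    grid = LandscapeGrid(
        volume=volume,
        land_cover=land_cover,
        zoning=zoning,
        roads=roads,
        cell_area=spec.cell_area,
    )
    return grid, centers


# ---------------------------------------------------------------------------
# Pinned fixtures used by the test suite.

FIXTURES = ("tiny_oracle", "leakage_demo", "two_centers")


def _fixture_tiny_oracle() -> tuple[LandscapeGrid, list[LoggingCenter]]:
    """15x15 grid, one center, mixed friction classes and a barrier patch."""
    rng = np.random.default_rng(20090101)
    n = 15
    volume = rng.uniform(5.0, 45.0, size=(n, n)).round(3)
    land_cover = np.full((n, n), int(LandCover.FOREST), dtype=np.int16)
    land_cover[0, :] = int(LandCover.DEFORESTED)
    land_cover[7, 3:6] = int(LandCover.NON_NAVIGABLE_WATER)
    land_cover[12:14, 10:13] = int(LandCover.GRASSLAND)
    zoning = np.full((n, n), int(Zoning.PRIVATE_NONPROTECTED), dtype=np.int16)
    zoning[2:5, 9:12] = int(Zoning.STRICTLY_PROTECTED)
    zoning[9:12, 1:4] = int(Zoning.SUSTAINABLE_USE_OTHER)
    roads = np.full((n, n), int(RoadClass.NONE), dtype=np.int16)
    roads[7, 6:13] = int(RoadClass.UNPAVED)
    roads[0:8, 6] = int(RoadClass.PAVED)
    roads[14, :] = int(RoadClass.NAVIGABLE_RIVER)
    centers = [LoggingCenter(id=0, row=7, col=7, capacity=80_000.0, price=100.0, harvest_cost=30.0)]
    land_cover[7, 7] = int(LandCover.DEFORESTED)
    grid = LandscapeGrid(volume=volume, land_cover=land_cover, zoning=zoning, roads=roads)
    return grid, centers


def _fixture_leakage_demo() -> tuple[LandscapeGrid, list[LoggingCenter]]:
    """A national-forest block ringed by cheaper-to-access undesignated and
    private land, so unconstrained CL outside draws harvest away from it."""
    n_rows, n_cols = 30, 30
    volume = np.full((n_rows, n_cols), 40.0)
    land_cover = np.full((n_rows, n_cols), int(LandCover.FOREST), dtype=np.int16)
    zoning = np.full((n_rows, n_cols), int(Zoning.PRIVATE_NONPROTECTED), dtype=np.int16)
    zoning[:, 15:23] = int(Zoning.UNDESIGNATED_FEDERAL)
    zoning[:, 23:] = int(Zoning.NATIONAL_FOREST)
    roads = np.full((n_rows, n_cols), int(RoadClass.NONE), dtype=np.int16)
    roads[15, 0:10] = int(RoadClass.UNPAVED)
    centers = [LoggingCenter(id=0, row=15, col=1, capacity=100_000.0, price=100.0, harvest_cost=30.0)]
    land_cover[15, 1] = int(LandCover.DEFORESTED)
    grid = LandscapeGrid(volume=volume, land_cover=land_cover, zoning=zoning, roads=roads)
    return grid, centers


def _fixture_two_centers() -> tuple[LandscapeGrid, list[LoggingCenter]]:
    """20x20 landscape with two well-separated centers."""
    spec = LandscapeSpec(
        n_rows=20,
        n_cols=20,
        n_centers=2,
        seed=7,
        category_fractions={
            Zoning.PRIVATE_NONPROTECTED: 0.5,
            Zoning.UNDESIGNATED_FEDERAL: 0.3,
            Zoning.NATIONAL_FOREST: 0.2,
        },
        mean_forest_volume=25.0,
        forest_fraction=0.9,
        grassland_fraction=0.0,
        water_fraction=0.0,
    )
    grid, centers = generate_landscape(spec)
    assert (centers[0].row - centers[1].row) ** 2 + (centers[0].col - centers[1].col) ** 2 > 4
    return grid, centers


def generate_fixture(name: str) -> tuple[LandscapeGrid, list[LoggingCenter]]:
    """Return a pinned, seed-fixed fixture bundle from the catalogue."""
    builders = {
        "tiny_oracle": _fixture_tiny_oracle,
        "leakage_demo": _fixture_leakage_demo,
        "two_centers": _fixture_two_centers,
    }
    try:
        return builders[name]()
    except KeyError:
        raise CatalogueError(f"unknown fixture {name!r}; catalogue: {FIXTURES}") from None
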