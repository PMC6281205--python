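"""Plain-text I/O for landscapes, center tables, ledgers and configs.

A landscape is stored as a directory of whitespace-delimited raster grids
(one file per layer) plus a ``meta.json`` with grid geometry and the
category legends, and a ``centers.csv`` table.  Everything round-trips
bit-exactly for integer and categorical layers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .landscape import (
    LandCover,
    LandscapeGrid,
    LoggingCenter,
    PlacementError,
    RegistrationError,
    RoadClass,
    SchemaError,
    Zoning,
)
from .ledger import BASELINE_COLUMNS, LEDGER_COLUMNS, AnnualLedger

__all__ = [
    "ParseError",
    "save_landscape",
    "load_landscape",
    "save_centers",
    "load_centers",
    "save_ledger",
    "load_ledger",
]

CENTER_COLUMNS = ("id", "row", "col", "capacity_m3yr", "price_brl_m3", "harvest_cost_brl_m3")

_INT_LAYERS = ("land_cover", "zoning", "roads")
_FLOAT_LAYERS = ("volume", "price", "harvest_cost")
_ALL_LAYERS = _FLOAT_LAYERS[:1] + _INT_LAYERS + _FLOAT_LAYERS[1:]


class ParseError(ValueError):
    """A file on disk is malformed."""


def _legend(enum_cls) -> dict[str, int]:
    return {m.name.lower(): int(m) for m in enum_cls}


def save_landscape(grid: LandscapeGrid, centers: list[LoggingCenter], path) -> Path:
    """Write ``grid`` and ``centers`` under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "cell_area_ha": grid.cell_area,
        "legends": {
            "land_cover": _legend(LandCover),
            "zoning": _legend(Zoning),
            "roads": _legend(RoadClass),
        },
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    for name in _INT_LAYERS:
        np.savetxt(path / f"{name}.txt", getattr(grid, name), fmt="%d")
    for name in _FLOAT_LAYERS:
        np.savetxt(path / f"{name}.txt", getattr(grid, name), fmt="%.10g")
    save_centers(centers, path / "centers.csv")
    return path


def load_landscape(raster_paths, center_table_path=None) -> tuple[LandscapeGrid, list[LoggingCenter]]:
    """Load a landscape from a directory or an explicit layer -> file mapping.

    Rasters must be co-registered (identical shapes); commercial volume is
    zeroed on non-forest cells; centers are validated against the grid.
    """
    if isinstance(raster_paths, (str, Path)):
        root = Path(raster_paths)
        mapping = {name: root / f"{name}.txt" for name in _ALL_LAYERS}
        meta_path = root / "meta.json"
        if center_table_path is None:
            center_table_path = root / "centers.csv"
    else:
        mapping = {k: Path(v) for k, v in dict(raster_paths).items()}
        meta_path = None

    layers: dict[str, np.ndarray] = {}
    for name, p in mapping.items():
        if not Path(p).exists():
            if name in ("price", "harvest_cost"):
                continue  # optional layers
            raise ParseError(f"missing raster file for layer {name!r}: {p}")
        try:
            arr = np.loadtxt(p, ndmin=2)
        except ValueError as exc:
            raise ParseError(f"could not parse raster {p}: {exc}") from exc
        layers[name] = arr

    shapes = {name: a.shape for name, a in layers.items()}
    if len(set(shapes.values())) > 1:
        raise RegistrationError(f"raster layers are misregistered: {shapes}")

    cell_area = 100.0
    if meta_path is not None and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        cell_area = float(meta.get("cell_area_ha", 100.0))

    grid = LandscapeGrid(
        volume=layers["volume"],
        land_cover=layers["land_cover"],
        zoning=layers["zoning"],
        roads=layers["roads"],
        price=layers.get("price"),
        harvest_cost=layers.get("harvest_cost"),
        cell_area=cell_area,
    )
    centers: list[LoggingCenter] = []
    if center_table_path is not None and Path(center_table_path).exists():
        centers = load_centers(center_table_path)
        for c in centers:
            c.check_on_grid(grid.shape)
    return grid, centers


def save_centers(centers: list[LoggingCenter], path) -> None:
    df = pd.DataFrame(
        {
            "id": [c.id for c in centers],
            "row": [c.row for c in centers],
            "col": [c.col for c in centers],
            "capacity_m3yr": [c.capacity for c in centers],
            "price_brl_m3": [c.price for c in centers],
            "harvest_cost_brl_m3": [c.harvest_cost for c in centers],
            "active": [int(c.active) for c in centers],
        }
    )
    df.to_csv(path, index=False)


def load_centers(path) -> list[LoggingCenter]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"could not parse center table {path}: {exc}") from exc
    missing = [c for c in CENTER_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"center table {path} missing columns {missing}")
    centers = []
    for rec in df.to_dict("records"):
        centers.append(
            LoggingCenter(
                id=int(rec["id"]),
                row=int(rec["row"]),
                col=int(rec["col"]),
                capacity=float(rec["capacity_m3yr"]),
                price=float(rec["price_brl_m3"]),
                harvest_cost=float(rec["harvest_cost_brl_m3"]),
                active=bool(int(rec.get("active", 1))),
            )
        )
    return centers


def save_ledger(ledger: AnnualLedger, path) -> None:
    """Write ledger records as CSV; the baseline table goes to a sidecar.

    ``<path>`` holds the per-year records; ``<path stem>.baseline.csv`` holds
    the per-category baseline stock/area.  End-state rasters are not saved.
    """
    path = Path(path)
    df = ledger.records.loc[:, list(LEDGER_COLUMNS)].copy()
    df.insert(0, "scenario", ledger.scenario)
    df.to_csv(path, index=False)
    ledger.baseline.loc[:, list(BASELINE_COLUMNS)].to_csv(
        path.with_suffix(".baseline.csv"), index=False
    )


def load_ledger(path) -> AnnualLedger:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"could not parse ledger {path}: {exc}") from exc
    missing = [c for c in LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"ledger {path} missing columns {missing}")
    scenario = ""
    if "scenario" in df.columns and len(df):
        scenario = str(df["scenario"].iloc[0])
    records = df.loc[:, list(LEDGER_COLUMNS)].astype(
        {"year": int, "center": int, "category": str, "mode": str,
         "volume_m3": float, "area_ha": float, "rent_brl": float}
    )
    baseline_path = path.with_suffix(".baseline.csv")
    if baseline_path.exists():
        baseline = pd.read_csv(baseline_path)
        missing = [c for c in BASELINE_COLUMNS if c not in baseline.columns]
        if missing:
            raise ParseError(f"baseline table {baseline_path} missing columns {missing}")
        baseline = baseline.loc[:, list(BASELINE_COLUMNS)].astype(
            {"category": str, "stock_m3": float, "area_ha": float}
        )
    else:
        baseline = AnnualLedger().baseline
    return AnnualLedger(records=records, baseline=baseline, scenario=scenario)
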