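"""Per-year, per-center, per-land-category harvest accounting."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LEDGER_COLUMNS", "BASELINE_COLUMNS", "AnnualLedger"]

LEDGER_COLUMNS = ("year", "center", "category", "mode", "volume_m3", "area_ha", "rent_brl")
BASELINE_COLUMNS = ("category", "stock_m3", "area_ha")


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": pd.Series(dtype=int),
            "center": pd.Series(dtype=int),
            "category": pd.Series(dtype=str),
            "mode": pd.Series(dtype=str),
            "volume_m3": pd.Series(dtype=float),
            "area_ha": pd.Series(dtype=float),
            "rent_brl": pd.Series(dtype=float),
        }
    )


def _empty_baseline() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": pd.Series(dtype=str),
            "stock_m3": pd.Series(dtype=float),
            "area_ha": pd.Series(dtype=float),
        }
    )


@dataclass
class AnnualLedger:
    """Harvest records for one scenario run.

    ``records`` holds one row per (year, center, land category) with the
    volume removed (m3), the area logged for the first time that year (ha)
    and the net rent earned (R$).  ``baseline`` holds the initial commercial
    stock (m3) and total area (ha) per land category.  ``rasters`` carries
    end-state arrays (remaining volume, cumulative logged mask, roads) and is
    not part of equality or serialization.
    """

    records: pd.DataFrame = field(default_factory=_empty_records)
    baseline: pd.DataFrame = field(default_factory=_empty_baseline)
    scenario: str = ""
    rasters: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in LEDGER_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"ledger records missing columns {missing}")
        missing = [c for c in BASELINE_COLUMNS if c not in self.baseline.columns]
        if missing:
            raise ValueError(f"ledger baseline missing columns {missing}")
        for col in ("volume_m3", "area_ha", "rent_brl"):
            if len(self.records) and (self.records[col] < -1e-9).any():
                raise ValueError(f"ledger column {col} has negative entries")

    def __eq__(self, other: object) -> bool:  # rasters deliberately excluded
        if not isinstance(other, AnnualLedger):
            return NotImplemented
        return (
            self.scenario == other.scenario
            and self.records.reset_index(drop=True).equals(other.records.reset_index(drop=True))
            and self.baseline.reset_index(drop=True).equals(other.baseline.reset_index(drop=True))
        )

    def total(self, column: str) -> float:
        return float(self.records[column].sum()) if len(self.records) else 0.0

    def by_category(self, column: str) -> pd.Series:
        """Sum of ``column`` per land category over all years and centers."""
        if not len(self.records):
            return pd.Series(dtype=float)
        return self.records.groupby("category")[column].sum()

    def by_year(self, column: str) -> pd.Series:
        if not len(self.records):
            return pd.Series(dtype=float)
        return self.records.groupby("year")[column].sum()
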