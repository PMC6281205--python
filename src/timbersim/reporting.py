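"""Per-category summary tables, currency conversion, and scenario comparison.

Internally everything is kept at full precision; the half-up rounding
helpers are applied only at presentation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .ledger import AnnualLedger

__all__ = [
    "METRICS",
    "TOTAL",
    "SummaryTable",
    "ScenarioComparison",
    "summarize",
    "compare_scenarios",
    "fraction_of_baseline",
    "round_half_up",
    "round_sig",
]

#: Harvest metrics carried by a summary table (plus the two baseline columns).
METRICS = ("volume_mm3", "area_mha", "profit_musd")
BASELINES = ("baseline_stock_mm3", "baseline_area_mha")
TOTAL = "total"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals (presentation only)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half up."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round_half_up(x, ndigits=sig - 1 - exponent)


@dataclass
class SummaryTable:
    """Per land category (+ grand total row): baseline stock (Mm3), baseline
    area (Mha), harvested volume (Mm3), logged area (Mha), net profit (MUSD)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in BASELINES + METRICS:
            if col not in self.data.columns:
                raise ValueError(f"summary table missing column {col}")
        if (self.data[list(BASELINES + METRICS)] < -1e-9).any().any():
            raise ValueError("summary table has negative entries")

    @classmethod
    def from_totals(cls, rows: dict[str, dict[str, float]]) -> "SummaryTable":
        """Build directly from per-category totals, e.g. published values."""
        return cls(pd.DataFrame.from_dict(rows, orient="index"))

    def value(self, category: str, column: str) -> float:
        return float(self.data.loc[category, column])

    @property
    def categories(self) -> list[str]:
        return [c for c in self.data.index if c != TOTAL]


def summarize(ledger: AnnualLedger, exchange_rate: float) -> SummaryTable:
    """Aggregate a ledger over years and centers into per-category totals.

    Volumes in million m3, areas in million ha, profits in million USD
    converted at ``exchange_rate`` BRL per USD.
    """
    if exchange_rate <= 0:
        raise ValueError("exchange_rate must be > 0")
    base = ledger.baseline.set_index("category")
    vol = ledger.by_category("volume_m3")
    area = ledger.by_category("area_ha")
    rent = ledger.by_category("rent_brl")
    rows: dict[str, dict[str, float]] = {}
    for cat in base.index:
        rows[cat] = {
            "baseline_stock_mm3": base.loc[cat, "stock_m3"] / 1e6,
            "baseline_area_mha": base.loc[cat, "area_ha"] / 1e6,
            "volume_mm3": float(vol.get(cat, 0.0)) / 1e6,
            "area_mha": float(area.get(cat, 0.0)) / 1e6,
            "profit_musd": float(rent.get(cat, 0.0)) / exchange_rate / 1e6,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc[TOTAL] = df.sum()
    return SummaryTable(df)


@dataclass
class ScenarioComparison:
    """Differences and percent changes of one scenario table vs another."""

    diff: pd.DataFrame  # second - first, per category x metric
    pct_change: pd.DataFrame  # (second - first) / first x 100; NaN where first = 0
    first: SummaryTable
    second: SummaryTable

    def pct(self, category: str, metric: str, ndigits: int = 1) -> float:
        """Percent change, rounded half-up for presentation."""
        return round_half_up(float(self.pct_change.loc[category, metric]), ndigits)

    def decrease_pct(self, category: str, metric: str, ndigits: int = 0) -> float:
        """Percent decrease (first - second)/first x 100, presentation-rounded."""
        return round_half_up(-float(self.pct_change.loc[category, metric]), ndigits)

    def profit_loss_busd(self, category: str, sig: int = 2) -> float:
        """Foregone profit first - second, in billion USD at ``sig`` figures."""
        loss = (
            self.first.value(category, "profit_musd")
            - self.second.value(category, "profit_musd")
        ) / 1e3
        return round_sig(loss, sig)


def compare_scenarios(table_first: SummaryTable, table_second: SummaryTable) -> ScenarioComparison:
    """Compare two summary tables sharing category sets and baselines."""
    a, b = table_first.data, table_second.data
    if set(a.index) != set(b.index):
        raise ValueError("summary tables have mismatched categories")
    b = b.loc[a.index]
    for col in BASELINES:
        if not np.allclose(a[col], b[col], rtol=1e-9, atol=1e-9):
            raise ValueError(f"summary tables disagree on {col}")
    metrics = list(METRICS)
    diff = b[metrics] - a[metrics]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = diff / a[metrics].replace(0.0, np.nan) * 100.0
    return ScenarioComparison(diff=diff, pct_change=pct, first=table_first, second=table_second)


def fraction_of_baseline(table: SummaryTable, category: str, metric: str) -> float:
    """Harvested metric as a percent of the category baseline (full precision).

    ``metric`` is ``"volume"`` (vs baseline stock) or ``"area"`` (vs baseline
    area).  Raises on a zero baseline.
    """
    pairs = {"volume": ("volume_mm3", "baseline_stock_mm3"), "area": ("area_mha", "baseline_area_mha")}
    if metric not in pairs:
        raise ValueError(f"metric must be one of {sorted(pairs)}")
    num_col, den_col = pairs[metric]
    den = table.value(category, den_col)
    if den <= 0:
        raise ValueError(f"category {category!r} has zero baseline {den_col}")
    return table.value(category, num_col) / den * 100.0
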