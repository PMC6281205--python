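"""Published 30-year scenario summaries used as worked-example inputs.

These per-category totals (baseline commercial stock in million m3, baseline
area in million ha, harvested volume in million m3, logged area in million
ha, and net profit in million USD at the 2009 exchange rate of R$ 1.995 per
USD) are the reference inputs for the reporting module's scenario-comparison
arithmetic.  They describe a full Amazon-scale run and are data, not
computed here.
"""

from __future__ import annotations

from .reporting import SummaryTable

__all__ = ["EXCHANGE_RATE_BRL_PER_USD", "reference_legal", "reference_illegal"]

EXCHANGE_RATE_BRL_PER_USD = 1.995

_BASELINE = {
    # category: (baseline stock Mm3, baseline area Mha)
    "national_forest": (223.0, 14.5),
    "undesignated_federal": (428.0, 39.7),
    "undesignated_state": (586.0, 37.5),
    "private_nonprotected": (792.0, 215.0),
    "sustainable_use_other": (871.0, 56.6),
    "total": (4835.0, 516.0),
}

_LEGAL = {
    # category: (volume Mm3, area Mha, profit MUSD)
    "national_forest": (92.8, 5.4, 2859.0),
    "undesignated_federal": (227.0, 15.6, 9044.0),
    "undesignated_state": (182.0, 9.4, 6134.0),
    "private_nonprotected": (412.0, 36.1, 16911.0),
    "sustainable_use_other": (336.0, 18.1, 10168.0),
    "total": (1250.0, 84.6, 45116.0),
}

_ILLEGAL = {
    "national_forest": (39.5, 2.2, 1579.0),
    "undesignated_federal": (295.0, 20.2, 12478.0),
    "undesignated_state": (233.0, 14.1, 9841.0),
    "private_nonprotected": (550.0, 45.9, 23314.0),
    "sustainable_use_other": (204.0, 8.7, 6382.0),
    "total": (1321.0, 91.1, 53594.0),
}


def _table(harvest: dict[str, tuple[float, float, float]]) -> SummaryTable:
    rows = {}
    for cat, (stock, area) in _BASELINE.items():
        vol, logged, profit = harvest[cat]
        rows[cat] = {
            "baseline_stock_mm3": stock,
            "baseline_area_mha": area,
            "volume_mm3": vol,
            "area_mha": logged,
            "profit_musd": profit,
        }
    return SummaryTable.from_totals(rows)


def reference_legal() -> SummaryTable:
    return _table(_LEGAL)


def reference_illegal() -> SummaryTable:
    return _table(_ILLEGAL)
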