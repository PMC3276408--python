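"""Production-approach outputs: cumulative disposition, stock change, peaks.

The report table mirrors the standard published layout: cumulative
emissions with and without energy capture, products in use, carbon at
solid waste disposal sites, the total HWP stock (in use + SWDS) and the
annual net stock change.  Internal values stay double precision; rounding
to whole MgC happens only at serialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fate import PoolLedger

#: Mass ratio of CO2 to C.
CO2_PER_C = 44.0 / 12.0


def mgc_to_mgco2(mgc: float) -> float:
    """Convert a carbon mass (MgC) to carbon dioxide mass (MgCO2)."""
    return mgc * CO2_PER_C


@dataclass
class StockFluxReport:
    """Cumulative disposition and annual stock change per inventory year."""

    table: pd.DataFrame

    def selected_years(self, years) -> pd.DataFrame:
        return self.table.loc[[y for y in years if y in self.table.index]]

    def to_csv(self, path, round_mgc: bool = True) -> None:
        out = self.table.round(0).astype("int64") if round_mgc else self.table
        out.rename_axis("inventory_year").to_csv(path)


def build_report(ledger: PoolLedger) -> StockFluxReport:
    """Assemble the stock/flux report from a pool ledger.

    ``total_hwp`` is exactly ``products_in_use + swds``; the first year's
    stock change is taken against an implicit zero stock the year before.
    """
    t = ledger.table
    report = pd.DataFrame(index=t.index.copy())
    report["emitted_energy_cum"] = t["emitted_energy_cum"]
    report["emitted_no_energy_cum"] = t["emitted_no_energy_cum"]
    report["products_in_use"] = t["in_use"]
    report["swds"] = t["swds"]
    report["total_hwp"] = report["products_in_use"] + report["swds"]
    report["stock_change"] = report["total_hwp"].diff()
    report.iloc[0, report.columns.get_loc("stock_change")] = report["total_hwp"].iloc[0]
    return StockFluxReport(table=report)


def assemble_total(products_in_use: float, swds: float) -> float:
    """The report's defining identity: total HWP stock = in use + SWDS."""
    return products_in_use + swds


def find_peak_and_sign_change(
    report: StockFluxReport,
) -> tuple[int, float, int | None]:
    """(peak year, peak total stock, first year of negative stock change
    after the peak; ``None`` if the stock never declines)."""
    totals = report.table["total_hwp"]
    if totals.empty:
        raise ValueError("empty report")
    peak_year = int(totals.idxmax())  # idxmax takes the earliest tie
    peak_total = float(totals.loc[peak_year])
    after = report.table.loc[report.table.index > peak_year, "stock_change"]
    neg = after[after < 0]
    first_negative = int(neg.index[0]) if len(neg) else None
    return peak_year, peak_total, first_negative


def vintage_attribution(
    ledger: PoolLedger, cutoff_year: int, inventory_year: int
) -> tuple[float, float]:
    """Remaining stock from pre-cutoff vintages at an inventory year.

    Returns (MgC remaining in use + SWDS from vintages before
    ``cutoff_year``, share of the total HWP stock in ``inventory_year``).
    """
    if cutoff_year > inventory_year:
        raise ValueError("cutoff year must not exceed inventory year")
    iu = ledger.in_use_by_vintage.loc[inventory_year]
    sw = ledger.swds_by_vintage.loc[inventory_year]
    pre = [v for v in iu.index if v < cutoff_year]
    remaining = float(iu[pre].sum() + sw[pre].sum())
    total = float(iu.sum() + sw.sum())
    share = remaining / total if total > 0 else 0.0
    return remaining, share


def vintage_share_percent(pre_cutoff_stock: float, total_stock: float) -> float:
    """Pre-cutoff share of the total stock, in percent."""
    if total_stock <= 0:
        raise ValueError("total stock must be positive")
    return 100.0 * pre_cutoff_stock / total_stock
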