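"""100-year-average carbon storage (forest-offset-protocol metric).

For each harvest year, the metric is the average carbon stored over the
century following harvest, split into products in use and products in
landfill, computed by applying per-primary-product storage factors to that
single year's HWP carbon.  By default the input carbon comes from the
production pipeline's conversion chain (the same HWP pool as the stock
accounting); the protocol's own mill-efficiency conversion is offered as
a standalone alternative input path.

Because the protocol's published storage-factor tables are not reproduced
in the regional study, the shipped defaults are fixture values; use
:func:`derive_storage_factors` to generate factors that are exactly
self-consistent with this package's cohort fate model.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .conversion import EndUseAllocation, PrimaryProductAllocation, primary_to_end_use
from .fate import PoolLedger, simulate
from .parameters import CFPPParameters, ParameterError, ParameterSet


@dataclass
class HundredYearAverage:
    """Per-harvest-year 100-year average storage (MgC).

    Columns: products_in_use_avg, landfill_avg, total_avg.  Each row
    depends only on that single harvest year's carbon.
    """

    table: pd.DataFrame

    def to_csv(self, path, round_mgc: bool = True) -> None:
        out = self.table.round(0).astype("int64") if round_mgc else self.table
        out.rename_axis("harvest_year").to_csv(path)


def mill_efficiency_pathway(
    delivered_carbon: float, wood_type: str, params: CFPPParameters
) -> float:
    """Carbon entering HWP out of carbon delivered to mills.

    The balance (1 - efficiency) is an immediate emission.  This is the
    protocol's standalone input path; the default route instead reuses the
    production pipeline's conversion chain.
    """
    if delivered_carbon < 0:
        raise ParameterError(f"negative delivered carbon {delivered_carbon}")
    try:
        eff = params.mill_efficiency[wood_type]
    except KeyError:
        raise ParameterError(f"unknown wood type {wood_type!r}") from None
    return delivered_carbon * eff


def hundred_year_average(
    alloc: PrimaryProductAllocation,
    params: ParameterSet,
    years: list[int] | None = None,
    storage_factor_scale: float = 1.0,
) -> HundredYearAverage:
    """Apply 100-year storage factors to each harvest year's HWP carbon.

    ``storage_factor_scale`` is the uncertainty-engine hook (the decay
    variable acts on storage factors in this route).
    """
    cf = params.cfpp
    idx = alloc.data.index if years is None else [y for y in years if y in alloc.data.index]
    rows = []
    for year in idx:
        iu = 0.0
        lf = 0.0
        for prod in alloc.data.columns:
            mass = float(alloc.data.at[year, prod])
            if prod not in cf.storage_factor_in_use or prod not in cf.storage_factor_landfill:
                raise ParameterError(f"no storage factors for primary product {prod!r}")
            iu += mass * min(1.0, cf.storage_factor_in_use[prod] * storage_factor_scale)
            lf += mass * min(1.0, cf.storage_factor_landfill[prod] * storage_factor_scale)
        rows.append({"products_in_use_avg": iu, "landfill_avg": lf, "total_avg": iu + lf})
    return HundredYearAverage(table=pd.DataFrame(rows, index=pd.Index(idx, name="harvest_year")))


def simulated_century_mean(
    ledger: PoolLedger, horizon: int = 100
) -> tuple[float, float]:
    """Century means of (in-use, landfill) pools of a single-vintage ledger.

    Averages years 0..horizon-1 since the (single) vintage.  Serves as the
    independent cross-check for storage-factor arithmetic.
    """
    t = ledger.table
    if len(t) < horizon:
        raise ValueError(f"ledger spans {len(t)} years, need >= {horizon}")
    window = t.iloc[:horizon]
    in_use_mean = float(window["in_use"].mean())
    landfill_mean = float(
        (window["landfill_fixed"] + window["landfill_decaying"]).mean()
    )
    return in_use_mean, landfill_mean


def derive_storage_factors(
    params: ParameterSet, vintage_year: int = 2000, horizon: int = 100
) -> CFPPParameters:
    """Storage factors self-consistent with the cohort fate model.

    For each primary product, a unit cohort (1 MgC) harvested in
    ``vintage_year`` is run through the fate model for ``horizon`` years;
    the century means of its in-use and landfill pools are that product's
    storage factors.  Fuelwood gets zero (instant emission).
    """
    in_use_f: dict[str, float] = {}
    landfill_f: dict[str, float] = {}
    for prod, material in params.flows.material_by_primary.items():
        if material == "fuelwood":
            in_use_f[prod] = 0.0
            landfill_f[prod] = 0.0
            continue
        unit = PrimaryProductAllocation(
            data=pd.DataFrame({prod: [1.0]}, index=[vintage_year]),
            material_by_primary=dict(params.flows.material_by_primary),
        )
        end_use = primary_to_end_use(unit, params)
        ledger = simulate(end_use, params, end_year=vintage_year + horizon - 1)
        iu, lf = simulated_century_mean(ledger, horizon=horizon)
        in_use_f[prod] = iu
        landfill_f[prod] = lf
    return CFPPParameters(
        mill_efficiency=dict(params.cfpp.mill_efficiency),
        storage_factor_in_use=in_use_f,
        storage_factor_landfill=landfill_f,
    )
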