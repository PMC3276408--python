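"""Carbon flow from timber product classes to primary products to end uses.

All allocations are linear (row-stochastic tables applied to carbon mass),
so mass is conserved at every stage.  The direct MgC-per-ccf factors are
the operative conversion path; the density chain
``ccf x 100 ft^3 x density (lbs/ft^3) / 2204.6 (lbs/Mg) x fiber fraction x 0.5``
is retained as an independent cross-check route only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harvest import HarvestSeries
from .parameters import ConversionFactors, ParameterError, ParameterSet


@dataclass
class PrimaryProductAllocation:
    """Carbon (MgC) per (year, primary product class), with material class."""

    data: pd.DataFrame  # year-indexed, one column per primary product
    material_by_primary: dict[str, str]

    def total(self) -> pd.Series:
        return self.data.sum(axis=1)

    def to_long_csv(self, path) -> None:
        long = self.data.rename_axis("year").reset_index().melt(
            id_vars="year", var_name="primary_product", value_name="mgc"
        )
        long.to_csv(path, index=False)


@dataclass
class EndUseAllocation:
    """Initial end-use cohorts per vintage year.

    ``cohorts`` has columns vintage, end_use, material, half_life, carbon
    (N0, MgC, before placement loss); ``fuelwood`` is the per-vintage MgC
    routed to immediate emission with energy capture.
    """

    cohorts: pd.DataFrame
    fuelwood: pd.Series

    def total_by_vintage(self) -> pd.Series:
        by_v = self.cohorts.groupby("vintage")["carbon"].sum()
        return by_v.add(self.fuelwood, fill_value=0.0)


def volume_to_carbon(volume: float, primary_product: str, cf: ConversionFactors) -> float:
    """Convert a primary-product volume (ccf) to carbon mass (MgC)."""
    if volume < 0:
        raise ParameterError(f"negative volume {volume}")
    try:
        factor = cf.carbon_per_ccf_by_primary_product[primary_product]
    except KeyError:
        raise ParameterError(
            f"no MgC/ccf factor for primary product {primary_product!r}"
        ) from None
    return float(volume) * factor


def volume_to_carbon_density_route(
    volume: float, primary_product: str, cf: ConversionFactors
) -> float:
    """Density-chain cross-check of :func:`volume_to_carbon` (MgC)."""
    density = cf.primary_density_by_product[primary_product]
    fiber = cf.fiber_fraction_by_product[primary_product]
    return float(volume) * 100.0 * density / cf.lbs_per_mg * fiber * cf.carbon_fraction


def timber_to_primary(
    series: HarvestSeries,
    params: ParameterSet,
    ratio_scale_by_year: dict[tuple[str, str], pd.Series] | None = None,
) -> PrimaryProductAllocation:
    """Allocate timber-class carbon to primary product classes.

    ``ratio_scale_by_year`` optionally maps (timber_class, primary_product)
    to a per-year multiplier; the targeted ratio entry is multiplied and the
    row renormalised (uncertainty-engine hook).
    """
    ratios = params.flows.timber_to_primary_ratios
    for cls in series.data.columns:
        if cls not in ratios:
            raise ParameterError(f"timber class {cls!r} has no primary-product ratios")
    primaries = sorted({p for row in ratios.values() for p in row})
    p_idx = {p: i for i, p in enumerate(primaries)}
    years = series.data.index.to_numpy()
    masses = series.data.to_numpy()
    base = np.zeros((len(series.data.columns), len(primaries)))
    for ci, cls in enumerate(series.data.columns):
        for prod, frac in ratios[cls].items():
            base[ci, p_idx[prod]] = frac
    result = masses @ base
    if ratio_scale_by_year:
        scaled_classes = {tcls for tcls, _ in ratio_scale_by_year}
        for cls in scaled_classes:
            if cls not in series.data.columns:
                continue
            ci = list(series.data.columns).index(cls)
            rows = np.tile(base[ci], (len(years), 1))
            for (tcls, prod), mults in ratio_scale_by_year.items():
                if tcls == cls and prod in p_idx:
                    m = mults.reindex(years).fillna(1.0).to_numpy()
                    rows[:, p_idx[prod]] *= m
            rows /= rows.sum(axis=1, keepdims=True)
            result += masses[:, [ci]] * (rows - base[ci])
    out = pd.DataFrame(result, index=series.data.index, columns=primaries)
    return PrimaryProductAllocation(
        data=out, material_by_primary=dict(params.flows.material_by_primary)
    )


def _rescale_row(row: dict[str, float], target: str, mult: float) -> dict[str, float]:
    if mult == 1.0 or row.get(target, 0.0) == 0.0:
        return row
    scaled = dict(row)
    scaled[target] = row[target] * mult
    norm = sum(scaled.values())
    return {k: v / norm for k, v in scaled.items()}


def primary_to_end_use(
    alloc: PrimaryProductAllocation,
    params: ParameterSet,
    end_use_scale: dict[tuple[str, str], float] | None = None,
    half_life_scale: float = 1.0,
) -> EndUseAllocation:
    """Distribute primary-product carbon to end-use cohorts per vintage.

    Fuelwood carbon never enters an end use: it is returned separately for
    immediate emission with energy capture.  The end-use distribution row is
    the one for the vintage clamped to the table's year domain.
    ``end_use_scale`` maps (primary_product, end_use) to a multiplier
    (row renormalised); ``half_life_scale`` scales every end-use half-life.
    """
    flows = params.flows
    rows = []
    fuelwood = pd.Series(0.0, index=alloc.data.index)
    values = alloc.data.to_numpy()
    row_cache: dict[tuple[str, int], dict[str, float]] = {}
    lo, hi = flows.end_use_year_range
    for yi, year in enumerate(alloc.data.index):
        for pi, prod in enumerate(alloc.data.columns):
            mass = float(values[yi, pi])
            if mass == 0.0:
                continue
            material = alloc.material_by_primary[prod]
            if material == "fuelwood":
                fuelwood[year] += mass
                continue
            clamped = min(max(int(year), lo), hi)
            key = (prod, clamped)
            row = row_cache.get(key)
            if row is None:
                row = flows.end_use_row(prod, clamped)
                if end_use_scale:
                    for (p, eu), mult in end_use_scale.items():
                        if p == prod and eu in row:
                            row = _rescale_row(row, eu, mult)
                row_cache[key] = row
            for end_use, frac in row.items():
                if frac == 0.0:
                    continue
                rows.append(
                    {
                        "vintage": int(year),
                        "end_use": end_use,
                        "material": material,
                        "half_life": flows.end_use_half_lives[end_use] * half_life_scale,
                        "carbon": mass * frac,
                    }
                )
    cohorts = pd.DataFrame(
        rows, columns=["vintage", "end_use", "material", "half_life", "carbon"]
    )
    return EndUseAllocation(cohorts=cohorts, fuelwood=fuelwood)
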