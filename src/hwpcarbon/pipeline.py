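"""End-to-end orchestration: records -> pools -> reports, with perturbation.

This is the single place that knows how each named uncertainty multiplier
maps onto the deterministic chain: per-year scalings of reported harvest,
unit conversion and carbon conversion; multiply-then-renormalise scalings
of allocation rows; scalings of half-lives, the landfill discard
fraction, the landfill fixed ("decay limit") fractions and the landfill
half-life.  Running with an empty draw dict reproduces the deterministic
analysis exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cfpp import HundredYearAverage, hundred_year_average
from .conversion import (
    EndUseAllocation,
    PrimaryProductAllocation,
    primary_to_end_use,
    timber_to_primary,
)
from .fate import PoolLedger, simulate
from .harvest import DEFAULT_BOUNDARY_POLICY, BoundaryPolicy, HarvestSeries, build_series
from .parameters import ParameterSet
from .reporting import StockFluxReport, build_report

_ALL_YEARS = range(1906, 2011)


def _year_scale(draws: dict[str, float], prefix_spans: list[tuple[str, int, int]]) -> pd.Series | None:
    """Combine period-scoped multipliers into a per-year scale series."""
    if not any(name in draws for name, _, _ in prefix_spans):
        return None
    s = pd.Series(1.0, index=list(_ALL_YEARS))
    for name, lo, hi in prefix_spans:
        if name in draws:
            s.loc[lo:hi] *= float(draws[name])
    return s


def perturbed_parameters(params: ParameterSet, draws: dict[str, float]) -> ParameterSet:
    """Apply the decay-side multipliers to a copy of the parameter set."""
    if not draws:
        return params
    p = params.copy()
    if "product_half_life" in draws:
        m = float(draws["product_half_life"])
        p.flows.end_use_half_lives = {
            k: v * m for k, v in p.flows.end_use_half_lives.items()
        }
    if "discards_to_landfill" in draws:
        m = float(draws["discards_to_landfill"])
        for material, anchors in p.disposition.anchors.items():
            for year, row in anchors.items():
                scaled = dict(row)
                scaled["landfill"] = row.get("landfill", 0.0) * m
                norm = sum(scaled.values())
                anchors[year] = {k: v / norm for k, v in scaled.items()}
    if "landfill_decay_limits" in draws:
        m = float(draws["landfill_decay_limits"])
        p.swds.landfill_fixed_fraction = {
            k: min(1.0, v * m) for k, v in p.swds.landfill_fixed_fraction.items()
        }
    if "landfill_half_life" in draws:
        m = float(draws["landfill_half_life"])
        p.swds.landfill_half_life = {
            k: v * m for k, v in p.swds.landfill_half_life.items()
        }
    return p


@dataclass
class ProductionRun:
    """All intermediate products of one stock-accounting run."""

    series: HarvestSeries
    primary: PrimaryProductAllocation
    end_use: EndUseAllocation
    ledger: PoolLedger
    report: StockFluxReport


def run_production(
    records: pd.DataFrame,
    params: ParameterSet,
    end_year: int = 2010,
    draws: dict[str, float] | None = None,
    policy: BoundaryPolicy = DEFAULT_BOUNDARY_POLICY,
) -> ProductionRun:
    """Full production-approach chain from raw records to the report."""
    draws = draws or {}
    p = perturbed_parameters(params, draws)

    series = build_series(
        records,
        p,
        policy=policy,
        carbon_scale_by_year=_year_scale(draws, [("ccf_mgc", 1906, 2009)]),
        mbf_ccf_scale_by_year=_year_scale(
            draws,
            [("mbf_ccf_1906_1979", 1906, 1979), ("mbf_ccf_1980_2009", 1980, 2009)],
        ),
        harvest_scale_by_year=_year_scale(
            draws,
            [
                ("harvest_1906_1945", 1906, 1945),
                ("harvest_1946_1979", 1946, 1979),
                ("harvest_1980_2009", 1980, 2009),
            ],
        ),
        sawtimber_share_scale_by_year=_year_scale(
            draws,
            [
                ("roundwood_to_sawtimber_1906_1979", 1906, 1979),
                ("roundwood_to_sawtimber_1980_2009", 1980, 2009),
            ],
        ),
    )

    ratio_scale: dict[tuple[str, str], pd.Series] = {}
    lumber_scale = _year_scale(
        draws,
        [
            ("sawtimber_to_lumber_1906_1949", 1906, 1949),
            ("sawtimber_to_lumber_1950_1979", 1950, 1979),
            ("sawtimber_to_lumber_1980_2009", 1980, 2009),
        ],
    )
    if lumber_scale is not None:
        ratio_scale[("sawtimber_sw", "softwood_lumber")] = lumber_scale
    pulp_scale = _year_scale(draws, [("residues_to_pulp", 1906, 2009)])
    if pulp_scale is not None:
        ratio_scale[("sawtimber_sw", "wood_pulp")] = pulp_scale

    primary = timber_to_primary(series, p, ratio_scale_by_year=ratio_scale or None)

    end_use_scale: dict[tuple[str, str], float] = {}
    if "lumber_to_new_housing" in draws:
        end_use_scale[("softwood_lumber", "new_housing")] = float(
            draws["lumber_to_new_housing"]
        )
    if "panels_to_new_housing" in draws:
        end_use_scale[("softwood_plywood", "new_housing")] = float(
            draws["panels_to_new_housing"]
        )
    end_use = primary_to_end_use(primary, p, end_use_scale=end_use_scale or None)

    ledger = simulate(end_use, p, end_year=end_year)
    report = build_report(ledger)
    return ProductionRun(
        series=series, primary=primary, end_use=end_use, ledger=ledger, report=report
    )


def run_cfpp(
    records: pd.DataFrame,
    params: ParameterSet,
    years: list[int] | None = None,
    draws: dict[str, float] | None = None,
    policy: BoundaryPolicy = DEFAULT_BOUNDARY_POLICY,
) -> HundredYearAverage:
    """100-year-average chain: same HWP carbon pool, storage factors on top.

    The decay variable scales the storage factors here; the three
    landfill variables have no effect on this route by construction.
    """
    draws = draws or {}
    p = perturbed_parameters(params, draws)
    series = build_series(
        records,
        p,
        policy=policy,
        carbon_scale_by_year=_year_scale(draws, [("ccf_mgc", 1906, 2009)]),
        mbf_ccf_scale_by_year=_year_scale(
            draws,
            [("mbf_ccf_1906_1979", 1906, 1979), ("mbf_ccf_1980_2009", 1980, 2009)],
        ),
        harvest_scale_by_year=_year_scale(
            draws,
            [
                ("harvest_1906_1945", 1906, 1945),
                ("harvest_1946_1979", 1946, 1979),
                ("harvest_1980_2009", 1980, 2009),
            ],
        ),
        sawtimber_share_scale_by_year=_year_scale(
            draws,
            [
                ("roundwood_to_sawtimber_1906_1979", 1906, 1979),
                ("roundwood_to_sawtimber_1980_2009", 1980, 2009),
            ],
        ),
    )
    ratio_scale: dict[tuple[str, str], pd.Series] = {}
    lumber_scale = _year_scale(
        draws,
        [
            ("sawtimber_to_lumber_1906_1949", 1906, 1949),
            ("sawtimber_to_lumber_1950_1979", 1950, 1979),
            ("sawtimber_to_lumber_1980_2009", 1980, 2009),
        ],
    )
    if lumber_scale is not None:
        ratio_scale[("sawtimber_sw", "softwood_lumber")] = lumber_scale
    pulp_scale = _year_scale(draws, [("residues_to_pulp", 1906, 2009)])
    if pulp_scale is not None:
        ratio_scale[("sawtimber_sw", "wood_pulp")] = pulp_scale
    primary = timber_to_primary(series, p, ratio_scale_by_year=ratio_scale or None)
    sf_scale = float(draws.get("product_half_life", 1.0))
    return hundred_year_average(primary, p, years=years, storage_factor_scale=sf_scale)
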