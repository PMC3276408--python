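"""Annual cohort simulator for harvested-wood-products carbon.

Carbon enters as end-use cohorts (per vintage year) and fuelwood.  Each
simulated year:

* every in-use cohort decays one step of first-order decay
  ``N_t = N_0 exp(-t ln2 / t_half)``; the year's loss is the discard flow,
* discards (plus the 8 % placement loss of any new vintage) are routed by
  the discard-year's disposition schedule into burned, recovered,
  composted, landfill and dump,
* burned and composted carbon is emitted without energy capture; landfill
  carbon is split into a fixed (never-decaying) and a decaying sub-pool;
  dump carbon decays faster than landfill carbon; recovered carbon
  re-enters products in use the following year as a new cohort with its
  original half-life and no second placement loss,
* solid-waste pools decay one step and their losses are emitted without
  energy capture,
* fuelwood is emitted with energy capture entirely in its vintage year.

Stocks for a vintage's harvest year are recorded after placement loss and
fuelwood emission but before any decay (t = 0).  The ledger satisfies an
exact mass balance: at every inventory year, pools plus cumulative
emissions equal cumulative harvested carbon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conversion import EndUseAllocation
from .parameters import DISPOSITIONS, DispositionSchedule, ParameterSet, SWDSParameters

_MATERIALS = ("solid_wood", "paper")


class SimulationError(RuntimeError):
    """Internal consistency failure (negative pool, broken mass balance)."""


def decay_in_use(n0: float, half_life: float, t: float) -> float:
    """Carbon remaining in use ``t`` years after vintage."""
    if t < 0:
        raise ValueError(f"negative time since vintage: {t}")
    if n0 < 0:
        raise ValueError(f"negative initial carbon: {n0}")
    if half_life <= 0:
        raise ValueError(f"half-life must be positive: {half_life}")
    return n0 * math.exp(-t * math.log(2.0) / half_life)


def place_in_use(end_use_carbon: float, loss_fraction: float) -> tuple[float, float]:
    """Split end-use carbon into (placed in use, discarded at placement)."""
    if not (0 <= loss_fraction <= 1):
        raise ValueError(f"loss fraction {loss_fraction} outside [0, 1]")
    placed = end_use_carbon * (1.0 - loss_fraction)
    return placed, end_use_carbon - placed


def route_discards(
    amount: float,
    material: str,
    year: int,
    schedule: DispositionSchedule,
    swds: SWDSParameters | None = None,
) -> dict[str, float]:
    """Split a discard flow into the five disposition categories.

    With ``swds`` given, the landfill amount is additionally split into
    ``landfill_fixed`` and ``landfill_decaying`` by the material's fixed
    fraction.  Amounts always sum to the input exactly.
    """
    if amount < 0:
        raise ValueError(f"negative discard amount {amount}")
    row = schedule.row(year, material)
    out = {cat: amount * row[cat] for cat in DISPOSITIONS}
    if swds is not None:
        ff = swds.landfill_fixed_fraction[material]
        out["landfill_fixed"] = out["landfill"] * ff
        out["landfill_decaying"] = out["landfill"] - out["landfill_fixed"]
    return out


def decay_swds(pool: float, half_life: float, dt: float) -> tuple[float, float]:
    """One decay step of a solid-waste pool: (remaining, emitted)."""
    if pool < 0 or dt < 0:
        raise ValueError("pool and dt must be non-negative")
    remaining = pool * math.exp(-dt * math.log(2.0) / half_life)
    return remaining, pool - remaining


def emit_fuelwood(
    fuelwood_carbon: float, vintage: int, emitted_energy: pd.Series
) -> pd.Series:
    """Book a vintage's fuelwood as emission with energy capture.

    ``emitted_energy`` holds annual (non-cumulative) additions; the running
    total is formed when the ledger is assembled.
    """
    if fuelwood_carbon < 0:
        raise ValueError(f"negative fuelwood carbon {fuelwood_carbon}")
    out = emitted_energy.copy()
    out[vintage] = out.get(vintage, 0.0) + fuelwood_carbon
    return out


@dataclass
class PoolLedger:
    """Per-inventory-year carbon pools and cumulative emissions (MgC).

    ``table`` is a year-indexed DataFrame with columns in_use,
    landfill_fixed, landfill_decaying, dump, swds, recovered_in_transit,
    emitted_energy_cum, emitted_no_energy_cum, cumulative_harvest.
    ``in_use_by_vintage`` / ``swds_by_vintage`` are (year x vintage) frames
    used for vintage attribution.
    """

    table: pd.DataFrame
    in_use_by_vintage: pd.DataFrame
    swds_by_vintage: pd.DataFrame

    @property
    def years(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def total_hwp(self) -> pd.Series:
        """Products in use plus SWDS (the HWP carbon stock)."""
        return self.table["in_use"] + self.table["swds"]

    def mass_balance_error(self) -> pd.Series:
        """Relative mass-balance error per inventory year."""
        t = self.table
        accounted = (
            t["in_use"]
            + t["swds"]
            + t["recovered_in_transit"]
            + t["emitted_energy_cum"]
            + t["emitted_no_energy_cum"]
        )
        denom = t["cumulative_harvest"].where(t["cumulative_harvest"] > 0, 1.0)
        return (accounted - t["cumulative_harvest"]).abs() / denom

    def check_mass_balance(self, tol: float = 1e-6) -> None:
        err = self.mass_balance_error()
        if (err > tol).any():
            year = int(err.idxmax())
            raise SimulationError(
                f"mass balance violated: relative error {err.max():.3e} in {year}"
            )

    def to_csv(self, path) -> None:
        self.table.rename_axis("inventory_year").to_csv(path)


def simulate(
    end_use: EndUseAllocation,
    params: ParameterSet,
    end_year: int | None = None,
) -> PoolLedger:
    """Run the annual cohort model and return the full :class:`PoolLedger`.

    Cohorts sharing a (material, half-life) pair decay identically, so they
    are pooled per vintage; this is exact for first-order decay.
    """
    cohorts = end_use.cohorts
    fuelwood = end_use.fuelwood

    vintage_years = set(fuelwood.index[fuelwood > 0].tolist())
    if len(cohorts):
        vintage_years |= set(cohorts["vintage"].tolist())
    if not vintage_years:
        raise SimulationError("no carbon input: empty cohorts and fuelwood")
    first = min(vintage_years)
    last = max(vintage_years)
    if end_year is None:
        end_year = last
    if end_year < last:
        raise SimulationError(f"end_year {end_year} precedes last vintage {last}")

    years = np.arange(first, end_year + 1)
    vintages = np.arange(first, last + 1)
    n_years, n_v = len(years), len(vintages)

    # decay classes: unique (material, half_life)
    if len(cohorts):
        classes = sorted(
            {(m, float(h)) for m, h in zip(cohorts["material"], cohorts["half_life"])}
        )
    else:
        classes = []
    n_k = len(classes)
    class_index = {c: i for i, c in enumerate(classes)}
    k_material = np.array([m for m, _ in classes], dtype=object)
    decay_f = np.array(
        [math.exp(-math.log(2.0) / h) if math.isfinite(h) else 1.0 for _, h in classes]
    )
    mat_idx = {m: i for i, m in enumerate(_MATERIALS)}
    k_mat = np.array([mat_idx[m] for m in k_material], dtype=int) if n_k else np.zeros(0, int)

    # per-vintage, per-class initial end-use carbon (before placement loss)
    n0 = np.zeros((n_v, n_k))
    if len(cohorts):
        v_arr = cohorts["vintage"].to_numpy().astype(int) - first
        k_arr = np.array(
            [
                class_index[(m, float(h))]
                for m, h in zip(cohorts["material"], cohorts["half_life"])
            ]
        )
        np.add.at(n0, (v_arr, k_arr), cohorts["carbon"].to_numpy().astype(float))
    fuel = np.zeros(n_v)
    for y, c in fuelwood.items():
        if first <= int(y) <= last:
            fuel[int(y) - first] += float(c)

    lf_f = np.array(
        [
            math.exp(-math.log(2.0) / params.swds.landfill_half_life[m])
            for m in _MATERIALS
        ]
    )
    dp_f = np.array(
        [math.exp(-math.log(2.0) / params.swds.dump_half_life[m]) for m in _MATERIALS]
    )
    fixed_frac = np.array([params.swds.landfill_fixed_fraction[m] for m in _MATERIALS])
    loss_frac = params.flows.placement_loss_fraction

    # state arrays
    in_use = np.zeros((n_v, n_k))
    transit = np.zeros((n_v, n_k))
    lf_fix = np.zeros((n_v, 2))
    lf_dec = np.zeros((n_v, 2))
    dump = np.zeros((n_v, 2))
    em_energy = np.zeros(n_v)
    em_no_energy = np.zeros(n_v)

    rows = []
    iu_by_v = np.zeros((n_years, n_v))
    swds_by_v = np.zeros((n_years, n_v))
    cum_harvest = 0.0

    for yi, year in enumerate(years):
        discard = np.zeros((n_v, n_k))

        # 1. one decay step for existing in-use cohorts
        if n_k:
            decayed = in_use * decay_f
            discard += in_use - decayed
            in_use = decayed

        # 2. one decay step for SWDS decaying pools
        lf_rem = lf_dec * lf_f
        em_no_energy += (lf_dec - lf_rem).sum(axis=1)
        lf_dec = lf_rem
        dp_rem = dump * dp_f
        em_no_energy += (dump - dp_rem).sum(axis=1)
        dump = dp_rem

        # 3. last year's recovered carbon re-enters in use (new cohort, t=0)
        in_use += transit
        transit = np.zeros((n_v, n_k))

        # 4. new vintage: placement loss and fuelwood emission
        vi = year - first
        if 0 <= vi < n_v:
            added = n0[vi] * (1.0 - loss_frac)
            in_use[vi] += added
            discard[vi] += n0[vi] - added
            em_energy[vi] += fuel[vi]
            cum_harvest += n0[vi].sum() + fuel[vi]

        # 5. route the year's discards with this calendar year's schedule
        if n_k:
            for mi, material in enumerate(_MATERIALS):
                sel = k_mat == mi
                if not sel.any():
                    continue
                disc_k = discard[:, sel]
                total_m = disc_k.sum()
                if total_m == 0.0:
                    continue
                frac = params.disposition.row(int(year), material)
                em_no_energy += disc_k.sum(axis=1) * (frac["burned"] + frac["composted"])
                transit[:, sel] += disc_k * frac["recovered"]
                lf_amount = disc_k.sum(axis=1) * frac["landfill"]
                lf_fix[:, mi] += lf_amount * fixed_frac[mi]
                lf_dec[:, mi] += lf_amount * (1.0 - fixed_frac[mi])
                dump[:, mi] += disc_k.sum(axis=1) * frac["dump"]

        # 6. record
        swds_v = lf_fix.sum(axis=1) + lf_dec.sum(axis=1) + dump.sum(axis=1)
        iu_v = in_use.sum(axis=1) if n_k else np.zeros(n_v)
        iu_by_v[yi] = iu_v
        swds_by_v[yi] = swds_v
        rows.append(
            {
                "in_use": iu_v.sum(),
                "landfill_fixed": lf_fix.sum(),
                "landfill_decaying": lf_dec.sum(),
                "dump": dump.sum(),
                "swds": swds_v.sum(),
                "recovered_in_transit": transit.sum(),
                "emitted_energy_cum": em_energy.sum(),
                "emitted_no_energy_cum": em_no_energy.sum(),
                "cumulative_harvest": cum_harvest,
            }
        )

    table = pd.DataFrame(rows, index=pd.Index(years, name="inventory_year"))
    if (table[["in_use", "landfill_fixed", "landfill_decaying", "dump"]] < -1e-12).any().any():
        raise SimulationError("negative pool encountered")
    ledger = PoolLedger(
        table=table,
        in_use_by_vintage=pd.DataFrame(iu_by_v, index=years, columns=vintages),
        swds_by_vintage=pd.DataFrame(swds_by_v, index=years, columns=vintages),
    )
    ledger.check_mass_balance(tol=1e-6)
    return ledger
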