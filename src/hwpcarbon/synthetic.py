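"""Synthetic harvest scenarios and known-answer fixtures.

The regional archival harvest series is not public, so analyses and tests
run on generated series with the same qualitative structure: low early
harvest (below 400,000 MgC/yr), a rapid mid-century ramp (about a
tripling over six years), a peak near 2.4 million MgC/yr in 1969, decline
after the mid-1970s, and 200,000-400,000 MgC/yr in the final decade.
Noise is multiplicative lognormal (harvest volumes are positive and
right-skewed).  Records are emitted in mbf so the ingest conversion chain
is exercised; pre-1946 records are inflated to compensate the ingest
boundary reduction, so era targets refer to the harmonised series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .harvest import DEFAULT_BOUNDARY_POLICY, BoundaryPolicy
from .parameters import ParameterSet, default_parameter_fixture


@dataclass
class Era:
    """A contiguous span of years with linearly interpolated harvest level."""

    start: int
    end: int
    level_start: float  # MgC/yr at the first year
    level_end: float  # MgC/yr at the last year


@dataclass
class HarvestScenario:
    """Parameters of a synthetic annual harvest series."""

    start_year: int
    end_year: int
    eras: list[Era]
    noise_sd: float = 0.0  # sd of log-multiplicative noise
    seed: int = 0
    name: str = "custom"
    #: emit per-class records (exercising reported splits) from this year on
    reported_split_from: int | None = 1980

    def validate(self) -> None:
        if not self.eras:
            raise ValueError("scenario has no eras")
        expected = self.start_year
        for era in self.eras:
            if era.start != expected:
                raise ValueError(f"eras not contiguous at {era.start} (expected {expected})")
            if era.end < era.start:
                raise ValueError(f"era ends before it starts: {era}")
            if era.level_start < 0 or era.level_end < 0:
                raise ValueError(f"negative level in {era}")
            expected = era.end + 1
        if expected != self.end_year + 1:
            raise ValueError(f"eras end at {expected - 1}, scenario at {self.end_year}")

    def target_mgc(self) -> pd.Series:
        """Noise-free target harvest (MgC/yr) per year."""
        self.validate()
        levels = {}
        for era in self.eras:
            n = era.end - era.start
            for i, year in enumerate(range(era.start, era.end + 1)):
                w = i / n if n else 0.0
                levels[year] = era.level_start + w * (era.level_end - era.level_start)
        return pd.Series(levels)

    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "start_year": self.start_year,
            "end_year": self.end_year,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "reported_split_from": self.reported_split_from,
            "eras": [
                [e.start, e.end, e.level_start, e.level_end] for e in self.eras
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "HarvestScenario":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            start_year=doc["start_year"],
            end_year=doc["end_year"],
            eras=[Era(*row) for row in doc["eras"]],
            noise_sd=doc.get("noise_sd", 0.0),
            seed=doc.get("seed", 0),
            name=doc.get("name", "custom"),
            reported_split_from=doc.get("reported_split_from"),
        )


def scenario_preset(name: str, seed: int = 0, **overrides) -> HarvestScenario:
    """Named scenario presets: ``figure3_like``, ``flat``, ``pulse``."""
    if name == "figure3_like":
        sc = HarvestScenario(
            start_year=1906,
            end_year=2010,
            eras=[
                Era(1906, 1914, 120_000, 180_000),
                Era(1915, 1929, 180_000, 300_000),
                Era(1930, 1939, 160_000, 220_000),
                Era(1940, 1949, 250_000, 350_000),
                Era(1950, 1956, 350_000, 1_050_000),  # tripling over 6 years
                Era(1957, 1968, 1_100_000, 2_300_000),
                Era(1969, 1969, 2_400_000, 2_400_000),  # peak
                Era(1970, 1975, 2_250_000, 1_850_000),
                Era(1976, 1990, 1_750_000, 1_100_000),
                Era(1991, 2000, 1_000_000, 400_000),
                Era(2001, 2010, 350_000, 250_000),
            ],
            noise_sd=0.03,
            seed=seed,
            name="figure3_like",
        )
    elif name == "flat":
        sc = HarvestScenario(
            start_year=1951,
            end_year=1960,
            eras=[Era(1951, 1960, 1000.0, 1000.0)],
            noise_sd=0.0,
            seed=seed,
            name="flat",
        )
    elif name == "pulse":
        sc = HarvestScenario(
            start_year=1960,
            end_year=1960,
            eras=[Era(1960, 1960, 1000.0, 1000.0)],
            noise_sd=0.0,
            seed=seed,
            name="pulse",
        )
    else:
        raise ValueError(f"unknown scenario preset {name!r}")
    for k, v in overrides.items():
        setattr(sc, k, v)
    sc.validate()
    return sc


def _effective_mgc_per_mbf(params: ParameterSet, timber_class: str | None, year: int) -> float:
    """MgC obtained downstream per reported mbf (for target inversion)."""
    cv = params.conversion
    if timber_class is not None:
        return (
            cv.mbf_to_ccf_by_timber_product[timber_class]
            * params.carbon_per_ccf_timber_class(timber_class)
        )
    from .harvest import partition_to_timber_products

    shares = partition_to_timber_products(1.0, year, params)
    factor = sum(
        w * params.carbon_per_ccf_timber_class(c) for c, w in shares.items() if w > 0
    )
    return cv.mbf_to_ccf_default * factor


def generate_harvest(
    scenario: HarvestScenario,
    params: ParameterSet | None = None,
    policy: BoundaryPolicy = DEFAULT_BOUNDARY_POLICY,
) -> pd.DataFrame:
    """Generate raw harvest records (mbf) realising the scenario.

    Returns the standard ingest DataFrame (year, volume, unit,
    timber_product, unit_tag).  Years at or after
    ``scenario.reported_split_from`` carry per-class records; earlier years
    carry a single untyped total, as in the archival record structure.
    """
    if params is None:
        params = default_parameter_fixture()
    rng = np.random.default_rng(scenario.seed)
    target = scenario.target_mgc()
    noise = (
        np.exp(rng.normal(0.0, scenario.noise_sd, size=len(target)))
        if scenario.noise_sd > 0
        else np.ones(len(target))
    )
    shares = params.flows.timber_class_shares
    commence = params.flows.commencement_year

    rows = []
    for (year, mgc), eps in zip(target.items(), noise):
        year = int(year)
        mgc = float(mgc) * float(eps)
        if mgc == 0.0:
            continue
        # undo the ingest boundary reduction so targets survive harmonisation
        if year < policy.cutoff_year:
            mgc /= 1.0 - policy.pre_cutoff_fraction
        split_from = scenario.reported_split_from
        if split_from is not None and year >= split_from:
            active = {c: w for c, w in shares.items() if commence.get(c, 0) <= year}
            norm = sum(active.values())
            for cls, w in active.items():
                cls_mgc = mgc * w / norm
                mbf = cls_mgc / _effective_mgc_per_mbf(params, cls, year)
                rows.append(
                    {"year": year, "volume": mbf, "unit": "mbf",
                     "timber_product": cls, "unit_tag": pd.NA}
                )
        else:
            mbf = mgc / _effective_mgc_per_mbf(params, None, year)
            rows.append(
                {"year": year, "volume": mbf, "unit": "mbf",
                 "timber_product": pd.NA, "unit_tag": pd.NA}
            )
    return pd.DataFrame(rows, columns=["year", "volume", "unit", "timber_product", "unit_tag"])


# ---------------------------------------------------------------------------
# Known-answer fixture
# ---------------------------------------------------------------------------

def generate_known_answer_case() -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """A tiny two-vintage case with a hand-computed expected ledger.

    Returns ``(cohort_spec, swds_spec, expected)`` where ``cohort_spec``
    describes the carbon inputs, ``swds_spec`` the decay/disposition
    constants, and ``expected`` the year-by-year pool ledger computed by
    the explicit scalar oracle below (independent spreadsheet-style
    arithmetic, no shared simulator code).

    Inputs: vintage 2000 has 100 MgC of solid wood in one end use
    (half-life 2 yr); vintage 2001 has 30 MgC in the same end use plus
    20 MgC of fuelwood.  Placement loss 8 %.  Disposition is constant:
    burned 0.2, recovered 0.1, composted 0.1, landfill 0.4, dump 0.2.
    Landfill fixed fraction 0.77, landfill half-life 20 yr, dump 10 yr.
    """
    cohort_spec = pd.DataFrame(
        [
            {"vintage": 2000, "end_use": "use_a", "material": "solid_wood",
             "half_life": 2.0, "carbon": 100.0},
            {"vintage": 2001, "end_use": "use_a", "material": "solid_wood",
             "half_life": 2.0, "carbon": 30.0},
        ]
    )
    swds_spec = {
        "placement_loss": 0.08,
        "disposition": {"burned": 0.2, "recovered": 0.1, "composted": 0.1,
                        "landfill": 0.4, "dump": 0.2},
        "landfill_fixed_fraction": 0.77,
        "landfill_half_life": 20.0,
        "dump_half_life": 10.0,
        "fuelwood": {2001: 20.0},
        "years": list(range(2000, 2011)),
    }
    expected = _oracle_ledger(cohort_spec, swds_spec)
    return cohort_spec, swds_spec, expected


def _oracle_ledger(cohort_spec: pd.DataFrame, spec: dict) -> pd.DataFrame:
    """Explicit scalar year-by-year bookkeeping for the known-answer case.

    Deliberately plain arithmetic over named scalars -- the reference the
    vectorised simulator is tested against.
    """
    d = spec["disposition"]
    ff = spec["landfill_fixed_fraction"]
    g_lf = 0.5 ** (1.0 / spec["landfill_half_life"])
    g_dp = 0.5 ** (1.0 / spec["dump_half_life"])
    loss = spec["placement_loss"]

    # cohorts keyed by half-life (all solid wood here)
    in_use: dict[float, float] = {}
    transit: dict[float, float] = {}
    lf_fix = lf_dec = dump = 0.0
    em_energy = em_no = 0.0
    cum = 0.0
    out = []
    for year in spec["years"]:
        discard: dict[float, float] = {}
        # decay in use
        for h in list(in_use):
            g = 0.5 ** (1.0 / h)
            lost = in_use[h] * (1.0 - g)
            in_use[h] -= lost
            discard[h] = discard.get(h, 0.0) + lost
        # decay SWDS
        em_no += lf_dec * (1.0 - g_lf)
        lf_dec *= g_lf
        em_no += dump * (1.0 - g_dp)
        dump *= g_dp
        # recovered from last year re-enters
        for h, m in transit.items():
            in_use[h] = in_use.get(h, 0.0) + m
        transit = {}
        # new vintage
        for _, row in cohort_spec[cohort_spec["vintage"] == year].iterrows():
            h = float(row["half_life"])
            n0 = float(row["carbon"])
            in_use[h] = in_use.get(h, 0.0) + n0 * (1.0 - loss)
            discard[h] = discard.get(h, 0.0) + n0 * loss
            cum += n0
        fw = spec["fuelwood"].get(year, 0.0)
        em_energy += fw
        cum += fw
        # route discards
        for h, m in discard.items():
            em_no += m * (d["burned"] + d["composted"])
            transit[h] = transit.get(h, 0.0) + m * d["recovered"]
            lf = m * d["landfill"]
            lf_fix += lf * ff
            lf_dec += lf * (1.0 - ff)
            dump += m * d["dump"]
        out.append(
            {
                "inventory_year": year,
                "in_use": sum(in_use.values()),
                "landfill_fixed": lf_fix,
                "landfill_decaying": lf_dec,
                "dump": dump,
                "swds": lf_fix + lf_dec + dump,
                "recovered_in_transit": sum(transit.values()),
                "emitted_energy_cum": em_energy,
                "emitted_no_energy_cum": em_no,
                "cumulative_harvest": cum,
            }
        )
    return pd.DataFrame(out).set_index("inventory_year")


def known_answer_parameter_set() -> ParameterSet:
    """A ParameterSet matching :func:`generate_known_answer_case` constants."""
    params = default_parameter_fixture()
    params.flows.placement_loss_fraction = 0.08
    params.disposition.anchors = {
        m: {2000: {"burned": 0.2, "recovered": 0.1, "composted": 0.1,
                   "landfill": 0.4, "dump": 0.2}}
        for m in ("solid_wood", "paper")
    }
    params.swds.landfill_fixed_fraction = {"solid_wood": 0.77, "paper": 0.44}
    params.swds.landfill_half_life = {"solid_wood": 20.0, "paper": 20.0}
    params.swds.dump_half_life = {"solid_wood": 10.0, "paper": 10.0}
    return params
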