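"""Harvest record ingest: units, administrative boundary, class partition.

Raw cut-and-sold style records (year, volume, unit, optional timber product
class and administrative-unit tag) are harmonised into a contiguous annual
series of carbon (MgC) by timber product class:

1. volume conversion mbf -> ccf (class-specific factor when the class is
   known, the regional default otherwise),
2. administrative boundary adjustment (records predating forest-level
   reporting are reduced by a fixed fraction; tagged excluded-forest
   records are subtracted for the era when they were reported),
3. ccf -> MgC using ratio-weighted primary-product carbon factors,
4. partition into timber product classes, either verbatim from reported
   per-class records or by long-run mean shares with not-yet-commenced
   classes zeroed and the remainder renormalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ConversionFactors, ParameterError, ParameterSet

VALID_UNITS = ("mbf", "ccf", "MgC")


class IngestError(ValueError):
    """Raw harvest records violate the ingest contract."""


@dataclass
class BoundaryPolicy:
    """How to normalise the harvest to the modern administrative boundary.

    ``pre_cutoff_fraction`` of the reported volume is removed for years
    before ``cutoff_year`` (era with no forest-level breakdown); between
    ``cutoff_year`` and ``exclusion_end_year`` (exclusive) any record tagged
    with a unit in ``excluded_unit_tags`` is subtracted; later years are
    taken as-is.
    """

    pre_cutoff_fraction: float = 0.053
    cutoff_year: int = 1946
    exclusion_end_year: int = 1975
    excluded_unit_tags: frozenset = frozenset({"colville"})

    def validate(self) -> None:
        if not (0 <= self.pre_cutoff_fraction < 1):
            raise IngestError(
                f"pre_cutoff_fraction {self.pre_cutoff_fraction} outside [0, 1)"
            )


DEFAULT_BOUNDARY_POLICY = BoundaryPolicy()


@dataclass
class HarvestSeries:
    """Contiguous annual carbon series (MgC) by timber product class.

    ``data`` is a year-indexed DataFrame with one column per timber class.
    """

    data: pd.DataFrame
    boundary_adjusted: bool = True
    partition_source: pd.Series | None = None  # per year: "reported"/"imputed"
    gap_years: list[int] = field(default_factory=list)

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def total(self) -> pd.Series:
        """Total harvested carbon per year (MgC)."""
        return self.data.sum(axis=1)

    def to_csv(self, path) -> None:
        self.data.rename_axis("year").to_csv(path)


def convert_volume(
    volume: float,
    unit: str,
    timber_product: str | None,
    cf: ConversionFactors,
) -> float:
    """Convert a volume to ccf (hundred cubic feet).

    mbf volumes use the product-specific factor when a class is given and
    the regional default (2.2 ccf/mbf) otherwise; ccf passes through.
    """
    if volume < 0:
        raise IngestError(f"negative volume {volume}")
    if unit == "ccf":
        return float(volume)
    if unit == "mbf":
        if timber_product is None:
            return float(volume) * cf.mbf_to_ccf_default
        try:
            factor = cf.mbf_to_ccf_by_timber_product[timber_product]
        except KeyError:
            raise IngestError(
                f"no mbf->ccf factor for timber product {timber_product!r}"
            ) from None
        return float(volume) * factor
    raise IngestError(f"unknown unit {unit!r} (expected one of {VALID_UNITS})")


def adjust_boundary(
    volume: float,
    year: int,
    policy: BoundaryPolicy = DEFAULT_BOUNDARY_POLICY,
    tagged_excluded_volume: float = 0.0,
) -> float:
    """Normalise a yearly volume to the modern administrative boundary."""
    policy.validate()
    if year < policy.cutoff_year:
        return volume * (1.0 - policy.pre_cutoff_fraction)
    if year < policy.exclusion_end_year:
        out = volume - tagged_excluded_volume
        if out < 0:
            raise IngestError(
                f"excluded volume {tagged_excluded_volume} exceeds total {volume} in {year}"
            )
        return out
    return volume


def partition_to_timber_products(
    total_carbon: float,
    year: int,
    params: ParameterSet,
    reported_split: dict[str, float] | None = None,
    tol: float = 1e-6,
) -> dict[str, float]:
    """Split a year's total carbon (MgC) into timber product classes.

    A reported per-class split is used verbatim (it must sum to the total);
    otherwise the long-run mean shares are applied, with classes that had
    not commenced by ``year`` zeroed and the remaining shares renormalised.
    """
    if total_carbon < 0:
        raise IngestError(f"negative total carbon {total_carbon}")
    shares = params.flows.timber_class_shares
    if reported_split is not None:
        s = sum(reported_split.values())
        if abs(s - total_carbon) > tol * max(1.0, abs(total_carbon)):
            raise IngestError(
                f"reported split sums to {s}, expected total {total_carbon}"
            )
        return {c: float(reported_split.get(c, 0.0)) for c in shares}
    commence = params.flows.commencement_year
    active = {c: w for c, w in shares.items() if commence.get(c, 0) <= year}
    norm = sum(active.values())
    if norm <= 0:
        raise IngestError(f"no timber product class active in {year}")
    return {
        c: (total_carbon * shares[c] / norm if c in active else 0.0) for c in shares
    }


def read_harvest_csv(path) -> pd.DataFrame:
    """Read the standard harvest CSV (year, volume, unit[, timber_product, unit_tag])."""
    df = pd.read_csv(path)
    required = {"year", "volume", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"{path}: missing columns {sorted(missing)}")
    for col in ("timber_product", "unit_tag"):
        if col not in df.columns:
            df[col] = pd.NA
    return df


def build_series(
    records: pd.DataFrame,
    params: ParameterSet,
    policy: BoundaryPolicy = DEFAULT_BOUNDARY_POLICY,
    carbon_scale_by_year: pd.Series | None = None,
    mbf_ccf_scale_by_year: pd.Series | None = None,
    harvest_scale_by_year: pd.Series | None = None,
    sawtimber_share_scale_by_year: pd.Series | None = None,
) -> HarvestSeries:
    """Build a contiguous :class:`HarvestSeries` from raw records.

    ``records`` is a DataFrame with columns year, volume, unit and optional
    timber_product / unit_tag.  The optional ``*_scale_by_year`` series are
    multiplicative perturbations used by the uncertainty engine: reported
    harvest volume, the mbf->ccf conversion factor, the ccf->MgC carbon
    factor, and the softwood-sawtimber share of imputed partitions.
    Missing interior years are zero-filled and flagged.
    """
    if len(records) == 0:
        raise IngestError("no harvest records")
    df = records.copy()
    df["year"] = df["year"].astype(int)
    bad = df[(df["year"] < 1906) | (df["year"] > 2010)]
    if len(bad):
        raise IngestError(f"years outside 1906-2010: {sorted(bad['year'].unique())}")
    if (df["volume"] < 0).any():
        raise IngestError("negative volumes in records")

    key = ["year", "timber_product", "unit_tag"]
    dupes = df[df.duplicated(subset=key, keep=False)]
    if len(dupes):
        raise IngestError(
            "duplicate (year, timber_product, unit_tag) records: "
            f"{dupes[key].drop_duplicates().to_dict('records')}"
        )

    def scale(series: pd.Series | None, year: int) -> float:
        if series is None:
            return 1.0
        return float(series.get(year, 1.0))

    def per_record(series: pd.Series | None, years: np.ndarray) -> np.ndarray:
        if series is None:
            return np.ones(len(years))
        return series.reindex(years).fillna(1.0).to_numpy()

    cf = params.conversion
    classes = list(params.flows.timber_class_shares)

    unit = df["unit"].astype(str).to_numpy()
    bad_units = set(unit) - set(VALID_UNITS)
    if bad_units:
        raise IngestError(f"unknown units {sorted(bad_units)} (expected {VALID_UNITS})")
    tp_raw = df["timber_product"].to_numpy()
    tp = np.array([None if pd.isna(t) else str(t) for t in tp_raw], dtype=object)
    unknown_tp = {t for t in tp if t is not None and t not in classes}
    if unknown_tp:
        raise IngestError(f"unknown timber product classes {sorted(unknown_tp)}")
    rec_year = df["year"].to_numpy()
    vol = df["volume"].astype(float).to_numpy()

    h_mult = per_record(harvest_scale_by_year, rec_year)
    v_mult = per_record(mbf_ccf_scale_by_year, rec_year)
    c_mult = per_record(carbon_scale_by_year, rec_year)

    mbf_fac = np.array(
        [
            cf.mbf_to_ccf_default if t is None else cf.mbf_to_ccf_by_timber_product[t]
            for t in tp
        ]
    )
    is_mbf = unit == "mbf"
    is_ccf = unit == "ccf"
    is_mgc = unit == "MgC"
    ccf = np.where(is_mbf, vol * mbf_fac * v_mult, np.where(is_ccf, vol, 0.0)) * h_mult
    mgc = np.where(is_mgc, vol * h_mult, 0.0)

    tagged = np.array(
        [
            (not pd.isna(t)) and str(t).lower() in policy.excluded_unit_tags
            for t in df["unit_tag"].to_numpy()
        ]
    )
    # administrative boundary weight per record: fixed reduction before the
    # cutoff, tagged-record subtraction inside the exclusion window
    policy.validate()
    w = np.ones(len(df))
    w[rec_year < policy.cutoff_year] = 1.0 - policy.pre_cutoff_fraction
    in_window = (rec_year >= policy.cutoff_year) & (rec_year < policy.exclusion_end_year)
    w[in_window & tagged] = 0.0
    ccf_adj = ccf * w
    mgc_adj = mgc * w
    cls_factor = np.array(
        [0.0 if t is None else params.carbon_per_ccf_timber_class(t) for t in tp]
    )
    carbon_adj = ccf_adj * cls_factor * c_mult + mgc_adj

    years = range(int(rec_year.min()), int(rec_year.max()) + 1)
    out = pd.DataFrame(0.0, index=list(years), columns=classes)
    partition_source = pd.Series("imputed", index=list(years))

    agg = pd.DataFrame(
        {"year": rec_year, "tp": tp, "ccf_adj": ccf_adj, "mgc_adj": mgc_adj,
         "carbon_adj": carbon_adj, "has_tp": tp != None}  # noqa: E711
    )
    for year, grp in agg.groupby("year"):
        year = int(year)
        if grp["has_tp"].all():
            split = grp.groupby("tp")["carbon_adj"].sum().to_dict()
            total = float(sum(split.values()))
            alloc = partition_to_timber_products(total, year, params, reported_split=split)
            if sawtimber_share_scale_by_year is not None and total > 0:
                m = scale(sawtimber_share_scale_by_year, year)
                fracs = _rescale_share(
                    {c: v / total for c, v in alloc.items()}, "sawtimber_sw", m
                )
                alloc = {c: total * wgt for c, wgt in fracs.items()}
            partition_source[year] = "reported"
        else:
            if grp["has_tp"].any():
                raise IngestError(
                    f"{year}: mix of class-tagged and untyped records is not supported"
                )
            total_ccf = float(grp["ccf_adj"].sum())
            # ccf -> MgC with the share-weighted carbon factor of the active mix
            alloc_shares = partition_to_timber_products(1.0, year, params)
            if sawtimber_share_scale_by_year is not None:
                m = scale(sawtimber_share_scale_by_year, year)
                alloc_shares = _rescale_share(alloc_shares, "sawtimber_sw", m)
            carbon_factor = sum(
                wgt * params.carbon_per_ccf_timber_class(c)
                for c, wgt in alloc_shares.items()
                if wgt > 0
            )
            cm = scale(carbon_scale_by_year, year)
            total_carbon = total_ccf * carbon_factor * cm + float(grp["mgc_adj"].sum())
            alloc = {c: total_carbon * wgt for c, wgt in alloc_shares.items()}
        out.loc[year] = pd.Series(alloc)

    recorded = set(int(y) for y in df["year"].unique())
    gap_years = [y for y in years if y not in recorded]

    return HarvestSeries(
        data=out,
        boundary_adjusted=True,
        partition_source=partition_source,
        gap_years=gap_years,
    )


def _rescale_share(shares: dict[str, float], target: str, mult: float) -> dict[str, float]:
    """Multiply one share by ``mult`` and renormalise the row to sum 1."""
    if target not in shares or shares[target] == 0:
        return shares
    scaled = dict(shares)
    scaled[target] = shares[target] * mult
    norm = sum(scaled.values())
    return {k: v / norm for k, v in scaled.items()}
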