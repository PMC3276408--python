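# Methods

`hwpcarbon` estimates the carbon stored in harvested wood products (HWP)
for a sub-national forest region from its annual timber harvest record.
Two standard metrics are computed from one carbon pool:

1. **Production-approach stock accounting** (the IPCC variant adopted by
   the US EPA): carbon is attributed to the place of harvest and followed
   through products in use and solid waste disposal sites (SWDS) for every
   inventory year, yielding cumulative stocks and annual stock change.
2. **100-year average storage** (the California Forest Project Protocol
   metric): for each harvest year alone, the mean carbon stored over the
   following century, split into products in use and landfill.

A Latin-hypercube Monte Carlo layer propagates parameter and data
uncertainty through either metric.

## The accounting chain

Annual harvest records (mbf, ccf or MgC; optionally per timber product
class and per administrative unit) are harmonised into a contiguous
series of carbon by timber product class:

- **Units.** mbf volumes convert to ccf with a product-specific factor
  (1.75-2.56 ccf/mbf) or the regional default 2.2 ccf/mbf when the class
  is unknown. Carbon conversion applies MgC/ccf factors defined at the
  primary-product level (0.711-0.919); a timber class's factor is the
  ratio-weighted mean over its primary products. The alternative density
  chain (100 ft³ × density / 2204.6 lbs/Mg × fiber fraction × 0.5 MgC/Mg)
  is retained only as a cross-check and agrees with the direct factors to
  within 0.5 % for the shipped fixture.
- **Boundary.** Years before 1946 are reduced by a fixed 5.3 % (the
  long-run share of a forest later transferred out of the region);
  1946-1974 records tagged with an excluded unit are subtracted; later
  years pass through. The adjustment is a policy object so other regions
  can substitute their own exclusions.
- **Partition.** Years with reported per-class volumes use them verbatim.
  Earlier years apply the long-run mean class shares (softwood sawtimber
  0.787, pulpwood 0.069, fuelwood 0.086, non-saw 0.020, other 0.038),
  zeroing classes whose processing had not yet commenced in the region and
  renormalising the rest. Commencement years are fixture assumptions
  (pulpwood 1948, non-saw 1935, all others 1906). Missing interior years
  are zero-filled and flagged, never interpolated by default.

Timber-class carbon is then allocated to primary products (lumber,
plywood, miscellaneous solid products, wood pulp, fuelwood, other) by
row-stochastic ratio tables, and each primary product's carbon to end
uses (housing, repair, non-residential construction, manufacturing,
shipping, paper products, other) using year-indexed distribution rows
defined for 1950-2006. Vintages outside that domain use the nearest edge
row — the 1950 row serves 1906-1949 and the 2006 row serves 2007-2010 —
and rows between stored anchor years are linearly interpolated, which
preserves row sums.

## Cohort fate model

Each (vintage, end use) cohort starts at `N0` minus an 8 % placement
loss, which is discarded immediately. In-use carbon follows first-order
decay, `N_t = N0 exp(-t ln2 / t_half)`, discretised annually: the year's
discard flow is `N_{t-1} - N_t`. Discards (including placement losses)
are routed by the discard-year's disposition row — burned, recovered,
composted, landfill, dump — which differs for solid wood and paper and
shifts over time from open dumps (dominant before 1970) to landfills
(67 % of solid-wood discards with dumps below 2 % by the 2000s; paper
recovery rises from 17 % in 1960 to about 50 % in 2004).

- Burned and composted carbon is emitted without energy capture.
- Landfill carbon splits into a fixed fraction (0.77 solid wood, 0.44
  paper) that never decays, and a decaying remainder with a material-
  specific half-life. Dumps have no fixed fraction and a shorter
  half-life (they are aerobic). All SWDS losses are emissions without
  energy capture; methane is not distinguished from CO2 and no
  CO2-equivalent weighting is applied.
- Recovered carbon re-enters products in use in the year after discard as
  a new cohort with its original material and half-life and no second
  placement loss; it may cycle repeatedly. This is the simplest
  mass-conserving reading of recovery and is isolated in one code path.
- Fuelwood is emitted with energy capture entirely in its vintage year.

Time convention: `t` is integer years since vintage; harvest-year stocks
are recorded after placement loss and fuelwood emission but before any
decay (`t = 0`). New SWDS deposits and re-entering recovered cohorts
likewise begin decaying the following year.

Cohorts sharing a (material, half-life) pair are pooled per vintage —
exact for linear first-order decay — so the simulator is a set of small
dense array updates per year. The ledger keeps per-vintage resolution for
in-use and SWDS pools, enabling vintage attribution (e.g. the share of a
final stock contributed by pre-1950 harvests). A mass-balance invariant
(pools + cumulative emissions + recovered-in-transit = cumulative
harvest) is checked every year at 1e-6 relative tolerance; in practice it
holds to machine precision.

## 100-year average

Storage factors per primary product (in use; landfill) are applied to a
single harvest year's HWP carbon; the total is their sum. By default the
input carbon comes from the production chain above — both metrics then
describe the same pool — while the protocol's own mill-efficiency input
path (0.675 softwood, 0.568 hardwood, balance emitted at the mill) is
available as a standalone alternative. Because the protocol's factor
tables are not public in the source material, the shipped factors are
fixture values; `derive_storage_factors` generates factors that are
exactly self-consistent with the cohort model (the century mean of a unit
cohort per product), and the test suite verifies that the factor path and
a brute-force century mean agree under those derived factors. The
published "landfills and dumps" column is modelled with the landfill
factor alone, as the protocol defines no separate dump factor.

## Uncertainty

Eighteen symmetric triangular variables cover conversion factors,
reported harvest (three periods), product distribution, and product
decay, each stated as a 90 % CI half-width (±5 % to ±30 %). The stated
"90 % CI ±a" is interpreted, by default, as the distribution's central
90 % interval: the support half-width is `b = a / (1 - sqrt(0.1)) ≈
1.4625 a`, from inverting the triangular CDF at 0.05. The alternative
reading (support = ±a, `bounds_equal_ci`) is selectable because the
choice materially changes the spread.

Sampling is Latin hypercube (one draw per probability bin per variable).
The three harvest-period variables are rank-correlated at 0.5 by
reordering each variable's stratified draws to the ranks of correlated
normal scores (Gaussian copula with Pearson ρ = 2 sin(π·0.5/6) so the
Spearman target is met); this leaves the margins untouched. Achieved
group correlation at 2,200 iterations is within ±0.05 of the target.
The decay-variable group has a single member in this parameterisation
(one multiplier scales all end-use half-lives together, which itself
encodes the "errors move together" assumption), so its 0.5 coefficient
is vacuous.

Perturbations are multiplicative. Scalings of a share inside a
row-stochastic table multiply the targeted entry and renormalise the
whole row; this is well defined for any positive multiplier (pure
scaling could push a 0.787 share above 1 at the ±30 % support) and
reduces to plain scaling for small shares. The landfill fixed fractions
are capped at 1. The 100-year-average analysis uses 15 of the 18
variables — the discard-to-landfill, landfill-decay-limit and
landfill-half-life variables do not enter that route — and its decay
variable acts on the storage factors. The two new-housing distribution
variables are carried in the 15 but are inert in the default
100-year-average route, whose storage factors are resolved at the
primary-product level.

Each iteration re-runs the full deterministic chain with perturbed
inputs; failures are recorded and excluded (never silently resampled,
which would break stratification), and more than 1 % failures aborts.
Results are the per-year simulation mean and empirical 5th/95th
percentiles; 2,200 iterations is the default, matching the scale at
which the percentile estimates stabilise.

## Synthetic data

No archival harvest series is distributed, so analyses and tests run on
a generated series: piecewise-linear era levels with multiplicative
lognormal noise (sd 0.03), reusing the 1906-2010 calendar. The
`figure3_like` preset encodes the documented qualitative anchors — below
400,000 MgC/yr before 1950, a tripling ramp over 1950-1956, a peak of
about 2.4 million MgC/yr in 1969, decline after the mid-1970s, and
200,000-400,000 MgC/yr after 2000. Records are emitted in mbf (per-class
records from 1980 onward, a single untyped total before) so the full
ingest path is exercised; pre-1946 records are inflated by 1/(1-0.053)
so that era targets refer to the boundary-harmonised series. A `pulse`
preset isolates single vintages and a `flat` preset gives stationary
input.

What the synthetic runs do *not* show: agreement with the published
regional magnitudes. Those depend on the archival harvest series and on
several unpublished source tables (primary-product ratios, end-use
distributions and half-lives, disposition schedules, storage factors)
for which this package ships documented fixture estimates. Passing tests
demonstrate the correctness of the accounting machinery — identities,
conservation, closed forms, oracle equivalence, sampling properties —
not the reproduction of the regional case study. Headline behaviours do
carry over qualitatively: stocks keep rising for decades after the
harvest peak, turn into a net source around the turn of the century, and
pre-1950 vintages contribute only a few percent of the final stock.

## Numerical choices and limitations

- All internal carbon is double precision MgC; rounding to whole MgC
  happens only at CSV export. MgC→MgCO2 uses 44/12 and is never stored.
- Ties in peak detection resolve to the earliest year.
- Zero-harvest years propagate exactly (zero cohorts, zero rows).
- Half-lives may be infinite (no decay), used in conservation tests.
- The simulator refuses negative pools and checks mass balance on every
  run; the known-answer fixture is computed by an independent scalar
  oracle with explicit year-by-year arithmetic.
- Fiscal vs calendar year labelling in historical records is treated as
  a single annual index; the model's time step is annual and no offset
  correction is attempted.
- The final harvest year is configurable (`end_year`); the deterministic
  drivers run inventory years 1906-2010 with harvests through 2010.
- Land-exchange history means the physical land base behind a fixed
  "modern boundary" series is not constant; the boundary policy is an
  approximation, not a reconstruction.
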