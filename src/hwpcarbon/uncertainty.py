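"""Monte Carlo uncertainty propagation with Latin hypercube sampling.

Each uncertain quantity is a symmetric triangular random variable stated
as a 90 % confidence half-width (e.g. "+/- 30 %") around the deterministic
value, applied as a multiplicative scaling of the targeted parameter or
harvest period.  Named groups (the three reported-harvest periods, the
product-decay variables) are rank-correlated at 0.5 via normal-copula
rank reordering (Iman-Conover style), which preserves each variable's
stratified margins exactly.

The default variable set has 18 members for the stock-accounting route;
the 100-year-average route drops the three landfill variables (discard
fraction to landfill, landfill decay limits, landfill half-life), leaving
15, since only the product half-life / storage-factor variable touches
that computation's decay side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

#: b = a / (1 - sqrt(0.1)): half-support of a symmetric triangular
#: distribution whose central 90 % interval is +/- a.
PERCENTILE_MATCH = 1.0 / (1.0 - math.sqrt(0.1))


class UncertaintyError(RuntimeError):
    pass


@dataclass(frozen=True)
class TriangularVar:
    """One uncertain multiplier: name, 90 % CI half-width, scope, group."""

    name: str
    ci90_halfwidth: float
    years: tuple[int, int] | None = None  # inclusive span the scaling applies to
    correlation_group: str | None = None
    cfpp: bool = True  # participates in the 100-year-average analysis


def default_uncertainty_variables() -> list[TriangularVar]:
    """The default 18-variable set (stock-accounting route).

    Spans and half-widths follow the published uncertainty table:
    conversion factors, reported harvest (three periods, correlated),
    product distribution, and product decay.
    """
    v = TriangularVar
    return [
        v("mbf_ccf_1906_1979", 0.30, (1906, 1979)),
        v("mbf_ccf_1980_2009", 0.15, (1980, 2009)),
        v("ccf_mgc", 0.05, (1906, 2009)),
        v("harvest_1906_1945", 0.30, (1906, 1945), "harvest"),
        v("harvest_1946_1979", 0.20, (1946, 1979), "harvest"),
        v("harvest_1980_2009", 0.15, (1980, 2009), "harvest"),
        v("roundwood_to_sawtimber_1906_1979", 0.30, (1906, 1979)),
        v("roundwood_to_sawtimber_1980_2009", 0.15, (1980, 2009)),
        v("sawtimber_to_lumber_1906_1949", 0.30, (1906, 1949)),
        v("sawtimber_to_lumber_1950_1979", 0.20, (1950, 1979)),
        v("sawtimber_to_lumber_1980_2009", 0.15, (1980, 2009)),
        v("lumber_to_new_housing", 0.15, (1906, 2009)),
        v("panels_to_new_housing", 0.15, (1906, 2009)),
        v("residues_to_pulp", 0.15, (1906, 2009)),
        v("product_half_life", 0.15, (1906, 2009), "half_life"),
        v("discards_to_landfill", 0.15, (1906, 2009), cfpp=False),
        v("landfill_decay_limits", 0.15, (1906, 2009), cfpp=False),
        v("landfill_half_life", 0.15, (1906, 2009), cfpp=False),
    ]


@dataclass
class MonteCarloSpec:
    """Sampling plan: variables, iteration count, correlation, seed."""

    variables: list[TriangularVar] = field(default_factory=default_uncertainty_variables)
    iterations: int = 2200
    sampling: str = "latin_hypercube"  # or "simple"
    correlation: dict[str, float] = field(
        default_factory=lambda: {"harvest": 0.5, "half_life": 0.5}
    )
    seed: int = 0
    mode_convention: str = "percentile_matched"  # or "bounds_equal_ci"

    def validate(self) -> None:
        if self.iterations < 2:
            raise UncertaintyError("need at least 2 iterations")
        for g, r in self.correlation.items():
            if not (-1.0 <= r <= 1.0):
                raise UncertaintyError(f"correlation[{g}]={r} outside [-1, 1]")
        if self.sampling not in ("latin_hypercube", "simple"):
            raise UncertaintyError(f"unknown sampling {self.sampling!r}")
        if self.mode_convention not in ("percentile_matched", "bounds_equal_ci"):
            raise UncertaintyError(f"unknown mode convention {self.mode_convention!r}")


def triangular_from_ci(
    center: float,
    ci90_halfwidth: float,
    mode_convention: str = "percentile_matched",
    nonnegative: bool = True,
):
    """Frozen symmetric triangular distribution around ``center``.

    ``ci90_halfwidth`` is a fraction of the center.  Under
    ``percentile_matched`` (default) the support half-width is
    ``a / (1 - sqrt(0.1))`` so the central 90 % probability interval is
    exactly +/- a (from the triangular CDF ``(x + b)^2 / (2 b^2) = 0.05``);
    under ``bounds_equal_ci`` the support itself is +/- a.  A zero
    half-width yields a degenerate point mass (useful for collapse checks).
    """
    if ci90_halfwidth < 0:
        raise UncertaintyError(f"negative half-width {ci90_halfwidth}")
    if ci90_halfwidth == 0:
        return _Degenerate(center)
    if mode_convention == "percentile_matched":
        b = ci90_halfwidth * PERCENTILE_MATCH
    elif mode_convention == "bounds_equal_ci":
        b = ci90_halfwidth
    else:
        raise UncertaintyError(f"unknown mode convention {mode_convention!r}")
    lo = center * (1.0 - b)
    if nonnegative and lo < 0:
        raise UncertaintyError(
            f"triangular lower bound {lo} < 0 for a non-negative parameter "
            f"(center {center}, support half-width {b})"
        )
    return stats.triang(c=0.5, loc=lo, scale=2.0 * center * b)


class _Degenerate:
    """Point mass: what a zero-half-width triangular collapses to."""

    def __init__(self, value: float):
        self.value = value

    def ppf(self, q):
        return np.full_like(np.asarray(q, dtype=float), self.value)

    def cdf(self, x):
        return (np.asarray(x, dtype=float) >= self.value).astype(float)


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula Pearson coefficient achieving a Spearman target."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def lhs_sample(spec: MonteCarloSpec) -> pd.DataFrame:
    """Draw the (iterations x variables) multiplier matrix.

    Latin hypercube margins (one draw per probability bin of width 1/n per
    variable); grouped variables are rank-reordered against correlated
    normal scores so their Spearman correlation approaches the group
    coefficient without disturbing the stratified margins.
    """
    spec.validate()
    n = spec.iterations
    names = [v.name for v in spec.variables]
    d = len(names)
    rng = np.random.default_rng(spec.seed)
    if spec.sampling == "latin_hypercube":
        sampler = qmc.LatinHypercube(d=d, seed=rng)
        u = sampler.random(n)
    else:
        u = rng.random((n, d))

    # rank-correlate within groups
    groups: dict[str, list[int]] = {}
    for j, var in enumerate(spec.variables):
        if var.correlation_group is not None:
            groups.setdefault(var.correlation_group, []).append(j)
    for gname, idx in groups.items():
        rho_s = spec.correlation.get(gname, 0.0)
        if len(idx) < 2 or rho_s == 0.0:
            continue
        k = len(idx)
        rho_p = _spearman_to_pearson(rho_s)
        cov = np.full((k, k), rho_p)
        np.fill_diagonal(cov, 1.0)
        try:
            z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
        except np.linalg.LinAlgError as exc:
            raise UncertaintyError(f"infeasible correlation matrix for group {gname!r}") from exc
        for col, j in enumerate(idx):
            ranks = stats.rankdata(z[:, col], method="ordinal").astype(int) - 1
            u[:, j] = np.sort(u[:, j])[ranks]

    out = np.empty((n, d))
    for j, var in enumerate(spec.variables):
        dist = triangular_from_ci(1.0, var.ci90_halfwidth, spec.mode_convention)
        out[:, j] = dist.ppf(u[:, j])
    return pd.DataFrame(out, columns=names)


@dataclass
class UncertaintyResult:
    """Simulation mean and empirical 90 % interval per output year."""

    table: pd.DataFrame  # year-indexed: mean, p5, p95
    achieved_correlation: dict[str, float]
    n_failures: int
    iterations: int

    def to_csv(self, path) -> None:
        self.table.rename_axis("year").to_csv(path)


def percent_spread(result_or_row, year: int | None = None) -> tuple[float, float]:
    """CI spread as percent differences from the simulation mean.

    Accepts an :class:`UncertaintyResult` plus a year, or a mapping with
    keys mean/p5/p95.  Returns ``(100 (p5 - mean) / mean,
    100 (p95 - mean) / mean)``.
    """
    if isinstance(result_or_row, UncertaintyResult):
        row = result_or_row.table.loc[year]
        mean, p5, p95 = float(row["mean"]), float(row["p5"]), float(row["p95"])
    else:
        row = result_or_row
        mean, p5, p95 = float(row["mean"]), float(row["p5"]), float(row["p95"])
    if mean == 0:
        raise UncertaintyError("mean is zero; percent spread undefined")
    return 100.0 * (p5 - mean) / mean, 100.0 * (p95 - mean) / mean


def mean_group_spearman(draws: pd.DataFrame, spec: MonteCarloSpec) -> dict[str, float]:
    """Achieved mean pairwise Spearman correlation per group."""
    out = {}
    for gname in spec.correlation:
        cols = [v.name for v in spec.variables if v.correlation_group == gname]
        if len(cols) < 2:
            continue
        mat = stats.spearmanr(draws[cols]).statistic
        mat = np.atleast_2d(mat)
        pairs = [mat[i, j] for i in range(len(cols)) for j in range(i + 1, len(cols))]
        out[gname] = float(np.mean(pairs))
    return out


def run_uncertainty(
    pipeline,
    spec: MonteCarloSpec,
    years: list[int],
    max_failure_fraction: float = 0.01,
) -> UncertaintyResult:
    """Propagate the sampled multipliers through a pipeline closure.

    ``pipeline(draws: dict[str, float]) -> pd.Series`` must return the
    output quantity per year for one perturbed run.  Failed iterations are
    recorded and excluded; more than ``max_failure_fraction`` failing
    aborts the analysis.
    """
    draws = lhs_sample(spec)
    results = np.full((spec.iterations, len(years)), np.nan)
    failures = 0
    for i in range(spec.iterations):
        row = draws.iloc[i].to_dict()
        try:
            series = pipeline(row)
            results[i] = [float(series.loc[y]) for y in years]
        except Exception:
            failures += 1
            if failures > max_failure_fraction * spec.iterations:
                raise UncertaintyError(
                    f"{failures} of {i + 1} iterations failed "
                    f"(> {max_failure_fraction:.0%} allowed)"
                )
    ok = ~np.isnan(results[:, 0])
    res = results[ok]
    table = pd.DataFrame(
        {
            "mean": res.mean(axis=0),
            "p5": np.percentile(res, 5, axis=0),
            "p95": np.percentile(res, 95, axis=0),
        },
        index=pd.Index(years, name="year"),
    )
    return UncertaintyResult(
        table=table,
        achieved_correlation=mean_group_spearman(draws, spec),
        n_failures=failures,
        iterations=spec.iterations,
    )
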