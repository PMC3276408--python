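"""Triangular CI calibration, LHS stratification, correlation induction."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hwpcarbon.uncertainty import (
    MonteCarloSpec,
    TriangularVar,
    UncertaintyError,
    lhs_sample,
    mean_group_spearman,
    percent_spread,
    run_uncertainty,
    default_uncertainty_variables,
    triangular_from_ci,
)


class TestTriangularFromCI:
    def test_percentile_matched_support(self):
        dist = triangular_from_ci(1.0, 0.30)
        b = 0.30 / (1 - math.sqrt(0.1))
        assert b == pytest.approx(0.4387, abs=1e-4)
        assert dist.ppf(0) == pytest.approx(1 - b)
        assert dist.ppf(1) == pytest.approx(1 + b)
        # the central 90 % interval is +/- 0.30 by construction:
        # triangular CDF (x + b)^2 / (2 b^2) = 0.05 at x = -0.30
        assert dist.cdf(0.70) == pytest.approx(0.05, abs=1e-12)
        assert dist.cdf(1.30) == pytest.approx(0.95, abs=1e-12)

    def test_bounds_equal_ci_support(self):
        dist = triangular_from_ci(1.0, 0.15, mode_convention="bounds_equal_ci")
        assert dist.ppf(0) == pytest.approx(0.85)
        assert dist.ppf(1) == pytest.approx(1.15)

    def test_symmetry_of_sampled_mean(self):
        dist = triangular_from_ci(1.0, 0.30)
        rng = np.random.default_rng(0)
        draws = dist.ppf(rng.random(100_000))
        assert draws.mean() == pytest.approx(1.0, abs=0.005)

    def test_negative_lower_bound_rejected(self):
        with pytest.raises(UncertaintyError, match="lower bound"):
            triangular_from_ci(1.0, 0.80)


class TestDefaultVariableSet:
    def test_eighteen_variables_fifteen_for_cfpp(self):
        variables = default_uncertainty_variables()
        assert len(variables) == 18
        assert sum(v.cfpp for v in variables) == 15
        excluded = {v.name for v in variables if not v.cfpp}
        assert excluded == {
            "discards_to_landfill", "landfill_decay_limits", "landfill_half_life"
        }

    def test_harvest_periods_and_halfwidths(self):
        by_name = {v.name: v for v in default_uncertainty_variables()}
        assert by_name["harvest_1906_1945"].ci90_halfwidth == 0.30
        assert by_name["harvest_1946_1979"].ci90_halfwidth == 0.20
        assert by_name["harvest_1980_2009"].ci90_halfwidth == 0.15
        assert by_name["ccf_mgc"].ci90_halfwidth == 0.05
        assert all(
            by_name[n].correlation_group == "harvest"
            for n in ("harvest_1906_1945", "harvest_1946_1979", "harvest_1980_2009")
        )


class TestLHS:
    def test_one_draw_per_quartile_bin(self):
        spec = MonteCarloSpec(
            variables=[TriangularVar("x", 0.30)], iterations=4, seed=1
        )
        draws = lhs_sample(spec)
        dist = triangular_from_ci(1.0, 0.30)
        u = dist.cdf(draws["x"].to_numpy())
        assert sorted(np.floor(u * 4).astype(int).tolist()) == [0, 1, 2, 3]

    def test_stratification_sup_norm_bound(self):
        n = 500
        spec = MonteCarloSpec(variables=default_uncertainty_variables(), iterations=n, seed=2)
        draws = lhs_sample(spec)
        for var in spec.variables:
            dist = triangular_from_ci(1.0, var.ci90_halfwidth)
            x = np.sort(draws[var.name].to_numpy())
            ecdf_hi = np.arange(1, n + 1) / n
            ecdf_lo = np.arange(0, n) / n
            cdf = dist.cdf(x)
            sup = max(np.abs(ecdf_hi - cdf).max(), np.abs(ecdf_lo - cdf).max())
            assert sup <= 1.0 / n + 1e-12, var.name

    def test_grouped_spearman_near_target_at_2200(self):
        spec = MonteCarloSpec(variables=default_uncertainty_variables(), iterations=2200, seed=3)
        draws = lhs_sample(spec)
        achieved = mean_group_spearman(draws, spec)
        assert 0.45 <= achieved["harvest"] <= 0.55

    def test_ungrouped_variables_stay_uncorrelated(self):
        spec = MonteCarloSpec(variables=default_uncertainty_variables(), iterations=2200, seed=4)
        draws = lhs_sample(spec)
        rho = stats.spearmanr(draws["ccf_mgc"], draws["lumber_to_new_housing"]).statistic
        assert abs(rho) < 0.1

    def test_same_seed_reproducible(self):
        spec = MonteCarloSpec(variables=default_uncertainty_variables(), iterations=64, seed=5)
        pd.testing.assert_frame_equal(lhs_sample(spec), lhs_sample(spec))


class TestRunUncertainty:
    def test_degenerate_halfwidths_collapse_to_deterministic(self):
        variables = [TriangularVar("a", 0.0), TriangularVar("b", 0.0)]
        spec = MonteCarloSpec(variables=variables, iterations=16, seed=0)

        def pipeline(draws):
            return pd.Series({2000: 10.0 * draws["a"] * draws["b"]})

        result = run_uncertainty(pipeline, spec, years=[2000])
        row = result.table.loc[2000]
        assert row["p5"] == row["mean"] == row["p95"] == 10.0

    def test_failures_tracked_and_capped(self):
        spec = MonteCarloSpec(
            variables=[TriangularVar("a", 0.30)], iterations=50, seed=0
        )

        def flaky(draws):
            if draws["a"] > 1.0:
                raise RuntimeError("boom")
            return pd.Series({2000: draws["a"]})

        with pytest.raises(UncertaintyError, match="failed"):
            run_uncertainty(flaky, spec, years=[2000])

    def test_monotone_response_to_harvest_multiplier(self, figure3_records, params):
        """Inflating harvest alone never decreases any year's total stock."""
        from hwpcarbon.pipeline import run_production

        base = run_production(
            figure3_records, params, draws={"harvest_1946_1979": 1.0}
        ).report.table["total_hwp"]
        up = run_production(
            figure3_records, params, draws={"harvest_1946_1979": 1.2}
        ).report.table["total_hwp"]
        assert (up >= base - 1e-9).all()
        assert up.loc[1970] > base.loc[1970]


class TestPercentSpread:
    def test_printed_interval_arithmetic(self):
        row = {"mean": 28_272_940.0, "p5": 20_723_740.0, "p95": 37_108_160.0}
        lo, hi = percent_spread(row)
        assert lo == pytest.approx(-26.7, abs=0.05)
        assert hi == pytest.approx(31.2, abs=0.05)

    def test_symmetric_interval(self):
        lo, hi = percent_spread({"mean": 100.0, "p5": 80.0, "p95": 120.0})
        assert lo == -hi == -20.0

    def test_zero_mean_rejected(self):
        with pytest.raises(UncertaintyError):
            percent_spread({"mean": 0.0, "p5": -1.0, "p95": 1.0})
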