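"""Catch/cost/revenue accounting, NPV, and the Monte Carlo engine."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penshell import (
    CostStructure,
    EquilibriumModel,
    MarketParams,
    ModelOptions,
    SimulationConfig,
    ValidationError,
    annual_cash_flow,
    catch_from_harvest,
    discount_sensitivity,
    expected_npv,
    npv,
    npv_mxn,
    run_monte_carlo,
    total_fixed_cost,
    variable_cost,
)
from penshell.presets import STUDY_EQUILIBRIA, calibrated_options, study_equilibrium

COSTS = CostStructure()
MARKET = MarketParams()


class TestCatch:
    @pytest.mark.parametrize(
        "H,F,CF,expected",
        [(35.0, 0.2, 0.25, 1750.0), (0.0, 0.2, 0.25, 0.0), (1.0, 1.0, 1.0, 1000.0)],
    )
    def test_muscle_catch(self, H, F, CF, expected):
        assert catch_from_harvest(H, F, CF) == pytest.approx(expected)

    def test_whole_animal_accounting_skips_conversion(self):
        assert catch_from_harvest(35.0, 0.2, 0.25, "price_on_whole") == pytest.approx(7000.0)

    def test_negative_harvest_rejected(self):
        with pytest.raises(ValidationError):
            catch_from_harvest(-1.0, 0.2, 0.25)


class TestCosts:
    def test_unused_boat_leaves_operational_costs_only(self):
        cs = CostStructure(
            operational_items=(("permits", 1000.0),),
            boat_items=(("engine", 500.0),),
            boat_usage_fraction=0.0,
        )
        assert total_fixed_cost(cs) == pytest.approx(1000.0)

    def test_boat_costs_weighted_by_usage(self):
        cs = CostStructure(
            operational_items=(("a", 100.0), ("b", 200.0)),
            boat_items=(("boat", 1000.0),),
            boat_usage_fraction=0.5,
        )
        assert total_fixed_cost(cs) == pytest.approx(800.0)

    def test_study_fixed_cost_is_preweighted_single_item(self):
        assert total_fixed_cost(COSTS) == pytest.approx(127_752.0)

    def test_variable_cost_arithmetic(self):
        # 1750 kg at 25 kg/trip -> 70 trips at MX$220 plus MX$0.80/kg
        assert variable_cost(1750.0, COSTS) == pytest.approx(70 * 220 + 1750 * 0.8)
        assert variable_cost(0.0, COSTS) == 0.0

    def test_variable_cost_linear_in_catch(self):
        assert variable_cost(3500.0, COSTS) == pytest.approx(2 * variable_cost(1750.0, COSTS))

    def test_ceil_trips_rounds_up(self):
        cs = CostStructure(cpue=25.0)
        assert variable_cost(10.0, cs, trips="ceil") == pytest.approx(220.0 + 8.0)


class TestCashFlow:
    def test_closed_fishery_year_burns_fixed_cost(self):
        flow = annual_cash_flow(0.0, 0.2, COSTS, MARKET)
        assert flow.revenue == 0.0 and flow.tax == 0.0
        assert flow.net == pytest.approx(-total_fixed_cost(COSTS))

    def test_study_scenario_revenue(self):
        # 35 t -> 1750 kg muscle at MX$200/kg
        flow = annual_cash_flow(35.0, 0.2, COSTS, MARKET)
        assert flow.revenue == pytest.approx(350_000.0)
        assert flow.total_cost == pytest.approx(127_752.0 + 16_800.0)
        profit = flow.revenue - flow.total_cost - 0.10 * 390_000.0
        assert flow.tax == pytest.approx(0.15 * profit)

    def test_conversion_factor_applied_exactly_once_by_default(self):
        once = annual_cash_flow(35.0, 0.2, COSTS, MARKET, ModelOptions())
        twice = annual_cash_flow(35.0, 0.2, COSTS, MARKET, ModelOptions(cf_application="twice"))
        assert twice.revenue == pytest.approx(once.revenue * MARKET.conversion_factor)

    def test_whole_animal_pricing(self):
        flow = annual_cash_flow(
            35.0, 0.2, COSTS, MARKET, ModelOptions(cf_application="price_on_whole")
        )
        assert flow.revenue == pytest.approx(7000.0 * 200.0)

    def test_revenue_tax_base(self):
        flow = annual_cash_flow(
            35.0, 0.2, COSTS, MARKET, ModelOptions(tax_base="revenue")
        )
        assert flow.tax == pytest.approx(0.15 * flow.revenue)

    @settings(max_examples=60, deadline=None)
    @given(H=st.floats(0.0, 200.0))
    def test_tax_never_negative(self, H):
        flow = annual_cash_flow(H, 0.2, COSTS, MARKET)
        assert flow.tax >= 0.0


class TestNPV:
    def test_undiscounted_sum_minus_investment(self):
        assert npv_mxn([100.0] * 10, 0.0, 390.0) == pytest.approx(610.0)

    def test_matches_annuity_closed_form(self):
        r, f, n, inv = 0.10, 180_000.0, 10, 390_000.0
        annuity = f * (1 - (1 + r) ** -n) / r
        assert npv_mxn([f] * n, r, inv) == pytest.approx(annuity - inv)

    def test_strictly_decreasing_in_rate_for_positive_flows(self):
        flows = [50_000.0] * 10
        values = [npv_mxn(flows, r, 10_000.0) for r in (0.0, 0.1, 0.2, 0.3)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_literal_indexing_leaves_first_flow_undiscounted(self):
        assert npv_mxn([110.0], 0.10, 0.0) == pytest.approx(100.0)
        assert npv_mxn([110.0], 0.10, 0.0, horizon_indexing="literal") == pytest.approx(110.0)

    def test_thousand_usd_conversion(self):
        value = npv([16_820.0], 0.0, 0.0, usd_per_mxn=1 / 16.82)
        assert value == pytest.approx(1.0)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValidationError):
            npv_mxn([1.0], -1.5, 0.0)


class TestMonteCarlo:
    def test_degenerate_sigma_gives_zero_variance(self):
        model = EquilibriumModel(mu=35.0, sigma=0.0)
        result = run_monte_carlo(model, COSTS, MARKET, SimulationConfig(n_runs=200, seed=5))
        assert result.summary.sd == pytest.approx(0.0)
        assert np.all(result.per_run_npv == result.per_run_npv[0])
        assert result.summary.mean == pytest.approx(
            expected_npv(model, COSTS, MARKET, SimulationConfig(seed=5))
        )

    def test_reproducible_under_seed(self):
        model = study_equilibrium(1)
        cfg = SimulationConfig(n_runs=100, seed=11)
        a = run_monte_carlo(model, COSTS, MARKET, cfg)
        b = run_monte_carlo(model, COSTS, MARKET, cfg)
        assert np.array_equal(a.per_run_npv, b.per_run_npv)

    def test_mean_matches_closed_form_when_flows_linear(self):
        """With revenue-based tax the yearly flow is linear in H, so the
        Monte Carlo mean must match the analytic expectation within 3 SE."""
        model = study_equilibrium(1)
        cfg = SimulationConfig(n_runs=2000, seed=17)
        options = ModelOptions(tax_base="revenue")
        result = run_monte_carlo(model, COSTS, MARKET, cfg, options)
        closed = expected_npv(model, COSTS, MARKET, cfg, options)
        se = result.summary.sd / np.sqrt(cfg.n_runs)
        assert abs(result.summary.mean - closed) < 3 * se

    def test_summary_matches_independent_recomputation(self):
        result = run_monte_carlo(
            study_equilibrium(2), COSTS, MARKET, SimulationConfig(n_runs=300, seed=2)
        )
        runs = result.per_run_npv
        s = result.summary
        assert s.min == runs.min() and s.max == runs.max()
        assert s.mean == pytest.approx(runs.sum() / runs.size, rel=1e-12)
        assert s.median == pytest.approx(float(np.median(runs)))
        assert s.sd == pytest.approx(float(np.std(runs, ddof=1)))
        assert s.q025 <= s.median <= s.q975

    def test_price_level_homogeneity(self):
        """Scaling every price-dimension parameter by k scales NPV by k."""
        k = 3.0
        cfg = SimulationConfig(n_runs=50, seed=9)
        model = study_equilibrium(1)
        base = run_monte_carlo(model, COSTS, MARKET, cfg)
        scaled_costs = CostStructure(
            operational_items=tuple((lbl, k * c) for lbl, c in COSTS.operational_items),
            cost_per_trip=k * COSTS.cost_per_trip,
            cost_per_kg=k * COSTS.cost_per_kg,
            initial_investment=k * COSTS.initial_investment,
        )
        scaled_market = dataclasses.replace(MARKET, price_per_kg=k * MARKET.price_per_kg)
        scaled = run_monte_carlo(model, scaled_costs, scaled_market, cfg)
        assert scaled.per_run_npv == pytest.approx(k * base.per_run_npv)

    def test_mean_npv_monotone_in_price_and_biomass_and_costs(self):
        cfg = SimulationConfig(n_runs=200, seed=21)
        model = study_equilibrium(1)
        base = run_monte_carlo(model, COSTS, MARKET, cfg).summary.mean
        richer = run_monte_carlo(
            model, COSTS, dataclasses.replace(MARKET, price_per_kg=250.0), cfg
        ).summary.mean
        bigger_stock = run_monte_carlo(
            dataclasses.replace(model, mu=45.0), COSTS, MARKET, cfg
        ).summary.mean
        dearer = run_monte_carlo(
            model, dataclasses.replace(COSTS, cost_per_trip=500.0), cfg=cfg, mp=MARKET
        ).summary.mean
        assert richer > base and bigger_stock > base and dearer < base


class TestDiscountSensitivity:
    def test_profitable_scenario_decreases_with_rate(self):
        model = study_equilibrium(1)
        results = discount_sensitivity(
            model, COSTS, MARKET, SimulationConfig(n_runs=400, seed=31),
            options=calibrated_options(),
        )
        means = [results[r].summary.mean for r in sorted(results)]
        assert means[0] > 0
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_loss_making_scenario_rises_toward_zero(self):
        model = study_equilibrium(3)
        results = discount_sensitivity(
            model, COSTS, MARKET, SimulationConfig(n_runs=400, seed=31)
        )
        means = [results[r].summary.mean for r in sorted(results)]
        assert all(m < 0 for m in means)
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_single_rate_consistent_with_run_monte_carlo(self):
        model = study_equilibrium(2)
        cfg = SimulationConfig(n_runs=150, seed=13)
        sweep = discount_sensitivity(model, COSTS, MARKET, cfg, rates=[0.10])
        direct = run_monte_carlo(model, COSTS, MARKET, cfg)
        assert np.array_equal(sweep[0.10].per_run_npv, direct.per_run_npv)

    def test_empty_rates_rejected(self):
        with pytest.raises(ValidationError):
            discount_sensitivity(
                study_equilibrium(1), COSTS, MARKET, SimulationConfig(n_runs=10, seed=1), rates=[]
            )


def test_study_equilibria_registry():
    assert set(STUDY_EQUILIBRIA) == {1, 2, 3, 4}
    model = study_equilibrium(1)
    assert (model.mu, model.sigma, model.fishing_mortality) == (35.0, 16.0, 0.20)
    with pytest.raises(KeyError):
        study_equilibrium(7)
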