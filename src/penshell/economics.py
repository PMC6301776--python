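"""Catch, cost, revenue, tax and discounted net-present-value model.

Yearly catch is a fixed fraction F of the harvestable biomass drawn by the
equilibrium projection, converted to sellable product.  Costs split into a
yearly fixed block (operational items plus boat items weighted by the
fraction of boat capacity the fishery uses) and a variable block driven by
effort (trips = catch / CPUE, at a cost per trip) and by catch handling (a
cost per kg).  Net yearly cash flows, after tax, are discounted over the
simulation horizon and netted against the initial investment; results are
reported in thousand USD at a fixed exchange rate.

Several readings of the product/revenue accounting are possible because
the muscle-yield conversion can be applied at the catch stage, at the
pricing stage, or not at all (pricing whole animals); the tax base and the
treatment of depreciation are similarly underdetermined in practice.  Each
choice is an explicit switch on :class:`ModelOptions` so that scenario
files state exactly which accounting they use.

The Monte Carlo engine runs ``n_runs`` independent multi-year projections
(one spawned random stream per run) and summarizes the per-run NPVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ValidationError
from .projection import EquilibriumModel, clamped_normal_mean, project_harvest

KG_PER_TON = 1000.0

#: MXN per USD (Banamex, April 2016) used to report NPVs in thousand USD.
DEFAULT_MXN_PER_USD = 16.82

CF_APPLICATIONS = ("once", "twice", "price_on_whole")
TAX_BASES = ("profit", "revenue")
HORIZON_INDEXINGS = ("investment_year_zero", "literal")
TRIP_MODES = ("continuous", "ceil")


@dataclass(frozen=True)
class CostStructure:
    """Cost side of the fishery, all amounts in MXN.

    ``operational_items`` are yearly operational costs (permits,
    monitoring, enforcement, maintenance); ``boat_items`` are yearly
    boat-availability costs charged in proportion to
    ``boat_usage_fraction``, the share of boat capacity the fishery uses.
    The defaults carry the La Paz pen-shell parameterization: a single
    fixed-cost line of MX$127,752/yr (already boat-usage weighted),
    MX$220 per trip, MX$0.80 per kg of catch, CPUE of 25 kg per trip,
    MX$390,000 of initial investment, 10% straight-line depreciation and a
    15% tax rate.
    """

    operational_items: tuple[tuple[str, float], ...] = (
        ("permits, monitoring, enforcement and maintenance (boat-usage weighted)", 127752.0),
    )
    boat_items: tuple[tuple[str, float], ...] = ()
    boat_usage_fraction: float = 1.0
    cost_per_trip: float = 220.0
    cost_per_kg: float = 0.80
    cpue: float = 25.0
    initial_investment: float = 390000.0
    depreciation_rate: float = 0.10
    tax_rate: float = 0.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "operational_items", tuple((str(k), float(v)) for k, v in self.operational_items))
        object.__setattr__(self, "boat_items", tuple((str(k), float(v)) for k, v in self.boat_items))
        for label, cost in (*self.operational_items, *self.boat_items):
            if cost < 0:
                raise ValidationError(f"cost item {label!r} must be >= 0, got {cost}")
        if not 0 <= self.boat_usage_fraction <= 1:
            raise ValidationError(f"boat_usage_fraction must be in [0, 1], got {self.boat_usage_fraction}")
        if self.cpue <= 0:
            raise ValidationError(f"cpue must be > 0, got {self.cpue}")
        for name in ("cost_per_trip", "cost_per_kg", "initial_investment", "depreciation_rate", "tax_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class MarketParams:
    """Market side: ex-vessel price (MXN per kg of product), muscle yield
    as a fraction of whole-animal weight, and the USD value of one MXN."""

    price_per_kg: float = 200.0
    conversion_factor: float = 0.25
    usd_per_mxn: float = 1.0 / DEFAULT_MXN_PER_USD

    def __post_init__(self) -> None:
        if self.price_per_kg <= 0:
            raise ValidationError(f"price_per_kg must be > 0, got {self.price_per_kg}")
        if not 0 < self.conversion_factor <= 1:
            raise ValidationError(f"conversion_factor must be in (0, 1], got {self.conversion_factor}")
        if self.usd_per_mxn <= 0:
            raise ValidationError(f"usd_per_mxn must be > 0, got {self.usd_per_mxn}")


@dataclass(frozen=True)
class ModelOptions:
    """Accounting switches spanning the defensible readings of the model.

    cf_application
        Where the muscle conversion factor enters: ``"once"`` (catch is
        muscle mass, priced per kg of muscle — the default), ``"twice"``
        (also multiplied into revenue) or ``"price_on_whole"`` (catch and
        price are on whole-animal weight; the conversion never applies).
    tax_base
        ``"profit"`` taxes max(0, revenue - costs - depreciation);
        ``"revenue"`` taxes gross revenue.
    include_depreciation
        Whether the straight-line depreciation charge shields profit tax.
    horizon_indexing
        ``"investment_year_zero"``: investment at year 0, operating years
        1..horizon.  ``"literal"``: operating years 0..horizon (horizon+1
        flows, the first undiscounted) with the investment still at year 0.
    trips
        Effort is catch/CPUE, either fractional (``"continuous"``) or
        rounded up per year (``"ceil"``).
    negative_draws
        Policy for negative biomass draws, passed to the projection.
    """

    cf_application: str = "once"
    tax_base: str = "profit"
    include_depreciation: bool = True
    horizon_indexing: str = "investment_year_zero"
    trips: str = "continuous"
    negative_draws: str = "clamp"

    def __post_init__(self) -> None:
        for name, allowed in (
            ("cf_application", CF_APPLICATIONS),
            ("tax_base", TAX_BASES),
            ("horizon_indexing", HORIZON_INDEXINGS),
            ("trips", TRIP_MODES),
            ("negative_draws", ("clamp", "redraw")),
        ):
            if getattr(self, name) not in allowed:
                raise ValidationError(f"{name} must be one of {allowed}, got {getattr(self, name)!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo design: horizon (years), discount rate, sensitivity
    sweep, number of runs and root seed."""

    horizon: int = 10
    discount_rate: float = 0.10
    sensitivity_rates: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40, 0.50)
    n_runs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValidationError(f"horizon must be >= 1, got {self.horizon}")
        if not 0 <= self.discount_rate < 1:
            raise ValidationError(f"discount_rate must be in [0, 1), got {self.discount_rate}")
        if self.n_runs < 1:
            raise ValidationError(f"n_runs must be >= 1, got {self.n_runs}")


class CashFlow(NamedTuple):
    """One operating year in MXN."""

    revenue: float
    total_cost: float
    tax: float
    net: float


@dataclass(frozen=True)
class NPVSummary:
    min: float
    mean: float
    max: float
    sd: float
    median: float
    q025: float
    q975: float


@dataclass(frozen=True)
class NPVResult:
    """Per-run NPVs (thousand USD) of one Monte Carlo scenario."""

    scenario_id: str
    per_run_npv: np.ndarray
    summary: NPVSummary = field(init=False)

    def __post_init__(self) -> None:
        runs = np.asarray(self.per_run_npv, dtype=float)
        object.__setattr__(self, "per_run_npv", runs)
        object.__setattr__(self, "summary", summarize_npv(runs))


def summarize_npv(per_run_npv: np.ndarray) -> NPVSummary:
    runs = np.asarray(per_run_npv, dtype=float)
    return NPVSummary(
        min=float(runs.min()),
        mean=float(runs.mean()),
        max=float(runs.max()),
        sd=float(runs.std(ddof=1)) if runs.size > 1 else 0.0,
        median=float(np.median(runs)),
        q025=float(np.quantile(runs, 0.025)),
        q975=float(np.quantile(runs, 0.975)),
    )


def catch_from_harvest(H, F: float, CF: float, cf_application: str = "once"):
    """Yearly catch (kg of product) from harvestable biomass H (tons).

    Under ``"once"``/``"twice"`` the catch is muscle mass, H*F*CF; under
    ``"price_on_whole"`` the catch is whole-animal mass, H*F.
    """
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValidationError("harvestable biomass must be >= 0")
    kg = H * F * KG_PER_TON
    if cf_application != "price_on_whole":
        kg = kg * CF
    return float(kg) if kg.ndim == 0 else kg


def total_fixed_cost(cs: CostStructure) -> float:
    """Yearly fixed cost: operational items plus boat items scaled by the
    boat-usage fraction."""
    ofc = sum(cost for _, cost in cs.operational_items)
    vfc = sum(cost for _, cost in cs.boat_items) * cs.boat_usage_fraction
    return ofc + vfc


def variable_cost(C, cs: CostStructure, trips: str = "continuous"):
    """Yearly variable cost (MXN) of landing C kg of catch: effort cost
    (trips at ``cost_per_trip``) plus handling cost (``cost_per_kg``)."""
    C = np.asarray(C, dtype=float)
    effort = C / cs.cpue
    if trips == "ceil":
        effort = np.ceil(effort)
    vc = effort * cs.cost_per_trip + C * cs.cost_per_kg
    return float(vc) if vc.ndim == 0 else vc


def annual_cash_flow(
    H,
    F: float,
    cs: CostStructure,
    mp: MarketParams,
    options: ModelOptions = ModelOptions(),
) -> CashFlow:
    """Revenue, total cost, tax and net cash flow (MXN) of one operating
    year with harvestable biomass H (tons).  Accepts arrays of H."""
    C = catch_from_harvest(H, F, mp.conversion_factor, options.cf_application)
    revenue = np.asarray(C) * mp.price_per_kg
    if options.cf_application == "twice":
        revenue = revenue * mp.conversion_factor
    total_cost = total_fixed_cost(cs) + variable_cost(C, cs, options.trips)
    depreciation = cs.depreciation_rate * cs.initial_investment if options.include_depreciation else 0.0
    if options.tax_base == "profit":
        tax = cs.tax_rate * np.maximum(0.0, revenue - total_cost - depreciation)
    else:
        tax = cs.tax_rate * revenue
    net = revenue - total_cost - tax
    if np.ndim(net) == 0:
        return CashFlow(float(revenue), float(total_cost), float(tax), float(net))
    return CashFlow(revenue, np.broadcast_to(total_cost, net.shape), tax, net)


def _discount_factors(n_flows: int, r: float, horizon_indexing: str) -> np.ndarray:
    if horizon_indexing == "literal":
        years = np.arange(0, n_flows)
    else:
        years = np.arange(1, n_flows + 1)
    return (1.0 + r) ** (-years)


def npv_mxn(
    cash_flows: Sequence[float] | np.ndarray,
    r: float,
    initial_investment: float,
    horizon_indexing: str = "investment_year_zero",
) -> float:
    """Net present value in MXN of yearly net flows against the initial
    investment (always charged at year 0).  ``cash_flows`` may be a 2-D
    array (runs x years), in which case one NPV per run is returned."""
    if r <= -1:
        raise ValidationError(f"discount rate must be > -1, got {r}")
    flows = np.asarray(cash_flows, dtype=float)
    factors = _discount_factors(flows.shape[-1], r, horizon_indexing)
    discounted = flows @ factors
    result = -initial_investment + discounted
    return float(result) if np.ndim(result) == 0 else result


def npv(
    cash_flows,
    r: float,
    initial_investment: float,
    usd_per_mxn: float = 1.0 / DEFAULT_MXN_PER_USD,
    horizon_indexing: str = "investment_year_zero",
):
    """NPV in thousand USD (flows and investment given in MXN)."""
    value = npv_mxn(cash_flows, r, initial_investment, horizon_indexing)
    return value * usd_per_mxn / 1000.0


def _harvest_matrix(
    model: EquilibriumModel, cfg: SimulationConfig, options: ModelOptions
) -> np.ndarray:
    """One row of annual harvestable-biomass draws per Monte Carlo run.

    Each run owns a child stream spawned deterministically from the root
    seed, so runs are independent and the whole matrix is reproducible.
    """
    n_years = cfg.horizon + 1 if options.horizon_indexing == "literal" else cfg.horizon
    root = np.random.SeedSequence(cfg.seed)
    rows = [
        project_harvest(model, n_years, np.random.default_rng(child), options.negative_draws)
        for child in root.spawn(cfg.n_runs)
    ]
    return np.vstack(rows)


def run_monte_carlo(
    model: EquilibriumModel,
    cs: CostStructure,
    mp: MarketParams,
    cfg: SimulationConfig,
    options: ModelOptions = ModelOptions(),
    scenario_id: str = "scenario",
    harvest_draws: np.ndarray | None = None,
) -> NPVResult:
    """Monte Carlo NPV distribution of a scenario.

    Runs ``cfg.n_runs`` independent multi-year harvest projections, maps
    each year through the cash-flow model, discounts at
    ``cfg.discount_rate`` and reports per-run NPVs in thousand USD.
    ``harvest_draws`` may be supplied to reuse a draw matrix (common random
    numbers across discount rates).
    """
    H = _harvest_matrix(model, cfg, options) if harvest_draws is None else np.asarray(harvest_draws)
    flow = annual_cash_flow(H, model.fishing_mortality, cs, mp, options)
    per_run = npv(
        flow.net, cfg.discount_rate, cs.initial_investment, mp.usd_per_mxn, options.horizon_indexing
    )
    return NPVResult(scenario_id=scenario_id, per_run_npv=np.atleast_1d(per_run))


def expected_npv(
    model: EquilibriumModel,
    cs: CostStructure,
    mp: MarketParams,
    cfg: SimulationConfig,
    options: ModelOptions = ModelOptions(),
) -> float:
    """Closed-form expected NPV (thousand USD), valid when the cash flow is
    linear in H over the support of the draws (continuous trips and a
    non-binding profit-tax clamp, or revenue-based tax).

    The yearly flow is then flow(E[H_effective]), where the effective
    harvest mean accounts for the negative-draw policy, and the NPV is the
    corresponding annuity minus the investment.
    """
    if options.negative_draws == "clamp":
        eh = clamped_normal_mean(model.mu, model.sigma)
    elif model.sigma == 0:
        eh = model.mu
    else:  # redraw == truncation at zero
        from scipy import stats

        z = model.mu / model.sigma
        eh = model.mu + model.sigma * stats.norm.pdf(z) / stats.norm.cdf(z)
    flow = annual_cash_flow(eh, model.fishing_mortality, cs, mp, options)
    n_flows = cfg.horizon + 1 if options.horizon_indexing == "literal" else cfg.horizon
    flows = np.full(n_flows, flow.net)
    return npv(flows, cfg.discount_rate, cs.initial_investment, mp.usd_per_mxn, options.horizon_indexing)


def discount_sensitivity(
    model: EquilibriumModel,
    cs: CostStructure,
    mp: MarketParams,
    cfg: SimulationConfig,
    rates: Sequence[float] | None = None,
    options: ModelOptions = ModelOptions(),
    scenario_id: str = "scenario",
) -> dict[float, NPVResult]:
    """One Monte Carlo per discount rate, sharing the harvest draw matrix
    across rates so the curves differ only by discounting."""
    rates = tuple(cfg.sensitivity_rates if rates is None else rates)
    if not rates:
        raise ValidationError("rates must be non-empty")
    draws = _harvest_matrix(model, cfg, options)
    results: dict[float, NPVResult] = {}
    for r in rates:
        rate_cfg = replace(cfg, discount_rate=r)
        results[r] = run_monte_carlo(
            model, cs, mp, rate_cfg, options,
            scenario_id=f"{scenario_id}@r={r:g}", harvest_draws=draws,
        )
    return results
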