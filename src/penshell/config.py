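"""YAML scenario files: loading, validation, and round-trip writing.

A scenario file groups the model inputs into sections mirroring the
domain types::

    name: scenario-1
    equilibrium: {mu: 35, sigma: 16, fishing_mortality: 0.20}
    costs:
      operational_items: [["permits and monitoring", 127752.0]]
      cost_per_trip: 220.0
    market: {price_per_kg: 200.0}
    simulation: {horizon: 10, discount_rate: 0.10, n_runs: 1000, seed: 0}
    options: {cf_application: once, tax_base: profit}

Every section and key is optional; omitted keys take the bundled La Paz
defaults.  Unknown keys raise :class:`~penshell.errors.ConfigError` naming
the offending key.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .economics import CostStructure, MarketParams, ModelOptions, SimulationConfig
from .errors import ConfigError, ValidationError
from .projection import EquilibriumModel

_SECTIONS = {
    "equilibrium": EquilibriumModel,
    "costs": CostStructure,
    "market": MarketParams,
    "simulation": SimulationConfig,
    "options": ModelOptions,
}


@dataclass(frozen=True)
class Scenario:
    """One fully specified simulation scenario."""

    name: str = "scenario"
    equilibrium: EquilibriumModel = field(default_factory=lambda: EquilibriumModel(0.0, 0.0))
    costs: CostStructure = field(default_factory=CostStructure)
    market: MarketParams = field(default_factory=MarketParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    options: ModelOptions = field(default_factory=ModelOptions)


def _build(cls, mapping: dict[str, Any], section: str):
    if not isinstance(mapping, dict):
        raise ConfigError(f"section {section!r} must be a mapping, got {type(mapping).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in section {section!r}: {', '.join(sorted(unknown))}")
    kwargs = dict(mapping)
    for key in ("operational_items", "boat_items"):
        if key in kwargs:
            try:
                kwargs[key] = tuple((str(k), float(v)) for k, v in kwargs[key])
            except (TypeError, ValueError) as err:
                raise ConfigError(f"{section}.{key} must be a list of [label, cost] pairs") from err
    if "sensitivity_rates" in kwargs:
        kwargs["sensitivity_rates"] = tuple(float(r) for r in kwargs["sensitivity_rates"])
    try:
        return cls(**kwargs)
    except (ValidationError, TypeError) as err:
        raise ConfigError(f"invalid section {section!r}: {err}") from err


def scenario_from_dict(raw: dict[str, Any], name: str | None = None) -> Scenario:
    if not isinstance(raw, dict):
        raise ConfigError(f"scenario document must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SECTIONS) - {"name"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    parts = {
        section: _build(cls, raw.get(section, {}) or {}, section)
        for section, cls in _SECTIONS.items()
    }
    return Scenario(name=str(name or raw.get("name", "scenario")), **parts)


def load_scenario(path) -> Scenario:
    """Read and validate one scenario YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return scenario_from_dict(raw)


def scenario_to_dict(scenario: Scenario) -> dict[str, Any]:
    out: dict[str, Any] = {"name": scenario.name}
    for section in _SECTIONS:
        data = dataclasses.asdict(getattr(scenario, section))
        for key in ("operational_items", "boat_items"):
            if key in data:
                data[key] = [list(item) for item in data[key]]
        if "sensitivity_rates" in data:
            data["sensitivity_rates"] = list(data["sensitivity_rates"])
        out[section] = data
    return out


def dump_scenario(scenario: Scenario, path) -> None:
    """Write a scenario YAML that :func:`load_scenario` reads back equal."""
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)
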