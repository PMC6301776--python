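"""Stochastic equilibrium projection of harvestable biomass.

The stock is assumed stationary at the level of the last survey: each
year's harvestable biomass H is an independent draw from N(mu, sigma^2),
where mu and sigma come from a biomass estimate (or are set directly for a
scenario).  Negative draws are clamped to zero by default — biomass cannot
be negative — which slightly raises the effective mean when sigma/mu is
large; a redraw policy is available instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class EquilibriumModel:
    """Equilibrium harvestable biomass (tons) and the exploitation rate.

    ``fishing_mortality`` is the fixed fraction of harvestable biomass
    removed each year (0.20 per Mexican guidance for this fishery).
    """

    mu: float
    sigma: float
    fishing_mortality: float = 0.20

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValidationError(f"mu must be >= 0, got {self.mu}")
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")
        if not 0 < self.fishing_mortality <= 1:
            raise ValidationError(
                f"fishing_mortality must be in (0, 1], got {self.fishing_mortality}"
            )


def draw_annual_harvestable(
    model: EquilibriumModel, rng: np.random.Generator, negative_draws: str = "clamp"
) -> float:
    """One year's harvestable biomass (tons), drawn from N(mu, sigma^2)."""
    return float(project_harvest(model, 1, rng, negative_draws)[0])


def project_harvest(
    model: EquilibriumModel,
    horizon: int,
    rng: np.random.Generator,
    negative_draws: str = "clamp",
) -> np.ndarray:
    """Sequence of ``horizon`` independent annual harvestable-biomass draws.

    ``negative_draws`` selects how impossible negative values are handled:
    ``"clamp"`` truncates them at zero (default, reproducible in a fixed
    number of variates), ``"redraw"`` rejects and redraws.
    """
    if horizon < 1:
        raise ValidationError(f"horizon must be >= 1, got {horizon}")
    draws = rng.normal(model.mu, model.sigma, size=horizon)
    if negative_draws == "clamp":
        return np.maximum(draws, 0.0)
    if negative_draws == "redraw":
        while True:
            bad = draws < 0
            if not bad.any():
                return draws
            draws[bad] = rng.normal(model.mu, model.sigma, size=int(bad.sum()))
    raise ValueError(f"negative_draws must be 'clamp' or 'redraw', got {negative_draws!r}")


def clamped_normal_mean(mu: float, sigma: float) -> float:
    """Expectation of max(X, 0) for X ~ N(mu, sigma^2).

    Closed form: mu * Phi(mu/sigma) + sigma * phi(mu/sigma).  Used as the
    analytic reference for the clamped draw and for linear expected-value
    oracles downstream.
    """
    if sigma == 0:
        return max(mu, 0.0)
    z = mu / sigma
    return mu * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)
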