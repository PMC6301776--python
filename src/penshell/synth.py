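"""Synthetic quadrat-campaign generator with known ground truth.

Emulates the features of a fisher-run pen-shell monitoring campaign that
matter for the estimator: strongly overdispersed per-quadrat abundance
with rare high-density patches (a negative-binomial baseline times a
Bernoulli patch state), a unimodal shell-length distribution straddling
the 14 cm legal limit (normal truncated at zero), and the measurement
protocol that records shell lengths for at most ``measurement_cap``
individuals per quadrat and only counts the rest.

The generator returns both the campaign (in the survey CSV schema) and a
:class:`GroundTruth` carrying the exact realized biomass per year, so the
whole estimation pipeline can be validated against known answers; the
distribution-level expectations needed for bias and CI-coverage studies
are available from :func:`expected_biomass`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import integrate, stats

from .biomass import AllometricParams, GRAMS_PER_TON, LEGAL_MIN_LENGTH
from .errors import ValidationError
from .projection import EquilibriumModel
from .survey import (
    DEFAULT_HABITAT_AREA,
    MEASUREMENT_CAP,
    CampaignDataset,
    QuadratObservation,
    write_campaign,
)

#: Quadrat counts per monitoring year in the 2011-2014 La Paz campaign.
STUDY_QUADRAT_COUNTS = {2011: 116, 2012: 121, 2013: 130, 2014: 140}


@dataclass(frozen=True)
class SynthParams:
    """Study-condition defaults for the generator.

    Abundance: baseline mean of 20 individuals per 1-ha quadrat with
    negative-binomial dispersion k=1.5 (variance well above the mean, as
    patchily distributed sessile bivalves show), and 6% of quadrats in a
    patch state with 15x abundance — patches then exceed the 114-individual
    measurement cap, exercising the counting protocol.  Lengths: normal
    with mean 15 cm and sd 3 cm truncated at zero, so the 14 cm legal
    limit falls inside the bulk of the distribution.
    """

    years: tuple[int, ...] = (2011, 2012, 2013, 2014)
    n_quadrats_per_year: tuple[int, ...] = (116, 121, 130, 140)
    quadrat_area: float = 1.0
    density_mean: float = 20.0
    density_dispersion: float = 1.5
    high_density_fraction: float = 0.06
    high_density_multiplier: float = 15.0
    length_mean: float = 15.0
    length_sd: float = 3.0
    measurement_cap: int = MEASUREMENT_CAP
    allometry: AllometricParams = field(default_factory=AllometricParams)
    habitat_area: float = DEFAULT_HABITAT_AREA
    min_length: float = LEGAL_MIN_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.years) != len(self.n_quadrats_per_year):
            raise ValidationError("years and n_quadrats_per_year must have equal length")
        if not 0 <= self.high_density_fraction <= 1:
            raise ValidationError(
                f"high_density_fraction must be in [0, 1], got {self.high_density_fraction}"
            )
        for name in (
            "quadrat_area", "density_mean", "density_dispersion",
            "high_density_multiplier", "length_mean", "length_sd", "habitat_area",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.measurement_cap < 1:
            raise ValidationError(f"measurement_cap must be >= 1, got {self.measurement_cap}")


@dataclass(frozen=True)
class GroundTruth:
    """Exact realized biomass of a generated campaign, per year, in tons,
    extrapolated to the habitat area from the generated sample density."""

    total_biomass: dict[int, float]
    harvestable_biomass: dict[int, float]
    habitat_area: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _draw_lengths(n: int, params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    a = (0.0 - params.length_mean) / params.length_sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=params.length_mean, scale=params.length_sd, size=n, random_state=rng
    )


def generate_campaign(params: SynthParams) -> tuple[CampaignDataset, GroundTruth]:
    """Generate one campaign plus its exact ground truth.

    Every individual's length is drawn (so the realized biomass is known
    exactly) and only then is the measurement cap applied: the first
    ``measurement_cap`` individuals are recorded as measured, the rest
    collapse into the unmeasured count.
    """
    rng = np.random.default_rng(params.seed)
    k = params.density_dispersion
    observations: list[QuadratObservation] = []
    total_t: dict[int, float] = {}
    harv_t: dict[int, float] = {}

    for year, n_quadrats in zip(params.years, params.n_quadrats_per_year):
        year_weight = 0.0
        year_harv_weight = 0.0
        for q in range(n_quadrats):
            patch = rng.random() < params.high_density_fraction
            mean = params.density_mean * (params.high_density_multiplier if patch else 1.0)
            count = int(rng.negative_binomial(k, k / (k + mean)))
            lengths = _draw_lengths(count, params, rng)
            weights = params.allometry.a * lengths**params.allometry.b
            year_weight += float(weights.sum())
            year_harv_weight += float(weights[lengths >= params.min_length].sum())
            measured = lengths[: params.measurement_cap]
            counted = max(0, count - params.measurement_cap)
            if count == 0:
                # an empty quadrat still contributes a zero density
                measured = np.empty(0)
            observations.append(
                QuadratObservation(
                    quadrat_id=f"Q{q + 1:03d}",
                    year=year,
                    sampled_area=params.quadrat_area,
                    measured_lengths=tuple(np.round(measured, 2)),
                    counted_unmeasured=counted,
                    high_density=bool(patch),
                )
            )
        sampled_area = n_quadrats * params.quadrat_area
        scale = params.habitat_area / sampled_area / GRAMS_PER_TON
        total_t[year] = year_weight * scale
        harv_t[year] = year_harv_weight * scale

    dataset = CampaignDataset(tuple(observations), habitat_area=params.habitat_area)
    truth = GroundTruth(
        total_biomass=total_t, harvestable_biomass=harv_t, habitat_area=params.habitat_area
    )
    return dataset, truth


def write_synthetic_campaign(params: SynthParams, csv_path, truth_path=None) -> GroundTruth:
    """Generate a campaign and write it (CSV schema plus optional JSON
    ground-truth sidecar)."""
    dataset, truth = generate_campaign(params)
    write_campaign(dataset, csv_path)
    if truth_path is not None:
        truth.to_json(truth_path)
    return truth


def ground_truth_equilibrium(
    truth: GroundTruth, year: int, sd_fraction: float = 0.0
) -> EquilibriumModel:
    """Equilibrium model anchored at the true harvestable biomass of
    ``year``, with sigma a stated fraction of the mean."""
    if year not in truth.harvestable_biomass:
        raise KeyError(f"year {year} not present in ground truth")
    mu = truth.harvestable_biomass[year]
    return EquilibriumModel(mu=mu, sigma=sd_fraction * mu)


def mean_individual_weight(params: SynthParams) -> tuple[float, float]:
    """Distribution-level expectations of whole-animal weight (g): overall
    and restricted to the harvestable (>= min_length) fraction — i.e. the
    harvestable value is E[W * 1{L >= min_length}]."""
    dist = stats.truncnorm(
        (0.0 - params.length_mean) / params.length_sd, np.inf,
        loc=params.length_mean, scale=params.length_sd,
    )
    a, b = params.allometry.a, params.allometry.b

    def integrand(x: float) -> float:
        return a * x**b * dist.pdf(x)

    total, _ = integrate.quad(integrand, 0, params.length_mean + 12 * params.length_sd)
    harv, _ = integrate.quad(
        integrand, params.min_length, params.length_mean + 12 * params.length_sd
    )
    return total, harv


def expected_biomass(params: SynthParams) -> tuple[float, float]:
    """Theoretical (superpopulation) total and harvestable biomass in tons
    over the habitat area, the estimand for bias and coverage studies."""
    mean_count = params.density_mean * (
        1.0 + params.high_density_fraction * (params.high_density_multiplier - 1.0)
    )
    ew_total, ew_harv = mean_individual_weight(params)
    density = mean_count / params.quadrat_area  # individuals per ha
    total = density * ew_total * params.habitat_area / GRAMS_PER_TON
    harv = density * ew_harv * params.habitat_area / GRAMS_PER_TON
    return total, harv
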