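"""Size-structured biomass estimation from quadrat surveys.

Individual shell length is converted to whole-animal weight through the
allometric relationship ``W = a * L**b``.  Within each quadrat, individuals
that were only counted (after the measurement cap) inherit the measured
size structure, so the quadrat's gross weight is the measured weight scaled
by ``1 + counted / measured``.  Quadrat gross weights become densities
(g/ha), and the between-quadrat mean density — extrapolated to the stratum
area — yields the biomass estimate, with a normal-approximation 95%
confidence interval built on the standard error of the mean density.

Harvestable biomass restricts the computation to individuals at or above
the legal minimum shell length (14 cm); edible biomass applies the
muscle-to-whole-animal conversion factor (0.25) on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ExpansionError, ValidationError
from .survey import QuadratObservation, StratifiedCampaign

#: Legal minimum shell length (cm) defining harvestable individuals.
LEGAL_MIN_LENGTH = 14.0

#: Adductor-muscle yield as a fraction of whole-animal weight.
MUSCLE_CONVERSION = 0.25

GRAMS_PER_TON = 1e6

#: Normal critical value for a two-sided 95% interval.
Z_95 = 1.959963984540054


@dataclass(frozen=True)
class AllometricParams:
    """Length-weight allometry ``W = a * L**b`` (W in g, L in cm).

    ``a`` is the condition constant and ``b`` the allometric exponent.  The
    default values are a plausible pooled-stock parameterization for
    pen-shell scallops (a stout bivalve close to isometric growth); they
    are placeholders to be replaced by stock-specific estimates whenever
    available.
    """

    a: float = 0.08
    b: float = 2.8

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValidationError(f"allometric parameters must be positive, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class BiomassEstimate:
    """Biomass of one sample-year extrapolated to the stratum area.

    All biomass figures are in metric tons.  ``total_sd`` and
    ``harvestable_sd`` are the standard errors of the area-extrapolated
    means (between-quadrat variability is the only modelled source of
    uncertainty); the 95% CI is ``mean ± 1.96 * sd``.  With a single
    quadrat the dispersion is undefined and reported as NaN with
    ``sd_defined=False``; an empty sample-year yields a no-data estimate
    with ``n_quadrats=0`` and NaN fields.
    """

    sample_id: int
    year: int
    total_mean: float
    total_sd: float
    ci_low: float
    ci_high: float
    harvestable_mean: float
    harvestable_sd: float
    edible_mean: float
    n_quadrats: int
    area_used: float
    sd_defined: bool = True

    @property
    def is_empty(self) -> bool:
        return self.n_quadrats == 0


def individual_weight(length, params: AllometricParams):
    """Whole-animal weight (g) of an individual of shell length ``length`` (cm)."""
    arr = np.asarray(length, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError(f"shell length must be > 0, got {length}")
    weight = params.a * arr**params.b
    return float(weight) if np.isscalar(length) else weight


def _expansion_factor(obs: QuadratObservation) -> float:
    if obs.counted_unmeasured == 0:
        return 1.0
    if not obs.measured_lengths:
        raise ExpansionError(
            f"quadrat {obs.quadrat_id!r} year {obs.year}: cannot expand "
            f"{obs.counted_unmeasured} counted individuals without measured lengths"
        )
    return 1.0 + obs.counted_unmeasured / len(obs.measured_lengths)


def expand_counted(obs: QuadratObservation, params: AllometricParams) -> float:
    """Gross weight (g) of a quadrat, expanding counted individuals.

    Counted-but-unmeasured individuals are assumed to follow the measured
    size distribution of the same quadrat, so the measured gross weight is
    scaled by ``1 + counted / n_measured``.
    """
    if not obs.measured_lengths:
        if obs.counted_unmeasured > 0:  # unreachable for validated observations
            raise ExpansionError(
                f"quadrat {obs.quadrat_id!r} year {obs.year}: counted individuals "
                "present but nothing was measured"
            )
        return 0.0
    measured = float(np.sum(individual_weight(np.asarray(obs.measured_lengths), params)))
    return measured * _expansion_factor(obs)


def harvestable_weight(
    obs: QuadratObservation, params: AllometricParams, min_length: float = LEGAL_MIN_LENGTH
) -> float:
    """Gross weight (g) of the harvestable (>= ``min_length``) fraction of a
    quadrat.  Counted individuals contribute in proportion to the measured
    harvestable share, i.e. the same expansion factor applies to the
    harvestable measured subset."""
    lengths = np.asarray(obs.measured_lengths, dtype=float)
    if lengths.size == 0:
        return 0.0
    harvestable = lengths[lengths >= min_length]
    if harvestable.size == 0:
        return 0.0
    measured = float(np.sum(individual_weight(harvestable, params)))
    return measured * _expansion_factor(obs)


def _no_data(sample_id: int, year: int, area: float) -> BiomassEstimate:
    nan = math.nan
    return BiomassEstimate(
        sample_id=sample_id, year=year, total_mean=nan, total_sd=nan,
        ci_low=nan, ci_high=nan, harvestable_mean=nan, harvestable_sd=nan,
        edible_mean=nan, n_quadrats=0, area_used=area, sd_defined=False,
    )


def estimate_biomass(
    sample: StratifiedCampaign,
    year: int,
    params: AllometricParams,
    min_length: float = LEGAL_MIN_LENGTH,
    conversion_factor: float = MUSCLE_CONVERSION,
) -> BiomassEstimate:
    """Estimate total, harvestable and edible biomass for one sample-year.

    Per-quadrat densities (g/ha) are averaged across quadrats and scaled to
    the stratum's extrapolation area; the standard error of the mean
    density, scaled the same way, gives the dispersion and the 95% CI.
    """
    observations = sample.for_year(year)
    area = sample.area_for_year(year)
    if not observations:
        return _no_data(sample.sample_id, year, area)

    total_density = np.array([expand_counted(o, params) / o.sampled_area for o in observations])
    harv_density = np.array(
        [harvestable_weight(o, params, min_length) / o.sampled_area for o in observations]
    )
    n = len(observations)
    scale = area / GRAMS_PER_TON

    total_mean = float(total_density.mean()) * scale
    harv_mean = float(harv_density.mean()) * scale
    if n > 1:
        total_sd = float(total_density.std(ddof=1)) / math.sqrt(n) * scale
        harv_sd = float(harv_density.std(ddof=1)) / math.sqrt(n) * scale
        sd_defined = True
    else:
        total_sd = harv_sd = math.nan
        sd_defined = False

    return BiomassEstimate(
        sample_id=sample.sample_id,
        year=year,
        total_mean=total_mean,
        total_sd=total_sd,
        ci_low=total_mean - Z_95 * total_sd if sd_defined else math.nan,
        ci_high=total_mean + Z_95 * total_sd if sd_defined else math.nan,
        harvestable_mean=harv_mean,
        harvestable_sd=harv_sd,
        edible_mean=conversion_factor * harv_mean,
        n_quadrats=n,
        area_used=area,
        sd_defined=sd_defined,
    )


def biomass_table(
    stratified_samples: dict[int, StratifiedCampaign],
    params: AllometricParams,
    min_length: float = LEGAL_MIN_LENGTH,
    conversion_factor: float = MUSCLE_CONVERSION,
) -> pd.DataFrame:
    """Tidy table of biomass estimates: one row per (sample, year).

    Years absent from a stratum produce no-data rows (NaN means), mirroring
    the em-dashes of a published summary table.
    """
    all_years = sorted({y for s in stratified_samples.values() for y in s.years})
    rows = []
    for sample_id, sample in sorted(stratified_samples.items()):
        for year in all_years:
            est = estimate_biomass(sample, year, params, min_length, conversion_factor)
            rows.append(
                {
                    "sample": sample_id,
                    "year": year,
                    "n_quadrats": est.n_quadrats,
                    "area_ha": est.area_used,
                    "total_mean_t": est.total_mean,
                    "total_sd_t": est.total_sd,
                    "ci_low_t": est.ci_low,
                    "ci_high_t": est.ci_high,
                    "harvestable_mean_t": est.harvestable_mean,
                    "harvestable_sd_t": est.harvestable_sd,
                    "edible_mean_t": est.edible_mean,
                }
            )
    return pd.DataFrame(rows)
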