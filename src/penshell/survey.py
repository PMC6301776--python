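"""Quadrat monitoring campaigns: reading, validation, and stratification.

A campaign is a set of quadrat-year observations collected by fishers
monitoring a benthic shellfish bed.  Within each quadrat, individuals are
measured (shell length in cm) up to a protocol cap — 114 individuals in the
La Paz pen-shell campaign — and any remainder is only counted.  Campaigns
are stratified into four analysis samples that differ in which quadrats and
which individuals they admit and in the area each is extrapolated to:

==========  ===========================  ========  =======================
sample      quadrats                     counted   extrapolation area
==========  ===========================  ========  =======================
1           all                          included  whole habitat
2           high-density only            included  area of those quadrats
3           low-density only             included  whole habitat
4           without counted individuals  n/a       whole habitat
==========  ===========================  ========  =======================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import EmptyStratumError, SchemaError, ValidationError

#: Habitable area of the pen-shell bed in the cove of La Paz (hectares).
DEFAULT_HABITAT_AREA = 1330.0

#: Maximum number of individuals measured per quadrat before the protocol
#: switches to counting.
MEASUREMENT_CAP = 114

CSV_COLUMNS = ["quadrat_id", "year", "sampled_area_ha", "length_cm", "count", "high_density"]

VALID_SAMPLE_IDS = (1, 2, 3, 4)


@dataclass(frozen=True)
class QuadratObservation:
    """One sampled quadrat in one campaign year.

    Parameters
    ----------
    quadrat_id
        Identifier of the quadrat, unique within a year.
    year
        Campaign year.
    sampled_area
        Area actually swept inside the quadrat, in hectares (> 0).
    measured_lengths
        Shell lengths of the measured individuals, in cm.
    counted_unmeasured
        Individuals counted after the measurement cap was reached.  Their
        size structure is assumed to mirror the measured individuals of the
        same quadrat, so a non-zero count requires a non-empty length list.
    high_density
        Flag marking the quadrat as belonging to the high-abundance patch
        subpopulation.  The flag is part of the input data; no numeric
        density threshold is imposed here (see :func:`flag_high_density`
        for an exploratory helper).
    """

    quadrat_id: str
    year: int
    sampled_area: float
    measured_lengths: tuple[float, ...] = ()
    counted_unmeasured: int = 0
    high_density: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "measured_lengths", tuple(float(x) for x in self.measured_lengths))
        if not self.sampled_area > 0:
            raise ValidationError(
                f"quadrat {self.quadrat_id!r} year {self.year}: "
                f"sampled_area must be > 0, got {self.sampled_area}"
            )
        for length in self.measured_lengths:
            if not length > 0:
                raise ValidationError(
                    f"quadrat {self.quadrat_id!r} year {self.year}: "
                    f"shell length must be > 0, got {length}"
                )
        if self.counted_unmeasured < 0:
            raise ValidationError(
                f"quadrat {self.quadrat_id!r} year {self.year}: "
                f"counted_unmeasured must be >= 0, got {self.counted_unmeasured}"
            )
        if self.counted_unmeasured > 0:
            if not self.measured_lengths:
                raise ValidationError(
                    f"quadrat {self.quadrat_id!r} year {self.year}: counted individuals "
                    "present but no measured lengths to borrow a size structure from"
                )
            if len(self.measured_lengths) > MEASUREMENT_CAP:
                raise ValidationError(
                    f"quadrat {self.quadrat_id!r} year {self.year}: protocol measures at "
                    f"most {MEASUREMENT_CAP} individuals before counting; got "
                    f"{len(self.measured_lengths)} measured alongside a count"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.measured_lengths) + self.counted_unmeasured


@dataclass(frozen=True)
class CampaignDataset:
    """A validated collection of quadrat observations plus the habitat area
    they may be extrapolated to."""

    observations: tuple[QuadratObservation, ...]
    habitat_area: float = DEFAULT_HABITAT_AREA

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        if not self.habitat_area > 0:
            raise ValidationError(f"habitat_area must be > 0, got {self.habitat_area}")
        seen: set[tuple[str, int]] = set()
        for obs in self.observations:
            key = (obs.quadrat_id, obs.year)
            if key in seen:
                raise ValidationError(f"duplicate quadrat-year pair {key}")
            seen.add(key)
        for year in self.years:
            total = sum(o.sampled_area for o in self.observations if o.year == year)
            if total > self.habitat_area * (1 + 1e-9):
                raise ValidationError(
                    f"year {year}: total sampled area {total} ha exceeds "
                    f"habitat area {self.habitat_area} ha"
                )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({o.year for o in self.observations}))

    def for_year(self, year: int) -> tuple[QuadratObservation, ...]:
        return tuple(o for o in self.observations if o.year == year)


@dataclass(frozen=True)
class SampleDefinition:
    """How one of the four analysis samples is carved out of a campaign."""

    sample_id: int
    include_counted: bool
    quadrat_filter: str  # "all" | "high_density_only" | "low_density_only" | "measured_only"
    extrapolate_to_habitat: bool

    @classmethod
    def for_sample(cls, sample_id: int) -> "SampleDefinition":
        if sample_id == 1:
            return cls(1, True, "all", True)
        if sample_id == 2:
            return cls(2, True, "high_density_only", False)
        if sample_id == 3:
            return cls(3, True, "low_density_only", True)
        if sample_id == 4:
            return cls(4, False, "measured_only", True)
        raise ValueError(f"sample_id must be one of {VALID_SAMPLE_IDS}, got {sample_id}")


@dataclass(frozen=True)
class StratifiedCampaign:
    """A campaign subset together with per-year extrapolation areas."""

    dataset: CampaignDataset
    sample_id: int
    extrapolation_area: dict[int, float] = field(default_factory=dict)

    @property
    def years(self) -> tuple[int, ...]:
        return self.dataset.years

    def for_year(self, year: int) -> tuple[QuadratObservation, ...]:
        return self.dataset.for_year(year)

    def area_for_year(self, year: int) -> float:
        return self.extrapolation_area.get(year, math.nan)


def read_campaign(path, habitat_area: float = DEFAULT_HABITAT_AREA) -> CampaignDataset:
    """Read a campaign CSV into a validated :class:`CampaignDataset`.

    The file holds one individual *or* one count batch per row with columns
    ``quadrat_id, year, sampled_area_ha, length_cm, count, high_density``
    (``length_cm`` empty on count rows, ``count`` empty on length rows).
    Rows sharing a quadrat-year merge into a single observation.
    """
    frame = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"campaign file {path} is missing column(s): {', '.join(missing)}")
    observations = []
    for (quadrat_id, year), group in frame.groupby(["quadrat_id", "year"], sort=True):
        areas = group["sampled_area_ha"].dropna().unique()
        if len(areas) != 1:
            raise ValidationError(
                f"quadrat {quadrat_id!r} year {year}: inconsistent sampled_area_ha {areas}"
            )
        lengths: list[float] = []
        counted = 0
        for idx, row in group.iterrows():
            has_length = pd.notna(row["length_cm"])
            has_count = pd.notna(row["count"])
            if has_length == has_count:
                raise ValidationError(
                    f"row {idx}: exactly one of length_cm and count must be set"
                )
            if has_length:
                if row["length_cm"] <= 0:
                    raise ValidationError(f"row {idx}: length_cm must be > 0, got {row['length_cm']}")
                lengths.append(float(row["length_cm"]))
            else:
                if row["count"] < 0:
                    raise ValidationError(f"row {idx}: count must be >= 0, got {row['count']}")
                counted += int(row["count"])
        try:
            obs = QuadratObservation(
                quadrat_id=str(quadrat_id),
                year=int(year),
                sampled_area=float(areas[0]),
                measured_lengths=tuple(lengths),
                counted_unmeasured=counted,
                high_density=bool(group["high_density"].any()),
            )
        except ValidationError as err:
            raise ValidationError(f"rows {list(group.index)}: {err}") from err
        observations.append(obs)
    return CampaignDataset(tuple(observations), habitat_area=habitat_area)


def to_frame(dataset: CampaignDataset) -> pd.DataFrame:
    """Flatten a campaign into the one-row-per-individual CSV layout."""
    records = []
    for obs in dataset.observations:
        for length in obs.measured_lengths:
            records.append((obs.quadrat_id, obs.year, obs.sampled_area, length, None, obs.high_density))
        if obs.counted_unmeasured > 0 or not obs.measured_lengths:
            # an explicit count row also preserves empty quadrats (count 0)
            records.append(
                (obs.quadrat_id, obs.year, obs.sampled_area, None, obs.counted_unmeasured, obs.high_density)
            )
    return pd.DataFrame(records, columns=CSV_COLUMNS)


def write_campaign(dataset: CampaignDataset, path) -> None:
    """Write a campaign in the CSV schema accepted by :func:`read_campaign`."""
    to_frame(dataset).to_csv(path, index=False)


def _matches(obs: QuadratObservation, definition: SampleDefinition) -> bool:
    if definition.quadrat_filter == "all":
        return True
    if definition.quadrat_filter == "high_density_only":
        return obs.high_density
    if definition.quadrat_filter == "low_density_only":
        return not obs.high_density
    if definition.quadrat_filter == "measured_only":
        return obs.counted_unmeasured == 0
    raise ValueError(f"unknown quadrat_filter {definition.quadrat_filter!r}")


def stratify(dataset: CampaignDataset, sample_id: int) -> StratifiedCampaign:
    """Carve the analysis sample ``sample_id`` out of a campaign.

    Sample 2 (high-density patches) is extrapolated only to the area of the
    qualifying quadrats in each year; the other samples extrapolate to the
    full habitat area.  For sample 4 the counted individuals are dropped by
    construction (only quadrats without counts qualify).

    Raises
    ------
    EmptyStratumError
        If sample 2 is requested but the campaign contains no high-density
        quadrat in any year.
    """
    definition = SampleDefinition.for_sample(sample_id)
    selected = tuple(o for o in dataset.observations if _matches(o, definition))
    if sample_id == 2 and not selected:
        raise EmptyStratumError("sample 2 requested but no quadrat is flagged high-density")
    if not definition.include_counted:
        selected = tuple(replace(o, counted_unmeasured=0) for o in selected)
    subset = CampaignDataset(selected, habitat_area=dataset.habitat_area)
    areas: dict[int, float] = {}
    for year in dataset.years:
        if definition.extrapolate_to_habitat:
            areas[year] = dataset.habitat_area
        else:
            areas[year] = sum(o.sampled_area for o in selected if o.year == year)
    return StratifiedCampaign(subset, sample_id=sample_id, extrapolation_area=areas)


def flag_high_density(dataset: CampaignDataset, quantile: float = 0.95) -> CampaignDataset:
    """Exploratory helper: flag quadrats whose abundance density exceeds the
    given campaign-wide quantile.

    The analysis itself trusts the ``high_density`` flag carried by the
    input data; this helper only suggests a flagging when none is present.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    densities = [o.n_individuals / o.sampled_area for o in dataset.observations]
    if not densities:
        return dataset
    cutoff = pd.Series(densities).quantile(quantile)
    flagged = tuple(
        replace(o, high_density=(o.n_individuals / o.sampled_area) > cutoff)
        for o in dataset.observations
    )
    return CampaignDataset(flagged, habitat_area=dataset.habitat_area)
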