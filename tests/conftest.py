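import pytest

from penshell import AllometricParams, CampaignDataset, QuadratObservation, SynthParams, generate_campaign


@pytest.fixture
def linear_allometry():
    """W = L: weight in g equals length in cm, handy for exact arithmetic."""
    return AllometricParams(a=1.0, b=1.0)


@pytest.fixture
def default_allometry():
    return AllometricParams()


@pytest.fixture
def make_obs():
    def _make(quadrat_id="Q1", year=2014, area=1.0, lengths=(), counted=0, high_density=False):
        return QuadratObservation(
            quadrat_id=quadrat_id,
            year=year,
            sampled_area=area,
            measured_lengths=tuple(lengths),
            counted_unmeasured=counted,
            high_density=high_density,
        )

    return _make


@pytest.fixture
def study_like_campaign(make_obs):
    """Tiny two-year campaign with the structural features of the study:
    low-density quadrats everywhere, high-density patches (with counted
    individuals) only in the later years."""
    obs = []
    for year, n_low, n_high in ((2013, 6, 2), (2014, 5, 3)):
        for i in range(n_low):
            obs.append(make_obs(f"L{i}", year, 1.0, [12.0 + i, 15.0, 16.5]))
        for i in range(n_high):
            obs.append(
                make_obs(f"H{i}", year, 1.0, [14.0, 15.0] * 3, counted=40, high_density=True)
            )
    return CampaignDataset(tuple(obs), habitat_area=1330.0)


@pytest.fixture
def small_synth_campaign():
    params = SynthParams(
        years=(2013, 2014),
        n_quadrats_per_year=(25, 30),
        density_mean=30.0,
        high_density_fraction=0.15,
        high_density_multiplier=8.0,
        seed=7,
    )
    dataset, truth = generate_campaign(params)
    return params, dataset, truth
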