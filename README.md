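# penshell

Bio-economic assessment toolkit for quadrat-surveyed benthic shellfish
fisheries, built around the *callo de hacha* pen-shell fishery (*Atrina
maura*, *A. tuberculosa*, *Pinna rugosa*) of the Ensenada de La Paz,
Baja California Sur. It is aimed at stock-assessment practitioners and
fishery economists who have community-collected quadrat monitoring data
and need to answer two questions: **how much biomass has recovered**, and
**is reopening the fishery economically viable**.

The pipeline has three stages:

1. **Biomass estimation.** Shell length L (cm) converts to whole-animal
   weight through the allometric relationship W = a·L^b. Within each
   quadrat, fishers measure up to 114 individuals and only count the rest;
   the counted remainder inherits the measured size structure, so the
   quadrat's gross weight is the measured weight times
   (1 + counted/measured). Quadrat gross weights become densities (g/ha);
   the between-quadrat mean density, extrapolated to the stratum area,
   gives the biomass B with a normal-approximation 95% CI
   (mean ± 1.96·SE). Harvestable biomass keeps individuals at or above the
   14 cm legal limit; edible biomass applies the 0.25 muscle yield.
   Campaigns stratify into four analysis samples (all quadrats /
   high-density patches only / low-density only / measured-only), each
   defining one scenario of stock status.
2. **Equilibrium projection.** The stock is assumed stationary: each
   year's harvestable biomass is an independent draw H ~ N(μ, σ²),
   clamped at zero, with μ and σ taken from a sample's estimate.
3. **Economics.** Yearly catch C = H·F·CF (fishing mortality F = 0.20,
   muscle conversion CF = 0.25) sells at the ex-vessel price; costs split
   into fixed (operational + boat·usage) and variable (trips = C/CPUE at a
   cost per trip, plus a cost per kg); tax applies to clamped profit; the
   10-year flow discounts at rate r against the initial investment:
   NPV = −I + Σ_y (R − Tc − Tax)/(1+r)^y, reported in thousand USD.
   A Monte Carlo (1000 runs per scenario) yields the NPV distribution,
   plus a discount-rate sensitivity sweep with common random numbers.

A synthetic-campaign generator with exact ground truth (overdispersed
quadrat abundance, rare high-density patches, truncated-normal lengths
straddling the legal limit, the 114-individual censoring protocol) makes
every stage testable without the original field data.

## Worked example

```bash
$ penshell synth --seed 11 --out campaign.csv --truth-out truth.json
synth: true harvestable biomass by year: 2011: 6.56 t, 2012: 7.37 t, 2013: 8.44 t, 2014: 6.97 t

$ penshell estimate-biomass campaign.csv --out biomass.csv | head -5
sample year n_quadrats area_ha total_mean_t total_sd_t ci_low_t ci_high_t harvestable_mean_t harvestable_sd_t edible_mean_t
     1 2011        116  1330.0         8.03       1.92     4.26     11.79               6.47             1.53          1.62
     1 2012        121  1330.0         9.24       1.96      5.4     13.08               7.51             1.62          1.88
     1 2013        130  1330.0        10.49        3.1     4.42     16.56               8.62             2.61          2.15
     1 2014        140  1330.0          8.6       1.73     5.21     11.99               6.99             1.44          1.75
```

Each row is one sample-year: the 2011 all-quadrat stratum (sample 1, 116
one-hectare quadrats) extrapolates to 8.03 t of total biomass over the
1330-ha habitat (95% CI 4.26–11.79 t), of which 6.47 t is above the 14 cm
legal limit and 1.62 t is sellable muscle. The generator's true
harvestable biomass (6.56 t in 2011) falls inside the interval.

```bash
$ penshell init-scenarios scenarios --seed 11
$ penshell simulate-npv --scenario scenarios/scenario-1.yaml --scenario scenarios/scenario-3.yaml
  scenario  n_runs  min_kusd  mean_kusd  max_kusd  sd_kusd  q2.5_kusd  median_kusd  q97.5_kusd
scenario-1    1000      -8.9       41.7     104.0     16.4       10.6         41.9        73.0
scenario-3    1000     -60.2      -54.3     -47.0      1.9      -57.9        -54.3       -50.6
```

Scenario 1 (equilibrium harvestable biomass 35 ± 16 t, the all-quadrat
estimate) is profitable in expectation — mean NPV +41.7 thousand USD over
10 years — while scenario 3 (4.5 ± 1.6 t, patches excluded) loses money
every year: the fixed monitoring-and-enforcement cost exceeds what the
small stock can earn. `penshell sensitivity --scenario ... --rates 0.1
--rates 0.3 --rates 0.5` shows the two regimes react oppositely to
discounting: profitable scenarios shrink toward zero, loss-making ones
rise toward zero.

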