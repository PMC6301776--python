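# Methods

## Survey model and biomass estimator

A monitoring campaign is a set of quadrat-year observations. Within a
quadrat of sampled area n (ha), fishers measure shell lengths up to a
protocol cap (114 individuals) and count the remainder. The estimator
assumes the measured individuals are a simple random subset of the
quadrat, so the counted remainder inherits the measured size structure:
quadrat gross weight = measured weight × (1 + counted/measured). The same
factor applies to the measured subset at or above the legal limit, which
keeps the harvestable fraction consistent with the gross expansion. This
rule is exactly unbiased whenever individuals within a quadrat are
exchangeable; the paired censored/uncensored test in the suite verifies
it empirically.

Individual weight uses the allometric form W = a·L^b (W in g, L in cm).
No stock-specific parameters are published for the pooled three-species
stock, so the shipped defaults (a = 0.08, b = 2.8, giving ≈130 g at the
14 cm legal limit and ≈350 g at 20 cm) are plausible pen-shell values
meant to be overridden; every quantity in the pipeline is homogeneous of
degree 1 in a, so mis-specifying a rescales but never reorders results.

Per-quadrat densities d_i = gross_i / n_i (g/ha) are treated as an i.i.d.
sample; the estimate for a stratum-year is mean(d) × A, where A is the
extrapolation area, with standard error sd(d)/√q × A (q quadrats) and a
normal 95% CI (±1.96·SE). Between-quadrat variability is the only modelled
uncertainty — allometric parameters and the habitat area enter as known
constants. A single quadrat yields an estimate with undefined dispersion
(flagged); an empty stratum-year yields a no-data record, not zero.

The four analysis samples: (1) all quadrats; (2) only quadrats flagged
high-density, extrapolated to the area of those quadrats in each year
rather than the habitat; (3) the complement of 2; (4) only quadrats with
no counted individuals. High-density status is an input flag (no numeric
threshold is imposed, since patch identification in the field was
judgement-based); `flag_high_density` offers a quantile-based suggestion
for exploratory work. Samples 2 and 3 partition sample 1 by construction,
and sample 4 equals the estimator run with counts removed — both are
property-tested.

## Equilibrium projection

The stock is assumed stationary at the last-survey level: yearly
harvestable biomass is drawn independently as H ~ N(μ, σ²). Negative
draws are clamped at zero by default, which raises the effective mean to
μΦ(μ/σ) + σφ(μ/σ); for the bundled scenarios the lift is ≤ 1.5% (μ/σ ≥
2.2) but the closed-form oracles account for it exactly. A redraw policy
(zero-truncated normal) is available; the choice is explicit because the
original analysis does not state one. No recruitment, growth or density
dependence is modelled — the projection is an uncertainty wrapper around
a static estimate, not population dynamics.

## Economic model

Per operating year with harvestable biomass H (tons):

- catch C = H·F·CF·1000 kg of muscle (F = 0.20, CF = 0.25);
- revenue R = C × price (MX$200/kg);
- fixed cost = Σ operational items + (Σ boat items)·Bu, where Bu is the
  boat-capacity share the fishery uses (the bundled cost of
  MX$127,752/yr is already Bu-weighted, entered as a single operational
  item);
- variable cost = (C/CPUE)·Ce + C·Cc (CPUE 25 kg/trip, Ce = MX$220,
  Cc = MX$0.80); trips are continuous by default to preserve linearity
  (integer-ceiling mode available);
- depreciation D = 10% of the MX$390,000 investment, a non-cash,
  tax-deductible charge;
- tax = 15% × max(0, R − costs − D);
- NPV = −I + Σ_{y=1..10} net_y/(1+r)^y, converted once to thousand USD
  at 16.82 MXN/USD.

Three aspects of this accounting are genuinely underdetermined in the
source material, so they are explicit switches rather than silent
choices (`ModelOptions`):

- **cf_application** — where the muscle conversion enters. `once`
  (default): catch is muscle mass priced per kg of muscle, consistent
  with the edible-biomass definition. `twice`: the conversion also
  multiplies revenue (a literal reading of the revenue prose).
  `price_on_whole`: catch, effort and price are on whole-animal weight.
- **tax_base** — `profit` (default, clamped at zero) or `revenue`.
- **include_depreciation**, **horizon_indexing** (`investment_year_zero`
  default vs `literal`, which adds an undiscounted year-0 operating
  flow), **trips**, **negative_draws**.

The published summary of this fishery's reopening analysis is not
reproducible from its stated parameters under any single one of these
readings; a linear solve of its four scenario means implies whole-animal
pricing together with a yearly fixed cost several times the printed one
and no effective tax — structure internal to the authors' spreadsheet
tool. The bundled *calibrated* preset therefore uses the closest
combination of documented switches only (`price_on_whole` +
`tax_base=revenue`) and makes no attempt to re-derive unpublished costs;
with it the sign pattern, ordering, dispersion scale and discount-rate
behaviour of the published scenarios all reproduce, while the level of
the profitable scenarios sits above the published means. The default
(`once` + `profit`) reading remains the package's internally consistent
model. The invariant surface — signs, monotonicity in price/biomass/
costs/rate, degree-1 price homogeneity, closed-form agreement of the
Monte Carlo mean when flows are linear — holds under every switch
combination and is what the test suite pins.

The Monte Carlo draws one independent stream per run (child seeds
spawned from the root `SeedSequence`), 1000 runs × 10 years per scenario;
the discount-rate sweep reuses one draw matrix across rates (common
random numbers) so sensitivity curves differ only by discounting.
Summary statistics (min/mean/max/sd/median/95% band) are recomputed from
the per-run NPVs and cross-checked independently in tests.

## Synthetic campaigns

The generator emulates the study conditions: four years of 116/121/130/140
one-hectare quadrats, a 1330-ha habitat, the 114-individual cap. Quadrat
abundance is negative-binomial (mean 20, dispersion k = 1.5) with a
Bernoulli patch state (6% of quadrats, ×15 abundance) reproducing the
rare high-density patches — patch quadrats exceed the cap and exercise
the counting protocol. Lengths are normal (15 ± 3 cm) truncated at zero,
so the 14 cm limit cuts through the bulk of the distribution. All
individuals are drawn first and the cap applied afterwards, so the
realized (ground-truth) biomass is known exactly; the distribution-level
expectations needed for bias and coverage studies come from numerical
integration of the weight function against the length density.

What the generator does **not** emulate: spatial structure of patches,
inter-annual trend or recruitment (years are i.i.d.), species
composition, and measurement error in lengths. Passing tests therefore
validate the estimator's arithmetic, unbiasedness and calibration under
the assumed sampling model, not the field protocol itself.

## Verification design and problem sizes

- CI coverage: 500 replicate single-year campaigns of 130 quadrats in the
  overdispersed patch-free regime; observed coverage must sit in 90–98%
  (measured ≈96%). With the 15× patch regime switched on the normal CI
  undercovers (≈87% in a 500-replicate run): rare extreme densities make
  the density mean heavy-tailed at q ≈ 130. This is a real limitation of
  the normal-approximation interval under strong patchiness, documented
  rather than hidden; a bootstrap interval would be the natural upgrade.
- Unbiasedness: 200 replicates of 60 quadrats, censoring off, mild
  patches; mean relative bias bound 2% (≈3× the Monte Carlo SE of the
  design).
- Censoring invariance: 150 paired campaigns (same seed with and without
  the cap) at densities that censor most quadrats; the mean paired
  difference must be within 3 SE of zero.
- Economics: 1000-run scenarios; closed-form agreement asserted within
  3 SE under a linear configuration.

These sizes were chosen to give each check ≥3:1 signal-to-noise while the
whole suite runs in well under a minute per heavy test.

## Known limitations

- The normal CI undercovers under extreme patchiness (above).
- Equilibrium projection ignores population dynamics; it propagates
  survey uncertainty, nothing more.
- The four samples embody contradictory beliefs about the patches
  (representative of the whole bed vs. confined to their own area); the
  package computes all four and takes no side.
- Economic parameters are point values; only biomass is stochastic, so
  the NPV bands understate full decision uncertainty.
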