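# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions taken where the procedure was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Chamber flux model

A closed chamber of volume V (default 0.15 m³) over a footprint S (default
0.25 m²) holds n = P·V/(R·T) moles of air. A linear change d′C/dt
(µmol mol⁻¹ s⁻¹) of the dry-air CO₂ mole fraction therefore corresponds to
a surface flux F = (V·P)/(R·T·S)·d′C/dt in µmol m⁻² s⁻¹. Implementation
details:

- **Units.** Pressure is configured in kPa (default 90, appropriate for
  ~1100 m elevation) and converted to Pa; air temperature is configured in
  °C and converted to kelvin — the ideal gas law requires absolute
  temperature.
- **Water correction.** The default correction to a dry-air basis is the
  dilution form C′ = co2/(1 − h2o/1000), which removes the apparent
  concentration change caused by evapotranspiration. A literal ratio
  co2/h2o is available as `form="as_printed"` for comparison with analyses
  that divided by the water mole fraction directly; it is dimensionally a
  ratio rather than a concentration and is not the default.
- **Window.** The slope is fit by OLS over t ∈ [30, 150] s since sealing
  (a 30 s fan-mixing period followed by the 120 s measurement); both
  endpoints are configurable.
- **Quality control.** Visits whose dark-series fit has r² below 0.8
  (configurable) or whose dark PAR exceeds 130 µmol m⁻² s⁻¹ are flagged,
  never dropped — downstream stages decide what to do with flags.
- **Signs.** NEE (light) and ER (dark) keep the analyzer's sign; GEP =
  NEE − ER holds exactly by construction. Negative NEE/GEP = sink.
- **GEP standardization.** The light response is modelled as a rectangular
  hyperbola GEP(PAR) = GEP_max·PAR/(k + PAR), fit by least squares to ≥ 3
  shading levels, and evaluated at the reference PAR (600). The hyperbola
  is the conventional light-response model; the fit is pluggable, and the
  pipeline's final statistics use non-standardized GEP.

## Synthetic-data generator

The generator emulates the full study: 3 communities × 8 blocks × 4
treatment plots (96 plots), 4 transplants in each transplant plot (192),
one harvest plot in 6 blocks per community (18), and a visit multiplicity
of 10 plots × 3, 61 × 2, 25 × 1 (177 visits). The multiplicity vector is
shuffled uniformly over all plots by the seeded generator; no structure is
imposed because none is known (10/61/25 cannot balance exactly over three
communities).

- **Fluxes.** Each plot's true (GEP, ER) is its community mean, plus any
  configured additive treatment effect, plus N(0, 0.6²) between-plot
  noise; each visit adds N(0, 0.25²) drift; NEE = GEP + ER. Community
  means default to GEP −5.9/−7.7/−10.7 and ER 4.0/5.0/6.3 µmol m⁻² s⁻¹
  for heath/meadow/shrub — mid-range daytime mid-season magnitudes for
  these community types, with the shrub community both fixing and
  respiring the most. Default treatment effects mirror the heath-centred
  response pattern the design is powered to detect (exclosures raise
  dwarf-shrub hits, depress bryophytes and ER; transplants add
  deciduous-shrub hits).
- **Chamber series.** The flux equation is inverted to get the implied
  d′C/dt; the corrected concentration evolves linearly from a random
  390–420 µmol mol⁻¹ start with Gaussian noise (sd 0.5 µmol mol⁻¹,
  configurable); H₂O drifts slowly upward from 6–14 mmol mol⁻¹, and the
  wet-air CO₂ column is back-computed so the dilution correction recovers
  the linear series exactly. With noise sd 0 the full pipeline returns
  the configured fluxes to machine precision (a round-trip identity the
  tests assert).
- **Vegetation.** Pin hits are negative-binomial (dispersion 6) around
  community × functional-group means, shifted by treatment effects;
  overdispersed counts are the safe default for point-intercept data.
  Harvest masses are truth(hits) + N(0, σ) on the g m⁻² scale, truncated
  at 0, then converted to quadrat grams (0.25 m quadrats in heath/meadow,
  0.50 m in shrub).
- **Determinism.** All randomness flows through one `default_rng(seed)`;
  a seed reproduces every table bit-for-bit. Mortality, frost damage and
  microclimate side effects are not simulated.

What the generator does **not** emulate — instrument drift and spikes,
pressure pumping, chamber leaks, non-linear saturation of concentrations,
spatial autocorrelation between neighbouring blocks, and
non-Gaussian/heteroscedastic calibration error. Tests passing on this
generator therefore demonstrate the correctness of the computational
chain and its frequentist calibration under the design, not robustness to
every field pathology.

## Biomass calibration

Candidate forms are the conventional point-intercept battery y = b·x,
y = a + b·x, y = a + b·x + c·x², and y = b·x^c (fit on log–log and
back-transformed); the battery is configurable. r², residual sd and the
Shapiro–Wilk residual-normality p are all computed on the original scale
so forms are comparable. Selection takes the highest r² among candidates
with normality p ≥ 0.05, falls back to the highest normality p if none
pass, and breaks exact ties toward fewer parameters.

The parametric bootstrap simulates new responses at the harvest design
points, refits the selected form, and predicts every experimental plot
from its hits; per-plot means and 2.5/97.5 percentiles over 1000
replicates give the estimate and CI. One deliberate refinement: the
replicate noise sd is drawn from the scaled inverse-χ² sampling
distribution of the residual variance (σ̂·√(ν/χ²_ν), ν = residual df)
rather than held at σ̂. With only 18 harvest quadrats a fixed-σ̂ bootstrap
produces z-type intervals whose true coverage falls measurably short of
nominal; propagating the variance uncertainty makes the intervals t-like
and restores ~95% coverage (the acceptance suite measures this).
Negative predictions are truncated at 0 and the truncation rate logged.
Plots with zero hits under a through-origin form get estimate 0 with a
degenerate CI.

## Treatment inference

- **Routing.** The factorial 2×2 ANOVA (sequential SS from explicit design
  matrices; on balanced data all decomposition types coincide and the
  residual df is 28 per community) is accepted when Shapiro–Wilk on its
  residuals and Levene across the four cells both pass at α = 0.05.
  Otherwise the response is ln-transformed (shifted by 10⁻³ if zeros are
  present, logged; negative values skip the ln stage) and re-checked;
  persistent failure routes to Kruskal–Wallis on the combined 4-level
  C/E/ET/T factor with Dunn's pairwise z comparisons. The Dunn
  multiplicity adjustment is configurable (none/Bonferroni/Holm; default
  none, as in common Dunn usage).
- **Mixed models.** Repeated fluxes are modelled with a plot random
  intercept, fit by maximum likelihood — not REML — because AICc
  comparisons across different fixed structures are invalid under REML.
  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting fixed effects plus
  both variance components; models within dAICc < 2 of the best form the
  equal-support set. When the optimizer hits the zero-variance boundary
  the model collapses to its exact OLS equivalent with the random
  variance pinned at 0 (warned). For the real-data pathway, ln transforms
  are applied to flux magnitudes (NEE and GEP are predominantly negative;
  the sign convention is metadata) — for additively-Gaussian synthetic
  fluxes the identity scale is the correctly specified analysis and is
  what the recovery studies use.
- **Contrasts.** Tukey-style simultaneous comparisons on models without
  interactions use the fixed-effect covariance and the studentized-range
  distribution with k = number of levels and df = n_obs − k_fixed; for a
  two-level factor this reduces exactly to the unadjusted t test. A
  generic nested-model likelihood-ratio operation supports robustness
  checks on abundance models.
- **Confidence intervals** are reported at 95% throughout.

## Problem sizes used in validation

The acceptance suite exercises the default design (96 plots / 177
visits), 1000 random draws for the ideal-gas oracle, 100 simulation reps
× 1000 bootstrap replicates for calibration coverage, 2000 reps for the
routed test's type-I error, and 50 reps × 5 candidate models for AICc
recovery — sizes at which the Monte-Carlo error of each measured rate is
small relative to its acceptance band.

## Known limitations

- The light-response model and the four calibration forms are documented
  stand-ins for procedures whose exact specifications are unavailable;
  both are pluggable.
- r²-based selection among nested forms favours the largest model except
  under exact ties; parsimony enters only as a tie-break. Coverage of the
  bootstrap CIs is robust to this (richer forms widen intervals), but the
  selected form should not be over-interpreted.
- The assumption router makes sequential decisions at fixed α without
  correcting the final test for the pre-testing; its realized type-I
  error is validated empirically instead.
- Hit counts may exceed the pin count (multiple contacts per pin are
  allowed), matching point-intercept practice for dense canopies.
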