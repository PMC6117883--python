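# tundraflux

A tested, reusable implementation of the computational chain behind a
herbivore-exclusion × shrub-introduction field experiment in alpine tundra:
closed-chamber CO₂ flux estimation, point-intercept → biomass calibration
with parametric-bootstrap confidence intervals, and factorial / mixed-model
treatment inference — driven end-to-end by a synthetic-data generator that
emulates the study design with known ground truth, so the whole pipeline
runs and validates without any field data.

It is aimed at ecosystem ecologists and biostatisticians who work with
static-chamber gas-exchange campaigns and point-intercept vegetation
surveys, and who want each analysis step available as a plain, auditable
Python function.

## The experiment and the models

**Design.** Three alpine plant communities (*Empetrum* heath, herb/cryptogam
meadow, *Salix* shrub) each hold 8 randomized blocks; within every block a
2×2 crossing of herbivore **exclosure** (E) and *Salix* **transplant** (T)
gives 4 plots (codes C, E, ET, T) — 96 experimental plots, plus one
destructive-harvest plot in 6 blocks per community (n = 18). Plots were
revisited during the season: 10 plots measured three times, 61 twice, 25
once — 177 chamber visits.

**Chamber fluxes.** Each visit pairs a light and a darkened deployment of a
sealed 0.5 × 0.5 × 0.6 m chamber. The CO₂ mole fraction is first corrected
to a dry-air basis, C′ = [CO₂] / (1 − [H₂O]/1000), then the slope d′C/dt is
fit by OLS over the 120 s measurement window that starts 30 s after
sealing, and converted to a surface flux with the ideal gas law:

    F = (V · P) / (R · T_air · S) · d′C/dt        [µmol m⁻² s⁻¹]

with V the chamber volume (m³), P the air pressure (Pa; 90 kPa default for
~1100 m elevation), R = 8.314 J mol⁻¹ K⁻¹, T_air in kelvin and S the
footprint (m²). The light deployment yields net ecosystem exchange (NEE),
the dark one ecosystem respiration (ER), and gross ecosystem photosynthesis
is GEP = NEE − ER; negative NEE/GEP denote a CO₂ sink. GEP can optionally
be standardized to a reference PAR (600 µmol m⁻² s⁻¹) through a
rectangular-hyperbola light-response fit.

**Biomass calibration.** Harvested quadrat masses (g m⁻²) are regressed on
pin hits per functional group under four candidate forms (through-origin
linear, linear, quadratic, power); the best form is chosen by r² among
candidates with Gaussian residuals (Shapiro–Wilk), and per-plot biomass
with 95% CIs comes from a 1000-replicate parametric bootstrap. Four groups
are calibrated with harvest data pooled across communities; deciduous
shrubs, lichens and bryophytes get community-specific models.

**Inference.** Community differences: one-way ANOVA + Tukey HSD. Treatment
effects within each community: 2×2 factorial ANOVA with an
assumption-checking router (ln-transform fallback, then Kruskal–Wallis on
the combined C/E/ET/T factor with Dunn post-hoc tests). Repeated fluxes:
Gaussian random-intercept mixed models (plot as random effect, ML fitting),
compared by AICc with the dAICc < 2 equal-support rule, plus Tukey-style
simultaneous contrasts on models without interactions.

## Worked example

```python
import tundraflux as tf
from tundraflux.fluxes import fluxes_from_log

exp = tf.simulate_experiment(tf.SimulationConfig(seed=1))
flux = fluxes_from_log(exp.analyzer_log)
print(flux[["plot", "visit", "NEE", "ER", "GEP"]].head(4).round(3))

bio, totals, models = tf.estimate_all(exp.harvest, exp.pin_hits, exp.design,
                                      n_boot=1000, seed=1)
anova, tukey = tf.oneway_anova_tukey(totals["total_g_m2"], totals["community"])
```

This prints the first chamber visits,

```
      plot  visit    NEE    ER    GEP
heath-b1-C      1 -1.220 4.650 -5.870
heath-b1-E      1 -3.501 2.367 -5.868
heath-b1-E      2 -3.100 2.312 -5.411
heath-b1-E      3 -2.811 2.617 -5.428
```

i.e. the heath control plot fixes a net −1.2 µmol CO₂ m⁻² s⁻¹ while
respiring 4.7, and community-mean fluxes recover the configured gradient
(heath GEP −5.8, meadow −7.7, shrub −10.9 µmol m⁻² s⁻¹). The biomass stage
returns per-plot functional-group estimates with bootstrap CIs; the one-way
ANOVA on plot totals gives `community F_2,93 = 4.45, p = 1.4e-02` for this
seed.

The same run is available from the shell:

```sh
tundraflux run --seed 1 --outdir runs/demo      # simulate → fluxes → biomass → stats
tundraflux validate --rundir runs/demo          # table contract checks
```

Every output, including the run manifest with file hashes, is reproduced
byte-for-byte by re-running with the same seed.

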