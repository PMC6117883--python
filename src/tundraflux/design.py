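"""Experimental design and synthetic-data generation.

Encodes the factorial skeleton of a herbivore-exclusion × shrub-introduction
field experiment — three alpine plant communities (heath, meadow, shrub),
eight randomized blocks per community, and a 2×2 crossing of herbivore
exclosure and Salix transplant within each block — and generates synthetic
chamber analyzer logs, point-intercept vegetation tables, and harvest tables
with known ground truth, so every downstream stage of the pipeline can be
exercised and validated without field data.

All randomness flows through a single seeded ``numpy`` generator: a given
``SimulationConfig.seed`` reproduces every generated value bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fluxes import ChamberGeometry, ConcentrationSeries, LOG_COLUMNS, slope_for_flux

COMMUNITIES = ("heath", "meadow", "shrub")

FUNCTIONAL_GROUPS = (
    "deciduous_shrubs",
    "dwarf_shrubs",
    "forbs",
    "graminoids",
    "seedless_vascular",
    "lichens",
    "bryophytes",
)

#: Functional groups whose pin-hit→biomass calibration pools harvest data
#: across communities, versus those fitted per community (woody and
#: cryptogam groups differ too much in architecture between communities).
POOLED_GROUPS = ("dwarf_shrubs", "forbs", "graminoids", "seedless_vascular")
COMMUNITY_SPECIFIC_GROUPS = ("deciduous_shrubs", "lichens", "bryophytes")

#: Bijection between the 2×2 factor levels and the combined treatment code.
TREATMENT_CODES: Mapping[tuple[int, int], str] = {
    (0, 0): "C", (1, 0): "E", (1, 1): "ET", (0, 1): "T",
}
CODE_TO_LEVELS = {v: k for k, v in TREATMENT_CODES.items()}


class ConfigurationError(ValueError):
    """A design or simulation parameter is invalid; names the field."""


@dataclass(frozen=True)
class TreatmentLevel:
    exclosure: int
    transplant: int

    def __post_init__(self):
        if self.exclosure not in (0, 1) or self.transplant not in (0, 1):
            raise ConfigurationError("exclosure and transplant must be 0 or 1")

    @property
    def combined_code(self) -> str:
        return TREATMENT_CODES[(self.exclosure, self.transplant)]

    @classmethod
    def from_code(cls, code: str) -> "TreatmentLevel":
        try:
            e, t = CODE_TO_LEVELS[code]
        except KeyError:
            raise ConfigurationError(f"unknown treatment code {code!r}") from None
        return cls(e, t)


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the factorial design."""

    communities: tuple[str, ...] = COMMUNITIES
    blocks_per_community: int = 8
    transplants_per_plot: int = 4
    harvest_blocks_per_community: int = 6
    quadrat_side_m: Mapping[str, float] = field(
        default_factory=lambda: {"heath": 0.25, "meadow": 0.25, "shrub": 0.50}
    )
    pins_per_quadrat: int = 25

    def validate(self) -> None:
        if not self.communities:
            raise ConfigurationError("communities must be non-empty")
        for name in ("blocks_per_community", "transplants_per_plot",
                     "harvest_blocks_per_community", "pins_per_quadrat"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.harvest_blocks_per_community > self.blocks_per_community:
            raise ConfigurationError(
                "harvest_blocks_per_community cannot exceed blocks_per_community"
            )
        for c in self.communities:
            if self.quadrat_side_m.get(c, 0) <= 0:
                raise ConfigurationError(f"quadrat_side_m missing or non-positive for {c!r}")


@dataclass(frozen=True)
class ExperimentDesign:
    """The complete plot registry every pipeline stage consumes.

    ``plots`` has one row per experimental plot with columns
    plot, community, block, exclosure, transplant, code, n_transplants;
    ``harvest_plots`` one row per destructive-harvest plot (a separate plot
    within selected blocks, disjoint from the treatment plots).
    """

    config: DesignConfig
    plots: pd.DataFrame
    harvest_plots: pd.DataFrame

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_transplants(self) -> int:
        return int(self.plots["n_transplants"].sum())

    @property
    def n_harvest_plots(self) -> int:
        return len(self.harvest_plots)


def build_design(config: DesignConfig | None = None) -> ExperimentDesign:
    """Expand a :class:`DesignConfig` into the full plot registry.

    Deterministic: harvest blocks are the first ``harvest_blocks_per_community``
    block indices in each community.
    """
    config = config or DesignConfig()
    config.validate()
    rows = []
    for community in config.communities:
        for block in range(1, config.blocks_per_community + 1):
            for (e, t), code in TREATMENT_CODES.items():
                rows.append({
                    "plot": f"{community}-b{block}-{code}",
                    "community": community,
                    "block": block,
                    "exclosure": e,
                    "transplant": t,
                    "code": code,
                    "n_transplants": config.transplants_per_plot if t else 0,
                })
    plots = pd.DataFrame(rows)
    if plots.duplicated(["community", "block", "exclosure", "transplant"]).any():
        raise ConfigurationError("duplicate (community, block, exclosure, transplant) keys")
    hrows = [
        {
            "plot": f"{community}-b{block}-H",
            "community": community,
            "block": block,
            "quadrat_side_m": config.quadrat_side_m[community],
            "pins": config.pins_per_quadrat,
        }
        for community in config.communities
        for block in range(1, config.harvest_blocks_per_community + 1)
    ]
    return ExperimentDesign(config=config, plots=plots, harvest_plots=pd.DataFrame(hrows))


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationTruth:
    """True pin-hits→biomass relationship for one functional group.

    ``form`` ∈ {origin_linear, linear, quadratic, power}; coefficients are
    (b,), (a, b), (a, b, c) or (b, c) respectively, on the g m⁻² scale.
    """

    form: str
    coefficients: tuple[float, ...]
    residual_sd: float

    def predict(self, hits) -> np.ndarray:
        x = np.asarray(hits, dtype=float)
        c = self.coefficients
        if self.form == "origin_linear":
            return c[0] * x
        if self.form == "linear":
            return c[0] + c[1] * x
        if self.form == "quadratic":
            return c[0] + c[1] * x + c[2] * x**2
        if self.form == "power":
            return c[0] * np.where(x > 0, x, 1.0) ** c[1] * (x > 0)
        raise ConfigurationError(f"unknown calibration form {self.form!r}")


def _default_flux_means() -> dict[str, dict[str, float]]:
    # Central GEP/ER magnitudes per community (µmol m⁻² s⁻¹, GEP sink-negative),
    # chosen to sit mid-range of daytime mid-season alpine chamber fluxes:
    # the shrub community photosynthesizes and respires most, the heath least.
    return {
        "heath": {"GEP": -5.9, "ER": 4.0},
        "meadow": {"GEP": -7.7, "ER": 5.0},
        "shrub": {"GEP": -10.7, "ER": 6.3},
    }


def _default_calibration_truth() -> dict[str, CalibrationTruth]:
    return {
        "deciduous_shrubs": CalibrationTruth("origin_linear", (3.0,), 6.0),
        "dwarf_shrubs": CalibrationTruth("linear", (8.0, 2.4), 9.0),
        "forbs": CalibrationTruth("origin_linear", (1.2,), 2.5),
        "graminoids": CalibrationTruth("origin_linear", (1.6,), 3.5),
        "seedless_vascular": CalibrationTruth("origin_linear", (0.9,), 1.2),
        "lichens": CalibrationTruth("linear", (2.0, 1.8), 4.0),
        "bryophytes": CalibrationTruth("linear", (4.0, 1.7), 5.0),
    }


def _default_hit_means() -> dict[str, dict[str, float]]:
    # Mean pin hits per plot by community × functional group, loosely tracking
    # the community descriptions (heath: dwarf-shrub dominated; meadow: forbs,
    # graminoids and cryptogams; shrub: deciduous canopy over cryptogams).
    return {
        "heath": {"deciduous_shrubs": 2, "dwarf_shrubs": 45, "forbs": 3,
                  "graminoids": 5, "seedless_vascular": 1, "lichens": 8,
                  "bryophytes": 6},
        "meadow": {"deciduous_shrubs": 2, "dwarf_shrubs": 6, "forbs": 25,
                   "graminoids": 22, "seedless_vascular": 4, "lichens": 10,
                   "bryophytes": 14},
        "shrub": {"deciduous_shrubs": 35, "dwarf_shrubs": 4, "forbs": 12,
                  "graminoids": 15, "seedless_vascular": 2, "lichens": 12,
                  "bryophytes": 18},
    }


def _default_treatment_effects() -> dict:
    # Additive ground-truth treatment effects, mirroring the heath-centred
    # response pattern the design is powered to detect: exclosures raise
    # dwarf-shrub abundance and depress bryophytes and ER; transplants add
    # deciduous-shrub hits wherever they are planted.
    return {
        "hits": {
            ("heath", "exclosure", "dwarf_shrubs"): 10.0,
            ("heath", "exclosure", "bryophytes"): -3.0,
            ("heath", "transplant", "graminoids"): 4.0,
            ("heath", "transplant", "deciduous_shrubs"): 5.0,
            ("meadow", "transplant", "deciduous_shrubs"): 5.0,
        },
        "flux": {
            ("heath", "exclosure"): {"ER": -0.6, "GEP": 0.3},
        },
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and noise levels for the synthetic experiment."""

    seed: int = 0
    community_flux_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_flux_means)
    treatment_effects: Mapping = field(default_factory=_default_treatment_effects)
    chamber_noise_sd: float = 0.5          # µmol mol⁻¹ on the corrected series
    plot_flux_sd: float = 0.6              # between-plot sd of true ER and GEP
    visit_flux_sd: float = 0.25            # visit-to-visit drift of true fluxes
    measurement_multiplicity: Mapping[int, int] = field(
        default_factory=lambda: {3: 10, 2: 61, 1: 25})
    calibration_truth: Mapping[str, CalibrationTruth] = field(
        default_factory=_default_calibration_truth)
    hit_means: Mapping[str, Mapping[str, float]] = field(default_factory=_default_hit_means)
    hit_dispersion: float = 6.0            # negative-binomial size parameter
    samples_per_second: float = 1.0

    def validate(self, design: ExperimentDesign) -> None:
        n_assigned = sum(self.measurement_multiplicity.values())
        if n_assigned != design.n_plots:
            raise ConfigurationError(
                f"measurement_multiplicity covers {n_assigned} plots, "
                f"design has {design.n_plots}"
            )
        for g in FUNCTIONAL_GROUPS:
            if g not in self.calibration_truth:
                raise ConfigurationError(f"calibration_truth missing group {g!r}")

    @property
    def n_visits(self) -> int:
        return sum(m * n for m, n in self.measurement_multiplicity.items())


# ---------------------------------------------------------------------------
# Chamber-series generator
# ---------------------------------------------------------------------------

def simulate_chamber_series(
    plot: str,
    visit: int,
    truth: tuple[float, float],
    cfg: SimulationConfig,
    geom: ChamberGeometry | None = None,
    rng: np.random.Generator | None = None,
    t_air: float | None = None,
) -> tuple[ConcentrationSeries, ConcentrationSeries]:
    """Generate the paired (light, dark) analyzer series for one visit.

    ``truth`` is the (NEE, ER) pair in µmol m⁻² s⁻¹.  The corrected
    concentration evolves linearly with the slope implied by inverting the
    ideal-gas flux equation for the true flux, plus Gaussian noise of sd
    ``chamber_noise_sd``; the wet-air CO2 column is then back-computed from
    a smooth positive H2O series so that the dilution correction recovers
    the linear series exactly.
    """
    nee, er = truth
    if not (np.isfinite(nee) and np.isfinite(er)):
        raise ConfigurationError("true fluxes must be finite")
    geom = geom or ChamberGeometry()
    rng = rng or np.random.default_rng(cfg.seed)
    if t_air is None:
        t_air = float(rng.normal(12.0, 2.0))
    dt = 1.0 / cfg.samples_per_second
    t = np.arange(0.0, 150.0 + dt / 2, dt)  # 30 s mixing + 120 s measurement

    out = []
    for mode, flux in (("light", nee), ("dark", er)):
        slope = slope_for_flux(flux, geom, t_air)
        c0 = float(rng.uniform(390.0, 420.0))
        corrected = c0 + slope * t
        if cfg.chamber_noise_sd > 0:
            corrected = corrected + rng.normal(0.0, cfg.chamber_noise_sd, size=t.shape)
        h0 = float(rng.uniform(6.0, 14.0))
        h2o = h0 + 0.004 * t  # slow evapotranspiration drift, mmol/mol
        co2 = corrected * (1.0 - h2o / 1000.0)
        if mode == "light":
            par_samples = np.clip(rng.normal(1100.0, 40.0, size=t.shape), 0.0, None)
        else:
            par_samples = np.clip(rng.normal(2.0, 1.5, size=t.shape), 0.0, None)
        out.append(ConcentrationSeries(
            plot=plot, visit=visit, mode=mode, t=t, co2=co2, h2o=h2o,
            par=float(par_samples.mean()), t_air=t_air, par_samples=par_samples,
        ))
    return out[0], out[1]


def _true_plot_fluxes(design: ExperimentDesign, cfg: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw each plot's true (NEE, ER, GEP) from community means + effects."""
    eff = cfg.treatment_effects.get("flux", {})
    rows = []
    for _, p in design.plots.iterrows():
        means = cfg.community_flux_means[p["community"]]
        gep, er = float(means["GEP"]), float(means["ER"])
        for factor in ("exclosure", "transplant"):
            if p[factor]:
                d = eff.get((p["community"], factor), {})
                gep += d.get("GEP", 0.0)
                er += d.get("ER", 0.0)
        gep += rng.normal(0.0, cfg.plot_flux_sd)
        er += rng.normal(0.0, cfg.plot_flux_sd)
        er = max(er, 0.1)  # respiration is always a source
        rows.append({"plot": p["plot"], "community": p["community"],
                     "true_GEP": gep, "true_ER": er, "true_NEE": gep + er})
    return pd.DataFrame(rows)


def assign_multiplicities(design: ExperimentDesign, cfg: SimulationConfig,
                          rng: np.random.Generator) -> pd.Series:
    """Assign the visit multiplicities (how often each plot was measured).

    The pooled multiplicity vector is shuffled uniformly at random over all
    plots (10 plots measured thrice, 61 twice, 25 once under the defaults).
    """
    cfg.validate(design)
    mult = np.concatenate([
        np.full(n, m, dtype=int) for m, n in sorted(cfg.measurement_multiplicity.items())
    ])
    rng.shuffle(mult)
    return pd.Series(mult, index=design.plots["plot"].to_numpy(), name="n_visits")


def simulate_visit_truth(
    design: ExperimentDesign,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the true per-visit (NEE, ER, GEP) table for the whole campaign.

    One row per plot visit (177 under the defaults): plot truth drawn from
    community means + treatment effects + between-plot noise, then perturbed
    by visit-to-visit drift.  This is the flux ground truth the chamber
    series encode; it can also drive the mixed-model stage directly when the
    per-second analyzer layer is not needed.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    truths = _true_plot_fluxes(design, cfg, rng)
    mult = assign_multiplicities(design, cfg, rng)
    rows = []
    for _, row in truths.iterrows():
        plot = row["plot"]
        for visit in range(1, int(mult[plot]) + 1):
            gep = row["true_GEP"] + rng.normal(0.0, cfg.visit_flux_sd)
            er = max(row["true_ER"] + rng.normal(0.0, cfg.visit_flux_sd), 0.05)
            rows.append({"plot": plot, "visit": visit,
                         "community": row["community"],
                         "true_NEE": gep + er, "true_ER": er, "true_GEP": gep})
    return pd.DataFrame(rows)


def simulate_campaign(
    design: ExperimentDesign,
    cfg: SimulationConfig,
    geom: ChamberGeometry | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full flux-measurement campaign.

    Returns ``(analyzer_log, truth)`` where ``analyzer_log`` is the
    long-format per-second log (one light + one dark series per visit) and
    ``truth`` records the true per-visit fluxes the generator used.
    """
    geom = geom or ChamberGeometry()
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_visit_truth(design, cfg, rng)
    log_parts = []
    for _, row in truth.iterrows():
        light, dark = simulate_chamber_series(
            row["plot"], int(row["visit"]), (row["true_NEE"], row["true_ER"]),
            cfg, geom=geom, rng=rng)
        for s in (light, dark):
            log_parts.append(pd.DataFrame({
                "plot": s.plot, "visit": s.visit, "mode": s.mode,
                "t": s.t, "co2": s.co2, "h2o": s.h2o,
                "par": s.par_samples, "t_air": s.t_air,
            }))
    log = pd.concat(log_parts, ignore_index=True)[LOG_COLUMNS]
    return log, truth


# ---------------------------------------------------------------------------
# Vegetation generator
# ---------------------------------------------------------------------------

def _negbin(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    """Negative-binomial draws parameterised by mean and dispersion (size)."""
    mean = max(mean, 0.05)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def simulate_vegetation(
    design: ExperimentDesign,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the point-intercept table and the harvest calibration table.

    Pin hits are overdispersed counts (negative binomial) around community
    × group means, shifted additively by the configured treatment effects.
    Harvest masses are ``truth.predict(hits) + N(0, residual_sd)`` on the
    g m⁻² scale, truncated at zero, then converted back to quadrat grams.
    """
    cfg.validate(design)
    rng = rng or np.random.default_rng(cfg.seed + 1)
    hit_eff = cfg.treatment_effects.get("hits", {})

    pin_rows = []
    for _, p in design.plots.iterrows():
        for g in FUNCTIONAL_GROUPS:
            mean = float(cfg.hit_means[p["community"]][g])
            for factor in ("exclosure", "transplant"):
                if p[factor]:
                    mean += hit_eff.get((p["community"], factor, g), 0.0)
            hits = int(_negbin(rng, mean, cfg.hit_dispersion, 1)[0])
            pin_rows.append({"plot": p["plot"], "community": p["community"],
                             "block": p["block"], "exclosure": p["exclosure"],
                             "transplant": p["transplant"], "code": p["code"],
                             "functional_group": g, "hits": hits})
    pins = pd.DataFrame(pin_rows)

    harvest_rows = []
    for _, h in design.harvest_plots.iterrows():
        side = float(h["quadrat_side_m"])
        for g in FUNCTIONAL_GROUPS:
            mean = float(cfg.hit_means[h["community"]][g])
            hits = int(_negbin(rng, mean, cfg.hit_dispersion, 1)[0])
            truth = cfg.calibration_truth[g]
            gm2 = float(truth.predict(hits))
            if truth.residual_sd > 0:
                gm2 += float(rng.normal(0.0, truth.residual_sd))
            gm2 = max(gm2, 0.0)
            harvest_rows.append({
                "plot": h["plot"], "community": h["community"], "block": h["block"],
                "functional_group": g, "hits": hits,
                "mass_g": gm2 * side**2, "quadrat_side_m": side,
            })
    return pins, pd.DataFrame(harvest_rows)


# ---------------------------------------------------------------------------
# Bundled synthetic experiment + table writers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExperiment:
    """Everything one simulated field season produces, with its ground truth."""

    design: ExperimentDesign
    config: SimulationConfig
    analyzer_log: pd.DataFrame
    flux_truth: pd.DataFrame
    pin_hits: pd.DataFrame
    harvest: pd.DataFrame


def simulate_experiment(
    cfg: SimulationConfig | None = None,
    design: ExperimentDesign | None = None,
    geom: ChamberGeometry | None = None,
) -> SyntheticExperiment:
    """Run the whole generator: design, chamber campaign, vegetation tables."""
    cfg = cfg or SimulationConfig()
    design = design or build_design()
    log, truth = simulate_campaign(design, cfg, geom=geom)
    pins, harvest = simulate_vegetation(design, cfg)
    return SyntheticExperiment(design=design, config=cfg, analyzer_log=log,
                               flux_truth=truth, pin_hits=pins, harvest=harvest)


def write_tables(exp: SyntheticExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write the design registry and all synthetic input tables as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "design": outdir / "design.csv",
        "harvest_plots": outdir / "harvest_plots.csv",
        "analyzer_log": outdir / "analyzer_log.csv",
        "flux_truth": outdir / "flux_truth.csv",
        "pin_hits": outdir / "pin_hits.csv",
        "harvest": outdir / "harvest.csv",
    }
    exp.design.plots.to_csv(paths["design"], index=False)
    exp.design.harvest_plots.to_csv(paths["harvest_plots"], index=False)
    exp.analyzer_log.to_csv(paths["analyzer_log"], index=False)
    exp.flux_truth.to_csv(paths["flux_truth"], index=False)
    exp.pin_hits.to_csv(paths["pin_hits"], index=False)
    exp.harvest.to_csv(paths["harvest"], index=False)
    return paths
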