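"""End-to-end pipeline: simulate → fluxes → biomass → stats → report.

Ties the stages together behind a single :class:`RunConfig`, with stable
comma-separated file contracts between stages, a manifest recording the
configuration hash, seed, library versions and per-stage row counts, and a
report-only table validator.  A persisted config plus seed reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels
import yaml

from . import biomass as biomass_mod
from . import fluxes as fluxes_mod
from . import stats as stats_mod
from .design import (
    DesignConfig,
    ExperimentDesign,
    SimulationConfig,
    build_design,
    simulate_experiment,
    write_tables,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "fluxes", "biomass", "stats")

FLUX_RESPONSES = ("GEP", "NEE", "ER")

#: Candidate fixed-effect structures for the flux model-selection table.
FLUX_CANDIDATES = (
    ("intercept", "1"),
    ("community", "C(community)"),
    ("treatment", "exclosure * transplant"),
    ("community+treatment", "C(community) + exclosure * transplant"),
    ("community*treatment", "C(community) * exclosure * transplant"),
)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage."""


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    outdir: str = "runs/run"
    stages: tuple[str, ...] = ALL_STAGES
    n_boot: int = biomass_mod.DEFAULT_N_BOOT
    water_correction: str = "dilution"
    window: tuple[float, float] = fluxes_mod.DEFAULT_WINDOW
    pressure_kpa: float = 90.0
    alpha: float = stats_mod.DEFAULT_ALPHA
    aicc_threshold: float = stats_mod.DEFAULT_AICC_THRESHOLD

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["window"] = list(self.window)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_stats(flux: pd.DataFrame, totals: pd.DataFrame, outdir: Path,
                 config: RunConfig) -> dict[str, int]:
    counts = {}
    # community comparison of total standing biomass
    anova, tukey = stats_mod.oneway_anova_tukey(
        totals["total_g_m2"], totals["community"], alpha=config.alpha)
    tukey.to_csv(outdir / "community_tukey.csv", index=False)
    pd.DataFrame([t.__dict__ for t in anova.terms]
                 + [{"name": "residual", "df": anova.residual_df,
                     "ss": anova.residual_ss, "F": np.nan, "p": np.nan}]
                 ).to_csv(outdir / "community_anova.csv", index=False)
    counts["community_tukey_rows"] = len(tukey)

    # per-community routed 2×2 factorial on total biomass
    rows = []
    for community, sub in totals.groupby("community"):
        routed = stats_mod.check_assumptions_and_route(
            sub["total_g_m2"], sub["exclosure"], sub["transplant"],
            alpha=config.alpha)
        if routed.anova is not None:
            for term in routed.anova.terms:
                rows.append({"community": community, "route": routed.route,
                             "term": term.name, "df": term.df, "F": term.F,
                             "p": term.p,
                             "residual_df": routed.anova.residual_df})
        else:
            rows.append({"community": community, "route": routed.route,
                         "term": "treatment(KW)", "df": routed.rank.kw_df,
                         "F": routed.rank.kw_H, "p": routed.rank.kw_p,
                         "residual_df": np.nan})
    pd.DataFrame(rows).to_csv(outdir / "factorial_totals.csv", index=False)
    counts["factorial_rows"] = len(rows)

    # flux mixed models: AICc selection + Tukey treatment contrasts
    sel_parts, contrast_parts = [], []
    flux_meta = flux.merge(
        totals[["plot", "community", "exclosure", "transplant", "code"]],
        on="plot", how="left")
    for response in FLUX_RESPONSES:
        candidates = [
            stats_mod.fit_flux_mixed_model(flux_meta, response, formula, label=label)
            for label, formula in FLUX_CANDIDATES
        ]
        table = stats_mod.select_by_aicc(candidates, threshold=config.aicc_threshold)
        table.insert(0, "response", response)
        sel_parts.append(table)
        no_int = stats_mod.fit_flux_mixed_model(
            flux_meta, response, "C(community) + C(code)", label="no-interactions")
        contrasts = stats_mod.tukey_contrasts_mixed(no_int, "code")
        contrasts.insert(0, "response", response)
        contrast_parts.append(contrasts)
    pd.concat(sel_parts, ignore_index=True).to_csv(
        outdir / "flux_model_selection.csv", index=False)
    pd.concat(contrast_parts, ignore_index=True).to_csv(
        outdir / "flux_tukey_contrasts.csv", index=False)
    counts["model_selection_rows"] = sum(len(t) for t in sel_parts)
    return counts


def run_pipeline(config: RunConfig,
                 sim_config: SimulationConfig | None = None,
                 design_config: DesignConfig | None = None) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    Returns the manifest dict.  A failure in any stage raises
    :class:`StageError` naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = build_design(design_config)
    sim = sim_config or SimulationConfig(seed=config.seed)
    geom = fluxes_mod.ChamberGeometry(P=config.pressure_kpa)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                     "scipy": scipy.__version__,
                     "statsmodels": statsmodels.__version__},
        "stages_run": [], "stages_skipped": [s for s in ALL_STAGES
                                             if s not in config.stages],
        "counts": {}, "files": {},
    }
    flux = totals = None
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            logger.info("stage %s skipped", stage)
            continue
        try:
            if stage == "simulate":
                exp = simulate_experiment(sim, design, geom=geom)
                write_tables(exp, outdir)
                state["exp"] = exp
                manifest["counts"].update({
                    "plots": design.n_plots,
                    "harvest_plots": design.n_harvest_plots,
                    "transplants": design.n_transplants,
                    "flux_visits": int(len(exp.flux_truth)),
                    "analyzer_rows": int(len(exp.analyzer_log)),
                })
            elif stage == "fluxes":
                log = state["exp"].analyzer_log if "exp" in state else \
                    pd.read_csv(outdir / "analyzer_log.csv")
                flux = fluxes_mod.fluxes_from_log(
                    log, geom, window=config.window,
                    water_correction=config.water_correction)
                flux.to_csv(outdir / "fluxes.csv", index=False)
                manifest["counts"]["flux_rows"] = int(len(flux))
            elif stage == "biomass":
                exp = state.get("exp")
                harvest = exp.harvest if exp else pd.read_csv(outdir / "harvest.csv")
                pins = exp.pin_hits if exp else pd.read_csv(outdir / "pin_hits.csv")
                bio, totals, models = biomass_mod.estimate_all(
                    harvest, pins, design, n_boot=config.n_boot, seed=config.seed)
                bio.to_csv(outdir / "biomass.csv", index=False)
                totals.to_csv(outdir / "biomass_totals.csv", index=False)
                pd.DataFrame([
                    {"functional_group": g, "scope": s, "form": m.form,
                     "coefficients": json.dumps(list(m.coefficients)),
                     "r2": m.r2, "normality_p": m.residual_normality_p,
                     "residual_sd": m.residual_sd, "n": m.n}
                    for (g, s), m in sorted(models.items())
                ]).to_csv(outdir / "calibration_report.csv", index=False)
                manifest["counts"]["biomass_rows"] = int(len(bio))
            elif stage == "stats":
                if flux is None:
                    flux = pd.read_csv(outdir / "fluxes.csv")
                if totals is None:
                    totals = pd.read_csv(outdir / "biomass_totals.csv")
                manifest["counts"].update(
                    _stage_stats(flux, totals, outdir, config))
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages_run"].append(stage)
    for f in sorted(outdir.glob("*.csv")):
        manifest["files"][f.name] = _sha256(f)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = {
    "analyzer_log": fluxes_mod.LOG_COLUMNS,
    "pin_hits": ["plot", "community", "functional_group", "hits"],
    "harvest": ["community", "block", "functional_group", "hits", "mass_g",
                "quadrat_side_m"],
    "design": ["plot", "community", "block", "exclosure", "transplant", "code"],
}


def validate_tables(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Report-only validation of the pipeline's input tables.

    Checks column presence, pairing of light/dark series, monotone
    timestamps, non-negative hits and masses, and treatment-cell
    completeness against the design.  Returns a violations table (empty if
    everything checks out); never raises.
    """
    violations: list[dict] = []

    def add(table, row, column, message):
        violations.append({"table": table, "row": row, "column": column,
                           "message": message})

    for name, df in tables.items():
        req = REQUIRED_COLUMNS.get(name)
        if req:
            for col in req:
                if col not in df.columns:
                    add(name, None, col, "missing column")

    log = tables.get("analyzer_log")
    if log is not None and all(c in log.columns for c in fluxes_mod.LOG_COLUMNS):
        modes = log.groupby(["plot", "visit"])["mode"].agg(set)
        for (plot, visit), mset in modes.items():
            if "dark" not in mset:
                add("analyzer_log", None, "mode",
                    f"unpaired light measurement: plot {plot} visit {visit}")
            if "light" not in mset:
                add("analyzer_log", None, "mode",
                    f"unpaired dark measurement: plot {plot} visit {visit}")
        for key, g in log.groupby(["plot", "visit", "mode"]):
            t = g["t"].to_numpy()
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                add("analyzer_log", None, "t",
                    f"non-monotone timestamps in series {key}")

    for name, col in (("pin_hits", "hits"), ("harvest", "hits"),
                      ("harvest", "mass_g")):
        df = tables.get(name)
        if df is not None and col in df.columns:
            bad = df.index[df[col] < 0]
            for idx in bad:
                add(name, int(idx), col, f"negative {col}")

    design = tables.get("design")
    if design is not None and {"community", "block", "code"} <= set(design.columns):
        for (community, block), g in design.groupby(["community", "block"]):
            missing = {"C", "E", "ET", "T"} - set(g["code"])
            if missing:
                add("design", None, "code",
                    f"{community} block {block} missing treatment cells {sorted(missing)}")

    return pd.DataFrame(violations, columns=["table", "row", "column", "message"])
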