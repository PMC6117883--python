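"""Closed-chamber CO2 flux estimation.

Converts raw chamber concentration time series into per-visit net ecosystem
exchange (NEE, light chamber), ecosystem respiration (ER, darkened chamber)
and gross ecosystem photosynthesis (GEP = NEE - ER), with optional
standardization of GEP to a reference PAR level via a rectangular-hyperbola
light-response fit.

Sign convention: negative NEE/GEP denote a CO2 sink, positive a source.

The flux is derived from the ideal gas law: the chamber headspace holds
n = P V / (R T) moles of air, so a rate of change d'C/dt of the (dry-air
corrected) CO2 mole fraction in µmol mol⁻¹ s⁻¹ over a footprint of S m²
corresponds to

    flux = (V · P) / (R · T · S) · d'C/dt   [µmol m⁻² s⁻¹]

with P in Pa and T in K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: Ideal gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314

#: Slope-fit window in seconds since chamber sealing: the measurement starts
#: after a 30 s mixing period and lasts 120 s.
DEFAULT_WINDOW = (30.0, 150.0)

#: Dark measurements should be near-dark; higher PAR is flagged, not dropped.
DARK_PAR_WARN_THRESHOLD = 130.0

#: Dark-fit r² floor below which a visit is flagged (never dropped).
DEFAULT_R2_FLOOR = 0.8


class InsufficientDataError(ValueError):
    """Too few samples (or PAR levels) to perform the requested fit."""


class DegenerateRegressionError(ValueError):
    """The regression design is degenerate (e.g. zero time variance)."""


class PairingError(ValueError):
    """Light and dark series do not belong to the same plot visit."""


class LightCurveFitError(RuntimeError):
    """The light-response fit failed to converge; carries diagnostics."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber dimensions and ambient pressure.

    Defaults describe a 0.5 × 0.5 × 0.6 m chamber over a 0.25 m² plot at
    ~1100 m elevation (≈ 90 kPa).
    """

    V: float = 0.5 * 0.5 * 0.6   # chamber volume, m³
    S: float = 0.25              # footprint surface area, m²
    P: float = 90.0              # air pressure, kPa

    def __post_init__(self) -> None:
        for name in ("V", "S", "P"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ChamberGeometry.{name} must be positive")


@dataclass
class ConcentrationSeries:
    """One chamber deployment: CO2/H2O samples plus visit metadata.

    ``t`` is seconds since sealing; ``co2`` in µmol mol⁻¹ (wet air), ``h2o``
    in mmol mol⁻¹.  ``par`` is the mean PAR during the measurement and
    ``t_air`` the mean air temperature in °C.
    """

    plot: str
    visit: int
    mode: str                    # "light" | "dark"
    t: np.ndarray
    co2: np.ndarray
    h2o: np.ndarray
    par: float
    t_air: float
    par_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        self.h2o = np.asarray(self.h2o, dtype=float)
        if self.mode not in ("light", "dark"):
            raise ValueError(f"mode must be 'light' or 'dark', got {self.mode!r}")
        if not (len(self.t) == len(self.co2) == len(self.h2o)):
            raise ValueError("t, co2, h2o must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.co2 <= 0):
            raise ValueError("co2 mole fractions must be positive")
        if np.any((self.h2o < 0) | (self.h2o >= 1000)):
            raise ValueError("h2o mole fractions must be in [0, 1000) mmol/mol")

    def n_in_window(self, window: tuple[float, float] = DEFAULT_WINDOW) -> int:
        lo, hi = window
        return int(np.count_nonzero((self.t >= lo) & (self.t <= hi)))


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of corrected concentration on time."""

    dCdt: float       # slope, µmol mol⁻¹ s⁻¹
    intercept: float
    r2: float
    n: int


@dataclass(frozen=True)
class FluxTriple:
    """Per plot-visit NEE, ER and GEP (µmol m⁻² s⁻¹), sink-negative."""

    plot: str
    visit: int
    NEE: float
    ER: float
    GEP: float
    GEP600: float | None = None
    r2_light: float = float("nan")
    r2_dark: float = float("nan")
    par_light: float = float("nan")
    par_dark: float = float("nan")
    t_air: float = float("nan")
    flagged: bool = False


@dataclass(frozen=True)
class LightResponseFit:
    """Fitted rectangular hyperbola GEP(PAR) = GEP_max · PAR / (k + PAR)."""

    gep_max: float
    k: float
    rss: float
    n: int

    def predict(self, par: float) -> float:
        return self.gep_max * par / (self.k + par)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def correct_for_water(co2, h2o, form: str = "dilution"):
    """Correct a wet-air CO2 mole fraction for water-vapour content.

    Parameters
    ----------
    co2 : float or array, µmol mol⁻¹ (must be > 0)
    h2o : float or array, mmol mol⁻¹ (must be in [0, 1000))
    form : {"dilution", "as_printed"}
        ``dilution`` (default) returns the dry-air mole fraction
        ``co2 / (1 - h2o/1000)``.  ``as_printed`` returns the literal ratio
        ``co2 / h2o`` (requires h2o > 0), retained for fidelity with analyses
        that divided by the water mole fraction directly.
    """
    co2 = np.asarray(co2, dtype=float)
    h2o = np.asarray(h2o, dtype=float)
    if np.any(co2 <= 0):
        raise ValueError("co2 must be positive")
    if np.any((h2o < 0) | (h2o >= 1000)):
        raise ValueError("h2o must be in [0, 1000) mmol/mol")
    if form == "dilution":
        out = co2 / (1.0 - h2o / 1000.0)
    elif form == "as_printed":
        if np.any(h2o == 0):
            raise ZeroDivisionError("as_printed correction undefined for h2o = 0")
        out = co2 / h2o
    else:
        raise ValueError(f"unknown correction form {form!r}")
    return float(out) if out.ndim == 0 else out


def fit_slope(
    series: ConcentrationSeries,
    window: tuple[float, float] = DEFAULT_WINDOW,
    water_correction: str = "dilution",
) -> SlopeFit:
    """OLS regression of water-corrected CO2 concentration on time.

    Only samples with ``window[0] <= t <= window[1]`` (seconds since
    sealing) enter the fit.
    """
    lo, hi = window
    mask = (series.t >= lo) & (series.t <= hi)
    n = int(np.count_nonzero(mask))
    if n < 2:
        raise InsufficientDataError(
            f"{n} samples in window [{lo}, {hi}] s for plot {series.plot}; need >= 2"
        )
    t = series.t[mask]
    if np.ptp(t) == 0:
        raise DegenerateRegressionError("zero time variance inside the window")
    c = correct_for_water(series.co2[mask], series.h2o[mask], form=water_correction)
    res = stats.linregress(t, c)
    r2 = float(res.rvalue**2)
    if math.isnan(r2):  # constant response: slope 0, perfect "fit" of a flat line
        r2 = 1.0
    return SlopeFit(dCdt=float(res.slope), intercept=float(res.intercept), r2=r2, n=n)


def compute_flux(fit: SlopeFit | float, geom: ChamberGeometry, t_air: float) -> float:
    """Ideal-gas conversion of a concentration slope to a surface flux.

    flux = V·P_pa / (R · T_K · S) · dCdt, in µmol m⁻² s⁻¹; pressure is
    converted from kPa to Pa and air temperature from °C to K.
    """
    if t_air <= -273.15:
        raise ValueError(f"non-physical air temperature {t_air} °C")
    dCdt = fit.dCdt if isinstance(fit, SlopeFit) else float(fit)
    p_pa = geom.P * 1000.0
    t_k = t_air + 273.15
    return (geom.V * p_pa) / (R_GAS * t_k * geom.S) * dCdt


def slope_for_flux(flux: float, geom: ChamberGeometry, t_air: float) -> float:
    """Inverse of :func:`compute_flux`: the d'C/dt implied by a true flux.

    Used by the synthetic-data generator so that a noise-free generated
    series round-trips to the configured flux exactly.
    """
    if t_air <= -273.15:
        raise ValueError(f"non-physical air temperature {t_air} °C")
    p_pa = geom.P * 1000.0
    t_k = t_air + 273.15
    return flux * (R_GAS * t_k * geom.S) / (geom.V * p_pa)


def assemble_fluxes(
    light: ConcentrationSeries,
    dark: ConcentrationSeries,
    geom: ChamberGeometry,
    window: tuple[float, float] = DEFAULT_WINDOW,
    water_correction: str = "dilution",
    r2_floor: float = DEFAULT_R2_FLOOR,
    dark_par_threshold: float = DARK_PAR_WARN_THRESHOLD,
) -> FluxTriple:
    """Compute the NEE/ER/GEP triple for one paired light/dark visit.

    NEE comes from the light series, ER from the dark series, and
    GEP = NEE - ER by construction.  Visits with a poor dark fit
    (r² < ``r2_floor``) or suspiciously bright dark measurements are
    flagged but never dropped.
    """
    if (light.plot, light.visit) != (dark.plot, dark.visit):
        raise PairingError(
            f"light series ({light.plot}, visit {dark.visit}) does not match "
            f"dark series ({dark.plot}, visit {dark.visit})"
        )
    if light.mode != "light" or dark.mode != "dark":
        raise PairingError("series modes must be (light, dark)")
    if dark.par > dark_par_threshold:
        logger.warning(
            "dark measurement on plot %s visit %d has PAR %.1f µmol m-2 s-1",
            dark.plot, dark.visit, dark.par,
        )
    fit_l = fit_slope(light, window, water_correction)
    fit_d = fit_slope(dark, window, water_correction)
    nee = compute_flux(fit_l, geom, light.t_air)
    er = compute_flux(fit_d, geom, dark.t_air)
    flagged = fit_d.r2 < r2_floor
    return FluxTriple(
        plot=light.plot,
        visit=light.visit,
        NEE=nee,
        ER=er,
        GEP=nee - er,
        r2_light=fit_l.r2,
        r2_dark=fit_d.r2,
        par_light=light.par,
        par_dark=dark.par,
        t_air=light.t_air,
        flagged=flagged,
    )


def fit_light_response(par: Sequence[float], gep: Sequence[float]) -> LightResponseFit:
    """Least-squares fit of the rectangular hyperbola GEP_max·PAR/(k+PAR)."""
    par = np.asarray(par, dtype=float)
    gep = np.asarray(gep, dtype=float)
    if len(np.unique(par)) < 3:
        raise InsufficientDataError("need >= 3 distinct PAR levels for a light curve")
    s = np.sign(np.median(gep[gep != 0])) if np.any(gep != 0) else -1.0
    if np.any(np.sign(gep[gep != 0]) != s):
        raise ValueError("GEP values must be of consistent sign")

    def hyper(p, gmax, k):
        return gmax * p / (k + p)

    g0 = gep[np.argmax(par)] * 1.2 if np.any(gep != 0) else -1.0
    try:
        popt, _ = optimize.curve_fit(
            hyper, par, gep, p0=[g0, np.median(par)], maxfev=10000,
            bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise LightCurveFitError(
            f"light-response fit did not converge (n={len(par)}, "
            f"PAR range [{par.min():.0f}, {par.max():.0f}]): {exc}"
        ) from exc
    resid = gep - hyper(par, *popt)
    return LightResponseFit(gep_max=float(popt[0]), k=float(popt[1]),
                            rss=float(resid @ resid), n=len(par))


def standardize_gep(
    light_curve: Sequence[tuple[float, float]],
    reference_par: float = 600.0,
) -> float:
    """Standardize GEP to a reference PAR from >= 3 (PAR, GEP) shading levels.

    Fits the rectangular-hyperbola light response and returns its prediction
    at ``reference_par`` (default 600 µmol m⁻² s⁻¹).
    """
    pairs = np.asarray(light_curve, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("light_curve must be a sequence of (PAR, GEP) pairs")
    par, gep = pairs[:, 0], pairs[:, 1]
    if len(np.unique(par)) < 3 and np.all(par == reference_par):
        # every shading level was measured at the reference PAR itself:
        # no extrapolation needed
        return float(np.mean(gep))
    fit = fit_light_response(par, gep)
    return fit.predict(reference_par)


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------

LOG_COLUMNS = ["plot", "visit", "mode", "t", "co2", "h2o", "par", "t_air"]


def series_from_log(df: pd.DataFrame) -> list[ConcentrationSeries]:
    """Build ConcentrationSeries objects from a long-format analyzer log.

    Expects one row per second with columns ``plot, visit, mode, t, co2,
    h2o, par, t_air``.
    """
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"analyzer log is missing columns: {missing}")
    out = []
    for (plot, visit, mode), g in df.groupby(["plot", "visit", "mode"], sort=True):
        g = g.sort_values("t")
        out.append(ConcentrationSeries(
            plot=str(plot), visit=int(visit), mode=str(mode),
            t=g["t"].to_numpy(), co2=g["co2"].to_numpy(), h2o=g["h2o"].to_numpy(),
            par=float(g["par"].mean()), t_air=float(g["t_air"].mean()),
            par_samples=g["par"].to_numpy(),
        ))
    return out


def fluxes_from_log(
    df: pd.DataFrame,
    geom: ChamberGeometry | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    water_correction: str = "dilution",
) -> pd.DataFrame:
    """Compute the full flux table (one row per plot visit) from an analyzer log."""
    geom = geom or ChamberGeometry()
    series = series_from_log(df)
    by_key: dict[tuple[str, int], dict[str, ConcentrationSeries]] = {}
    for s in series:
        by_key.setdefault((s.plot, s.visit), {})[s.mode] = s
    rows = []
    for (plot, visit), pair in sorted(by_key.items()):
        if "light" not in pair or "dark" not in pair:
            missing = "dark" if "dark" not in pair else "light"
            raise PairingError(f"plot {plot} visit {visit} is missing its {missing} series")
        triple = assemble_fluxes(pair["light"], pair["dark"], geom,
                                 window=window, water_correction=water_correction)
        rows.append(triple.__dict__)
    return pd.DataFrame(rows)
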