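"""Treatment inference for the factorial exclosure × transplant experiment.

The inference battery mirrors a standard ecological field-experiment
workflow:

* one-way ANOVA with Tukey HSD for community-level differences;
* per-community 2×2 factorial ANOVA (exclosure × transplant), with an
  assumption-checking router that falls back to an ln transform and, if
  that is still inadequate, to a Kruskal–Wallis test on the combined
  4-level treatment factor followed by Dunn's post-hoc comparisons;
* Gaussian random-intercept mixed models for the repeated flux
  measurements (plot as random effect), compared by small-sample-corrected
  AICc with the conventional dAICc < 2 equal-support rule, and Tukey-style
  simultaneous contrasts on models without interactions.

Mixed models are fit by maximum likelihood (not REML) so that AICc values
are comparable across different fixed-effect structures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_AICC_THRESHOLD = 2.0
#: Additive shift applied before an ln transform when zeros are present.
LN_SHIFT = 1e-3


class DesignError(ValueError):
    """A factor cell is empty or a factor is absent from the fitted model."""


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaTerm:
    name: str
    df: int
    ss: float
    F: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    terms: tuple[AnovaTerm, ...]
    residual_df: int
    residual_ss: float
    transform_applied: str = "none"   # none | ln

    def term(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def total_ss(self) -> float:
        return self.residual_ss + sum(t.ss for t in self.terms)


@dataclass(frozen=True)
class DunnComparison:
    group_a: str
    group_b: str
    z: float
    p: float
    p_adjusted: float


@dataclass(frozen=True)
class RankTestResult:
    kw_H: float
    kw_df: int
    kw_p: float
    dunn_pairs: tuple[DunnComparison, ...]


@dataclass(frozen=True)
class RoutedTestResult:
    route: str                       # parametric | ln | nonparametric
    anova: AnovaResult | None
    rank: RankTestResult | None
    shapiro_p: float
    levene_p: float
    ln_shift: float = 0.0


@dataclass
class MixedModelResult:
    """A fitted Gaussian random-intercept model plus selection metadata."""

    label: str
    formula: str
    fe_params: pd.Series
    fe_se: pd.Series
    cov_fe: pd.DataFrame
    var_plot: float
    var_resid: float
    llf: float
    k: int
    n_obs: int
    n_plots: int
    converged: bool

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k, self.n_obs)


# ---------------------------------------------------------------------------
# One-way ANOVA + Tukey HSD across communities
# ---------------------------------------------------------------------------

def oneway_anova_tukey(values, groups, alpha: float = DEFAULT_ALPHA
                       ) -> tuple[AnovaResult, pd.DataFrame]:
    """Classical one-way decomposition plus Tukey HSD pairwise comparisons."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) < 2:
        raise DesignError("need >= 2 groups for a one-way ANOVA")
    for lab in labels:
        if np.count_nonzero(g == lab) < 2:
            raise DesignError(f"group {lab!r} has < 2 values")
    grand = y.mean()
    ss_between = sum(np.count_nonzero(g == lab) * (y[g == lab].mean() - grand) ** 2
                     for lab in labels)
    ss_within = sum(float(np.sum((y[g == lab] - y[g == lab].mean()) ** 2))
                    for lab in labels)
    df_b, df_w = len(labels) - 1, len(y) - len(labels)
    if ss_within == 0 and ss_between == 0:
        f_stat, p = 0.0, 1.0
    else:
        ms_w = ss_within / df_w
        f_stat = (ss_between / df_b) / ms_w if ms_w > 0 else np.inf
        p = float(stats.f.sf(f_stat, df_b, df_w)) if np.isfinite(f_stat) else 0.0
    result = AnovaResult(
        terms=(AnovaTerm("group", df_b, float(ss_between), float(f_stat), p),),
        residual_df=df_w, residual_ss=float(ss_within),
    )
    tk = pairwise_tukeyhsd(y, g, alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return result, tukey


# ---------------------------------------------------------------------------
# 2×2 factorial ANOVA
# ---------------------------------------------------------------------------

def _sequential_anova(y: np.ndarray, columns: list[tuple[str, np.ndarray]],
                      transform: str = "none") -> AnovaResult:
    """Sequential (type-I) sums of squares via nested least squares.

    For balanced designs the sequential, marginal and partial decompositions
    coincide, so this also reproduces the classical balanced-factorial table.
    """
    n = len(y)
    X = np.ones((n, 1))
    rss_prev = float(np.sum((y - y.mean()) ** 2))
    terms = []
    for name, col in columns:
        X = np.column_stack([X, col])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        terms.append([name, 1, max(rss_prev - rss, 0.0)])
        rss_prev = rss
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise DesignError("no residual degrees of freedom")
    ms_resid = rss_prev / df_resid
    out = []
    for name, df_t, ss in terms:
        if ms_resid > 0:
            f_stat = (ss / df_t) / ms_resid
            p = float(stats.f.sf(f_stat, df_t, df_resid))
        else:
            f_stat, p = (np.inf, 0.0) if ss > 0 else (0.0, 1.0)
        out.append(AnovaTerm(name, df_t, ss, float(f_stat), p))
    return AnovaResult(terms=tuple(out), residual_df=df_resid,
                       residual_ss=rss_prev, transform_applied=transform)


def factorial_anova(values, exclosure, transplant, transform: str = "none"
                    ) -> AnovaResult:
    """2×2 factorial ANOVA with main effects and their interaction.

    ``exclosure`` and ``transplant`` are 0/1 indicators.  With 8 blocks per
    community (32 plots) each effect has 1 df against 28 residual df.
    """
    y = np.asarray(values, dtype=float)
    e = np.asarray(exclosure, dtype=float)
    t = np.asarray(transplant, dtype=float)
    if not (len(y) == len(e) == len(t)):
        raise DesignError("values and factors must have equal length")
    for name, f in (("exclosure", e), ("transplant", t)):
        if set(np.unique(f)) != {0.0, 1.0}:
            raise DesignError(f"factor {name} must take both levels 0 and 1")
    for ee in (0, 1):
        for tt in (0, 1):
            if not np.any((e == ee) & (t == tt)):
                raise DesignError(f"empty cell: exclosure={ee}, transplant={tt}")
    return _sequential_anova(y, [("exclosure", e), ("transplant", t),
                                 ("exclosure:transplant", e * t)], transform)


def _factorial_residuals(y, e, t):
    X = np.column_stack([np.ones_like(y), e, t, e * t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def check_assumptions_and_route(values, exclosure, transplant,
                                alpha: float = DEFAULT_ALPHA) -> RoutedTestResult:
    """Run the factorial test with assumption checking and fallbacks.

    Residual normality (Shapiro–Wilk) and variance homogeneity across the
    four cells (Levene) are checked on the factorial fit; failure triggers
    a retry on ln-transformed values (shifted by a small constant if zeros
    are present), and persistent failure routes to Kruskal–Wallis + Dunn on
    the combined 4-level treatment factor.  Always returns a result.
    """
    y = np.asarray(values, dtype=float)
    e = np.asarray(exclosure, dtype=float)
    t = np.asarray(transplant, dtype=float)
    # combined code: C=(0,0), E=(1,0), T=(0,1), ET=(1,1)
    codes = np.where((e == 1) & (t == 1), "ET",
                     np.where(e == 1, "E", np.where(t == 1, "T", "C")))

    def _check(yy):
        resid = _factorial_residuals(yy, e, t)
        if np.allclose(resid, resid[0]):
            return 1.0, 1.0
        sw = float(stats.shapiro(resid).pvalue)
        cells = [yy[(e == ee) & (t == tt)] for ee in (0, 1) for tt in (0, 1)]
        lv = float(stats.levene(*cells).pvalue)
        return sw, lv

    sw, lv = _check(y)
    if sw >= alpha and lv >= alpha:
        return RoutedTestResult("parametric", factorial_anova(y, e, t), None, sw, lv)

    shift = 0.0
    if np.all(y > 0):
        y_ln = np.log(y)
    elif np.all(y >= 0):
        shift = LN_SHIFT
        logger.info("ln route: zeros present, shifting by %g before log", shift)
        y_ln = np.log(y + shift)
    else:
        y_ln = None
    if y_ln is not None:
        sw2, lv2 = _check(y_ln)
        if sw2 >= alpha and lv2 >= alpha:
            return RoutedTestResult("ln", factorial_anova(y_ln, e, t, transform="ln"),
                                    None, sw2, lv2, ln_shift=shift)

    rank = kruskal_dunn(y, codes)
    return RoutedTestResult("nonparametric", None, rank, sw, lv, ln_shift=shift)


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Dunn
# ---------------------------------------------------------------------------

def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return pvals
    if method == "bonferroni":
        return np.minimum(pvals * len(pvals), 1.0)
    if method == "holm":
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def kruskal_dunn(values, groups, adjust: str = "none") -> RankTestResult:
    """Kruskal–Wallis H (tie-corrected) plus Dunn's pairwise z comparisons.

    The multiplicity adjustment for the Dunn p-values is configurable
    (none, bonferroni, holm); the default reports unadjusted p-values.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = [lab for lab in pd.unique(g)]
    if sum(np.any(g == lab) for lab in labels) < 2:
        raise DesignError("need >= 2 non-empty groups")
    if np.all(y == y[0]):
        pairs = tuple(DunnComparison(str(a), str(b), 0.0, 1.0, 1.0)
                      for i, a in enumerate(labels) for b in labels[i + 1:])
        return RankTestResult(0.0, len(labels) - 1, 1.0, pairs)
    samples = [y[g == lab] for lab in labels]
    kw = stats.kruskal(*samples)
    n_tot = len(y)
    ranks = stats.rankdata(y)
    # tie correction for the Dunn variance
    _, counts = np.unique(y, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term
    mean_ranks = {lab: float(ranks[g == lab].mean()) for lab in labels}
    ns = {lab: int(np.count_nonzero(g == lab)) for lab in labels}
    zs, raw_p, pair_labels = [], [], []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = np.sqrt(base_var * (1.0 / ns[a] + 1.0 / ns[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            zs.append(z)
            raw_p.append(2.0 * stats.norm.sf(abs(z)))
            pair_labels.append((str(a), str(b)))
    adj = _adjust(np.asarray(raw_p), adjust)
    pairs = tuple(DunnComparison(a, b, float(z), float(p), float(pa))
                  for (a, b), z, p, pa in zip(pair_labels, zs, raw_p, adj))
    return RankTestResult(float(kw.statistic), len(labels) - 1,
                          float(kw.pvalue), pairs)


# ---------------------------------------------------------------------------
# Mixed models, AICc, Tukey contrasts
# ---------------------------------------------------------------------------

def aicc(llf: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2ℓ + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n - k - 1 <= 0)")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def ln_magnitude(flux: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """ln of the flux magnitude (the sign convention is carried separately).

    NEE and GEP are predominantly negative under the sink-negative
    convention, so the ln transform is applied to |flux|.
    """
    return np.log(np.maximum(np.abs(np.asarray(flux, dtype=float)), floor))


def fit_flux_mixed_model(
    data: pd.DataFrame,
    response: str,
    fixed: str,
    group_col: str = "plot",
    transform: str = "ln_abs",
    reml: bool = False,
    label: str | None = None,
) -> MixedModelResult:
    """Fit a Gaussian random-intercept model for repeated flux measurements.

    ``fixed`` is a patsy right-hand side (e.g. ``"exclosure * transplant"``
    or ``"C(community)"``); plot enters as a random intercept.  ML fitting
    is the default so AICc comparisons across fixed structures are valid.
    """
    df = data.copy()
    y = df[response].to_numpy(dtype=float)
    df["_y"] = ln_magnitude(y) if transform == "ln_abs" else y
    n_plots = df[group_col].nunique()
    if n_plots < 2:
        raise DesignError("need >= 2 plots for a random-intercept model")
    if (df.groupby(group_col).size() < 2).all():
        logger.warning("no plot has repeated measures; random-intercept "
                       "variance is not identifiable and will be ~0")
    model = smf.mixedlm(f"_y ~ {fixed}", df, groups=df[group_col])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=reml, method=["lbfgs", "powell"])
        fe = res.fe_params
        var_plot = float(res.cov_re.iloc[0, 0])
        var_resid = float(res.scale)
        llf = float(res.llf)
        cov_fe = res.cov_params().loc[fe.index, fe.index]
        fe_se = res.bse_fe
        converged = bool(res.converged)
    except np.linalg.LinAlgError:
        # boundary optimum (random-intercept variance ~0): the marginal
        # model collapses to OLS; pin the variance to 0 and warn
        logger.warning("random-intercept variance hit the boundary; "
                       "pinning it to 0 (OLS fit)")
        ols = smf.ols(f"_y ~ {fixed}", df).fit()
        fe = ols.params
        var_plot = 0.0
        var_resid = float(ols.ssr / len(df))  # ML residual variance
        llf = float(-0.5 * len(df) * (np.log(2 * np.pi * var_resid) + 1.0))
        cov_fe = ols.cov_params() * (var_resid / ols.mse_resid)
        fe_se = np.sqrt(np.diag(cov_fe))
        fe_se = pd.Series(fe_se, index=fe.index)
        converged = True
    k = len(fe) + 2  # + random-intercept variance + residual variance
    return MixedModelResult(
        label=label or fixed, formula=f"_y ~ {fixed}",
        fe_params=fe, fe_se=fe_se, cov_fe=cov_fe,
        var_plot=var_plot, var_resid=var_resid,
        llf=llf, k=k, n_obs=len(df), n_plots=n_plots,
        converged=converged,
    )


def select_by_aicc(candidates: list[MixedModelResult],
                   threshold: float = DEFAULT_AICC_THRESHOLD) -> pd.DataFrame:
    """Rank candidate models by AICc and flag the dAICc < threshold set.

    All candidates must have been fit to the same response vector (same
    n_obs) for the comparison to be meaningful.
    """
    if not candidates:
        raise ValueError("no candidate models")
    ns = {m.n_obs for m in candidates}
    if len(ns) != 1:
        raise ValueError(f"candidates fit to different response lengths: {ns}")
    rows = [{"label": m.label, "k": m.k, "llf": m.llf, "AICc": m.aicc}
            for m in candidates]
    table = pd.DataFrame(rows).sort_values("AICc", ignore_index=True)
    table["dAICc"] = table["AICc"] - table["AICc"].iloc[0]
    table["selected"] = table["dAICc"] < threshold
    return table


def tukey_contrasts_mixed(model: MixedModelResult, factor: str) -> pd.DataFrame:
    """Simultaneous pairwise comparisons of a factor's levels in a mixed model.

    Uses the fixed-effect estimates and their covariance; family-wise
    adjustment via the studentized-range distribution (the Tukey method).
    The model must have been fit without interactions involving ``factor``.
    """
    prefix = f"C({factor})[T."
    level_params = [p for p in model.fe_params.index if p.startswith(prefix)]
    is_binary = factor in model.fe_params.index
    if not level_params and not is_binary:
        raise DesignError(f"factor {factor!r} not found in the fitted model")
    if is_binary:
        levels = {f"{factor}=0": None, f"{factor}=1": factor}
    else:
        base = f"{factor}[base]"
        levels = {base: None}
        for p in level_params:
            levels[p[len(prefix):-1]] = p
    names = list(levels)
    n_levels = len(names)
    df_resid = model.n_obs - len(model.fe_params)
    rows = []
    for i in range(n_levels):
        for j in range(i + 1, n_levels):
            pi, pj = levels[names[i]], levels[names[j]]
            est = (model.fe_params.get(pj, 0.0) if pj else 0.0) - \
                  (model.fe_params.get(pi, 0.0) if pi else 0.0)
            var = 0.0
            if pi and pj:
                var = (model.cov_fe.loc[pi, pi] + model.cov_fe.loc[pj, pj]
                       - 2 * model.cov_fe.loc[pi, pj])
            elif pi or pj:
                p = pi or pj
                var = model.cov_fe.loc[p, p]
            se = float(np.sqrt(var))
            z = est / se if se > 0 else 0.0
            q = abs(z) * np.sqrt(2.0)
            p_adj = float(stats.studentized_range.sf(q, n_levels, df_resid))
            rows.append({"contrast": f"{names[j]} - {names[i]}",
                         "estimate": float(est), "se": se, "z": float(z),
                         "p_adjusted": p_adj})
    return pd.DataFrame(rows)


def likelihood_ratio_test(llf_null: float, llf_full: float, df: int
                          ) -> tuple[float, float]:
    """Generic nested-model likelihood-ratio test: returns (χ², p)."""
    if df <= 0:
        raise ValueError("df must be positive")
    chi2 = max(2.0 * (llf_full - llf_null), 0.0)
    return chi2, float(stats.chi2.sf(chi2, df))
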