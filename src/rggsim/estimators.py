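"""Realized-genetic-gain (RGG) estimation models for MET entry-mean records.

The registry covers the benchmark G x L x Y eBLUP model and its variants
(EB, E0 family), fixed-genotype eBLUE regression (E1 family), direct
regression on the first year of testing (E2/E3), last-year-only subsets
(E4/E5), the control-population contrast (E6), two-step check-calibrated
models (E7/E8), the forward-backward year-chaining model (E9), combining
ability models using pedigree from the breeder-trial stage (E10-E14), and a
raw phenotypic regression ("Pheno").

Estimates are classified as *direct* (the gain is a regression coefficient
inside the mixed model: beta_g on the first test year r_i, beta_t on the
calendar year, or beta_f on the crossing year w_i) or *indirect* (predicted
or estimated genotype values are regressed on year in a second step, either
line-by-line or through the cumulative-sum kappa estimator).  Check
cultivars calibrate environments but never contribute to the gain itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import genomic_relationship
from .lmm import FitResult, ModelSpec, RandomEffect, fit_reml

__all__ = [
    "MODEL_IDS",
    "EstimationResult",
    "EstimationOptions",
    "kappa_cumulative",
    "indirect_slope",
    "estimate",
    "prepare_met",
]

MODEL_IDS = (
    "EB", "E0", "E0V", "E0G", "E0GV", "E1", "E1V", "E2", "E2V", "E3", "E3V",
    "E4", "E4V", "E5", "E5V", "E6", "E6V", "E7", "E7G", "E8", "E9",
    "E10", "E10G", "E11", "E12", "E13", "E14", "Pheno",
)

#: models fitted on breeder-trial (BT3) + regional data with pedigree
PEDIGREE_MODELS = ("E10", "E10G", "E11", "E12", "E13", "E14")


class CapabilityError(ValueError):
    """The dataset lacks a column/feature the requested model needs."""


@dataclass
class EstimationOptions:
    v_structure: str = "diagonal"      # "diagonal" or "fa1" for the V variants
    e9_reference: int | None = None    # default: first year (forward-only)
    maxiter: int = 150
    gtol: float = 3e-4
    tol: float = 1e-9                  # production likelihood tolerance
    start: np.ndarray | None = None    # warm start for the REML fit


@dataclass
class EstimationResult:
    model_id: str
    slope: float                       # bu/ac per year
    se: float
    kind: str                          # direct | indirect-regression | indirect-kappa
    ci95: tuple = (np.nan, np.nan)
    g_hat: pd.Series | None = None     # per-line predicted/estimated values
    r_i: pd.Series | None = None       # regressor years per line
    kappa: pd.Series | None = None     # cumulative-sum series by year
    yearly_series: pd.Series | None = None  # series used by the linearity test
    fit: FitResult | None = None

    @property
    def z_ratio(self) -> float:
        return self.slope / self.se if self.se > 0 else np.nan


# ---------------------------------------------------------------------------
# primitive estimators
# ---------------------------------------------------------------------------

def kappa_cumulative(g_hat, r) -> pd.Series:
    """Cumulative sum of yearly average predicted values by first-test year.

    ``kappa_n`` is the mean of ``g_hat`` over lines first tested in year n;
    the returned series is the running sum ordered by year.  Years must be
    contiguous: a represented year with no lines is an error.
    """
    g = pd.Series(np.asarray(g_hat, float))
    yrs = pd.Series(np.asarray(r)).astype(int)
    if len(g) != len(yrs):
        raise ValueError("g_hat and r must be paired")
    means = g.groupby(yrs.values).mean().sort_index()
    full = np.arange(means.index.min(), means.index.max() + 1)
    if len(means) != len(full):
        missing = sorted(set(full) - set(means.index))
        raise ValueError(f"no lines first tested in year(s) {missing}")
    return means.cumsum()


def indirect_slope(values, years, weights=None) -> tuple:
    """OLS slope and standard error of ``values`` on ``years``."""
    x = np.asarray(years, float)
    y = np.asarray(values, float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct years")
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - 2, 1)
    s2 = float(resid @ (w * resid)) / dof
    cov = s2 * np.linalg.inv(WX.T @ X)
    return float(beta[1]), float(np.sqrt(cov[1, 1]))


# ---------------------------------------------------------------------------
# dataset preparation
# ---------------------------------------------------------------------------

def prepare_met(met_means: pd.DataFrame, stages=("PYT", "URT"),
                year_range: tuple | None = None) -> pd.DataFrame:
    """Subset and annotate an entry-mean MET table for estimation.

    Adds string factor columns, the environment key, and centered covariates
    used by the direct models.  ``year_range`` is (first, last) inclusive.
    """
    df = met_means[met_means["stage"].isin(stages)].copy()
    if year_range is not None:
        df = df[(df["year"] >= year_range[0]) & (df["year"] <= year_range[1])]
    if df.empty:
        raise CapabilityError("no records in the requested stages/years")
    df["is_check"] = df["is_check"].astype(bool)
    df["loc_f"] = "L" + df["loc"].astype(str)
    df["year_f"] = "Y" + df["year"].astype(str)
    df["env"] = df["loc_f"] + ":" + df["year_f"]
    is_line = ~df["is_check"]
    r0 = df.loc[is_line, "r"].mean()
    df["r_line"] = np.where(is_line, df["r"] - r0, 0.0)
    df["t_line"] = np.where(is_line, df["year"] - df["year"].mean(), 0.0)
    df["pop"] = np.where(is_line, "line", "check")
    # location-usage covariate (delta*z term): number of earlier years the
    # location already appears in these records; absorbs the cumulative
    # non-genetic trend tied to continuously used locations
    usage = (df[["loc_f", "year"]].drop_duplicates()
             .sort_values(["loc_f", "year"]))
    usage["z_cov"] = usage.groupby("loc_f").cumcount().astype(float)
    df = df.merge(usage, on=["loc_f", "year"], how="left")
    is_line = ~df["is_check"]
    if "cross_year" in df.columns:
        cy = df["cross_year"].astype(float)
        # F1 crossing year covariate for the direct combining-ability models
        df["cy_line"] = np.where(is_line & cy.notna(), cy - np.nanmean(cy[is_line]), 0.0)
    # checks act as self-crosses so combining-ability terms stay defined
    for pcol in ("parent1", "parent2"):
        if pcol in df.columns:
            df[pcol] = df[pcol].where(is_line, df["line"]).fillna("unknown")
    if "parent1" in df.columns and "parent2" in df.columns:
        lo = np.minimum(df["parent1"].astype(str), df["parent2"].astype(str))
        hi = np.maximum(df["parent1"].astype(str), df["parent2"].astype(str))
        df["cross"] = lo + "x" + hi
    return df.reset_index(drop=True)


def _grm_for(df: pd.DataFrame, marker_ids, marker_dosages):
    if marker_ids is None or marker_dosages is None:
        raise CapabilityError("model requires marker genotypes (GRM)")
    ids = pd.Index([str(i) for i in marker_ids])
    need = pd.Index(sorted(df["line"].astype(str).unique()))
    missing = need.difference(ids)
    if len(missing):
        raise CapabilityError(f"no marker genotypes for {len(missing)} lines")
    sel = ids.get_indexer(need)
    K = genomic_relationship(marker_dosages[sel])
    # slight ridge keeps the marginal covariance invertible for clones
    K[np.diag_indices_from(K)] += 1e-4
    return K, list(need)


# ---------------------------------------------------------------------------
# model building blocks
# ---------------------------------------------------------------------------

#: domain-scale starting values for the optimizer (typical soybean MET
#: magnitudes, (bu/ac)^2); they affect the search path, not the optimum
_INIT_VAR = {"G": 6.0, "GL": 5.0, "GY": 3.0, "LY": 80.0, "Y": 15.0,
             "E": 100.0, "P": 3.0, "F": 3.0, "COH": 1.0}
_RESID_INIT = 18.0


def _fit(spec: ModelSpec, df: pd.DataFrame, opts: EstimationOptions,
         start=None) -> FitResult:
    for e in spec.random:
        if e.init is None:
            e.init = _INIT_VAR.get(e.name)
    if spec.residual_init is None and spec.weights is not None:
        spec.residual_init = _RESID_INIT
    return fit_reml(spec, df, maxiter=opts.maxiter, tol=opts.tol,
                    gtol=opts.gtol,
                    start=start if start is not None else opts.start)


def _gl_gy_terms(opts: EstimationOptions, heterogeneous: bool) -> list:
    if not heterogeneous:
        return [RandomEffect("GL", ("line", "loc_f")),
                RandomEffect("GY", ("line", "year_f"))]
    if opts.v_structure == "fa1":
        return [RandomEffect("GL", ("line", "loc_f"), cov="fa1",
                             inner="loc_f", block="line"),
                RandomEffect("GY", ("line", "year_f"), cov="fa1",
                             inner="year_f", block="line")]
    return [RandomEffect("GL", ("line", "loc_f"), cov="diagonal",
                         group_by="loc_f"),
            RandomEffect("GY", ("line", "year_f"), cov="diagonal",
                         group_by="year_f")]


def _g_term(df, grm, marker_ids, marker_dosages) -> RandomEffect:
    if not grm:
        return RandomEffect("G", "line")
    K, ids = _grm_for(df, marker_ids, marker_dosages)
    return RandomEffect("G", "line", cov="grm", K=K, K_ids=ids)


def _full_model_fit(df, opts, heterogeneous=False, grm=False,
                    marker_ids=None, marker_dosages=None,
                    extra_fixed_cov=(), genotype_fixed=False) -> FitResult:
    random = [RandomEffect("Y", "year_f"), RandomEffect("LY", "env")]
    random += _gl_gy_terms(opts, heterogeneous)
    fixed_factors = ["loc_f"]
    if genotype_fixed:
        fixed_factors = ["line", "loc_f"]
    else:
        random.insert(0, _g_term(df, grm, marker_ids, marker_dosages))
    spec = ModelSpec(response="value", fixed_factors=fixed_factors,
                     fixed_covariates=["z_cov", *extra_fixed_cov],
                     random=random, weights="se2")
    return _fit(spec, df, opts)


def _line_table(df: pd.DataFrame) -> pd.DataFrame:
    cols = ["r"] + (["w"] if "w" in df.columns else [])
    return (df[~df["is_check"]].groupby("line")[cols].first())


def _eblue_series(fit: FitResult, lines) -> pd.Series:
    """Fixed-effect estimates for every line (reference level at zero)."""
    vals = {}
    for line in lines:
        key = f"line[{line}]"
        vals[line] = fit.fixed_effects.get(key, 0.0)
    return pd.Series(vals)


def _indirect_from_values(model_id, g, r, kind, fit=None) -> EstimationResult:
    slope, se = indirect_slope(g.to_numpy(), r.to_numpy())
    yearly = g.groupby(r.astype(int).values).mean().sort_index()
    return EstimationResult(model_id, slope, se, kind,
                            ci95=(slope - 1.96 * se, slope + 1.96 * se),
                            g_hat=g, r_i=r, yearly_series=yearly, fit=fit)


def _kappa_result(model_id, g, r, fit=None, scale=1.0) -> EstimationResult:
    kap = kappa_cumulative(scale * g.to_numpy(), r.to_numpy())
    slope, se = indirect_slope(kap.to_numpy(), kap.index.to_numpy())
    return EstimationResult(model_id, slope, se, "indirect-kappa",
                            ci95=(slope - 1.96 * se, slope + 1.96 * se),
                            g_hat=scale * g, r_i=r, kappa=kap,
                            yearly_series=kap, fit=fit)


def _direct_result(model_id, fit, coef_name) -> EstimationResult:
    slope = float(fit.fixed_effects[coef_name])
    se = float(fit.fixed_se[coef_name])
    return EstimationResult(model_id, slope, se, "direct",
                            ci95=(slope - 1.96 * se, slope + 1.96 * se),
                            fit=fit)


# ---------------------------------------------------------------------------
# model dispatch
# ---------------------------------------------------------------------------

def estimate(model_id: str, met_means: pd.DataFrame,
             options: EstimationOptions | None = None,
             year_range: tuple | None = None,
             marker_ids=None, marker_dosages=None) -> EstimationResult:
    """Estimate RGG with one registry model on an entry-mean MET table.

    ``met_means`` must carry the schema emitted by the breeding-program
    simulator (line, loc, year, stage, value, se2, is_check, r, w, parents).
    """
    opts = options or EstimationOptions()
    if model_id not in MODEL_IDS:
        raise CapabilityError(f"unknown model {model_id!r}")
    stages = ("BT3", "PYT", "URT") if model_id in PEDIGREE_MODELS else ("PYT", "URT")
    df = prepare_met(met_means, stages=stages, year_range=year_range)
    if model_id in PEDIGREE_MODELS:
        return _estimate_pedigree(model_id, df, opts, marker_ids, marker_dosages)
    if model_id == "Pheno":
        sub = df[~df["is_check"]]
        g = sub["value"].astype(float)
        g.index = sub["line"].to_numpy()
        return _indirect_from_values("Pheno", g, sub["r"].set_axis(g.index),
                                     "indirect-regression")
    if model_id.startswith(("E4", "E5")):
        df = df[df["stage"] == "URT"].reset_index(drop=True)
        if df.empty:
            raise CapabilityError(f"model {model_id} needs URT records")
    if model_id in ("E6", "E6V", "E7", "E7G", "E8") and not df["is_check"].any():
        raise CapabilityError(f"model {model_id} requires check cultivars")

    het = model_id.endswith("V")
    grm = "G" in model_id[2:] if model_id.startswith("E0") else model_id == "E7G"
    lines = _line_table(df)

    if model_id in ("EB",) or model_id.startswith("E0") or model_id in ("E4", "E4V"):
        fit = _full_model_fit(df, opts, heterogeneous=het, grm=grm,
                              marker_ids=marker_ids, marker_dosages=marker_dosages)
        g = fit.blup("G").reindex(lines.index)
        base = model_id if model_id != "EB" else "EB"
        if model_id == "EB":
            return _indirect_from_values("EB", g, lines["r"],
                                         "indirect-regression", fit)
        return _kappa_result(base, g, lines["r"], fit)

    if model_id in ("E1", "E1V", "E5", "E5V"):
        fit = _full_model_fit(df, opts, heterogeneous=het, genotype_fixed=True)
        g = _eblue_series(fit, lines.index)
        return _indirect_from_values(model_id, g, lines["r"],
                                     "indirect-regression", fit)

    if model_id in ("E2", "E2V", "E3", "E3V"):
        random = [RandomEffect("Y", "year_f"), RandomEffect("LY", "env"),
                  RandomEffect("G", "line")]
        random += _gl_gy_terms(opts, het)
        if model_id.startswith("E3"):
            df["cohort"] = np.where(df["is_check"], "chk",
                                    "R" + df["r"].fillna(0).astype(int).astype(str))
            random.append(RandomEffect("COH", "cohort"))
        spec = ModelSpec(response="value", fixed_factors=["loc_f", "pop"],
                         fixed_covariates=["z_cov", "r_line"], random=random,
                         weights="se2")
        fit = _fit(spec, df, opts)
        return _direct_result(model_id, fit, "r_line")

    if model_id in ("E6", "E6V"):
        random = [RandomEffect("G", "line"), RandomEffect("LY", "env"),
                  RandomEffect("Y", "year_f")]
        random += _gl_gy_terms(opts, het)
        spec = ModelSpec(response="value", fixed_factors=["loc_f", "pop"],
                         fixed_covariates=["z_cov", "t_line"], random=random,
                         weights="se2")
        fit = _fit(spec, df, opts)
        return _direct_result(model_id, fit, "t_line")

    if model_id in ("E7", "E7G", "E8"):
        e_hat = predict_environment_effects(df)
        sub = df[~df["is_check"]].copy()
        sub["E_hat"] = sub["env"].map(e_hat)
        sub = sub[sub["E_hat"].notna()].reset_index(drop=True)
        g_term = _g_term(sub, grm, marker_ids, marker_dosages)
        if model_id == "E8":
            spec = ModelSpec(response="value", fixed_covariates=["E_hat", "r_line"],
                             random=[g_term], weights="se2")
            fit = _fit(spec, sub, opts)
            return _direct_result("E8", fit, "r_line")
        spec = ModelSpec(response="value", fixed_covariates=["E_hat"],
                         random=[g_term], weights="se2")
        fit = _fit(spec, sub, opts)
        lines2 = _line_table(sub)
        g = fit.blup("G").reindex(lines2.index)
        return _indirect_from_values(model_id, g, lines2["r"],
                                     "indirect-regression", fit)

    if model_id == "E9":
        return _estimate_e9(df, opts)

    raise CapabilityError(f"model {model_id!r} not implemented")  # pragma: no cover


def predict_environment_effects(df: pd.DataFrame) -> pd.Series:
    """eBLUP of environment (location-year) effects from checks only.

    Environments without a check observation are excluded (and absent from
    the returned series).
    """
    checks = df[df["is_check"]].reset_index(drop=True)
    if checks.empty:
        raise CapabilityError("no check observations for environment prediction")
    spec = ModelSpec(response="value",
                     random=[RandomEffect("E", "env"),
                             RandomEffect("G", "line")],
                     weights="se2")
    fit = fit_reml(spec, checks)
    return fit.blup("E")


def _estimate_e9(df: pd.DataFrame, opts: EstimationOptions) -> EstimationResult:
    """Within-year fits chained through a reference year.

    Year-to-year corrections come from the mean difference of predicted
    values of genotypes (checks and carry-over lines) shared by consecutive
    years; values are then expressed relative to the reference year and the
    gain is the regression of per-line corrected values on r_i.
    """
    years = sorted(df["year"].unique())
    if len(years) < 2:
        raise CapabilityError("E9 needs at least two years")
    ref = opts.e9_reference if opts.e9_reference is not None else years[0]
    per_year = {}
    for yr in years:
        sub = df[df["year"] == yr].reset_index(drop=True)
        spec = ModelSpec(response="value", fixed_factors=["loc_f"],
                         random=[RandomEffect("G", "line")], weights="se2")
        fit = fit_reml(spec, sub)
        mu = float(fit.fixed_effects["(Intercept)"])
        per_year[yr] = fit.blup("G") + mu
    # corrections between consecutive years from shared genotypes
    offset = {years[0]: 0.0}
    for a, b in zip(years[:-1], years[1:]):
        shared = per_year[a].index.intersection(per_year[b].index)
        if len(shared) == 0:
            raise CapabilityError(f"no shared genotypes between years {a} and {b}")
        d = float((per_year[b][shared] - per_year[a][shared]).mean())
        offset[b] = offset[a] + d
    ref_off = offset[ref]
    corrected = {}
    for yr in years:
        corrected[yr] = per_year[yr] - (offset[yr] - ref_off)
    lines = _line_table(df)
    vals = {}
    for lid in lines.index:
        xs = [corrected[yr][lid] for yr in years if lid in corrected[yr].index]
        vals[lid] = float(np.mean(xs))
    g = pd.Series(vals)
    return _indirect_from_values("E9", g, lines["r"], "indirect-regression")


def _estimate_pedigree(model_id, df, opts, marker_ids, marker_dosages):
    """Combining-ability models on BT3 + PYT + URT with parent terms."""
    if "parent1" not in df.columns or "cross" not in df.columns:
        raise CapabilityError(f"model {model_id} requires parent columns")
    lines = df[~df["is_check"]]
    parents = sorted(set(lines["parent1"]).union(lines["parent2"]))
    # crossing year of each parent (w recorded on its own line record)
    w_map = (df.groupby("line")["w"].first().dropna())

    if model_id in ("E10", "E10G", "E11", "E13"):
        grm = model_id == "E10G"
        if model_id in ("E10", "E10G", "E13"):
            if grm:
                K, ids = _grm_for(
                    pd.DataFrame({"line": parents + list(df.loc[df["is_check"], "line"].unique())}),
                    marker_ids, marker_dosages)
                p_term = RandomEffect("P", "parent1", extra_factors="parent2",
                                      cov="grm", K=K, K_ids=ids)
            else:
                p_term = RandomEffect("P", "parent1", extra_factors="parent2")
            random = [RandomEffect("Y", "year_f"), RandomEffect("LY", "env"),
                      p_term, RandomEffect("F", "cross")]
            if model_id == "E13":
                e_hat = predict_environment_effects(df)
                sub = df[~df["is_check"]].copy()
                sub["E_hat"] = sub["env"].map(e_hat)
                sub = sub[sub["E_hat"].notna()].reset_index(drop=True)
                spec = ModelSpec(response="value", fixed_covariates=["E_hat"],
                                 random=[p_term, RandomEffect("F", "cross")],
                                 weights="se2")
                fit = _fit(spec, sub, opts)
            else:
                spec = ModelSpec(response="value", fixed_factors=["loc_f"],
                                 random=random, weights="se2")
                fit = _fit(spec, df, opts)
            p_hat = fit.blup("P")
        else:  # E11: fixed general combining ability
            spec = ModelSpec(
                response="value",
                fixed_factors=["loc_f", ("+", "parent1", "parent2")],
                random=[RandomEffect("Y", "year_f"), RandomEffect("LY", "env"),
                        RandomEffect("F", "cross")],
                weights="se2")
            fit = _fit(spec, df, opts)
            name = "parent1+parent2"
            p_hat = pd.Series(
                {p: fit.fixed_effects.get(f"{name}[{p}]", 0.0) for p in parents})
        keep = [p for p in p_hat.index if p in w_map.index]
        if len(keep) < 2:
            raise CapabilityError(f"model {model_id}: too few breeding lines with crossing years")
        g = 2.0 * p_hat[keep]
        w = w_map[keep].astype(float)
        if model_id in ("E10", "E10G"):
            return _kappa_result(model_id, g / 2.0, w, fit, scale=2.0)
        return _indirect_from_values(model_id, g, w, "indirect-regression", fit)

    # E12 / E14: direct regression on the crossing year
    e14 = model_id == "E14"
    sub = df.copy()
    if e14:
        e_hat = predict_environment_effects(df)
        sub = sub[~sub["is_check"]].copy()
        sub["E_hat"] = sub["env"].map(e_hat)
        sub = sub[sub["E_hat"].notna()].reset_index(drop=True)
    if "cy_line" not in sub.columns or not (sub["cy_line"] != 0).any():
        raise CapabilityError(f"model {model_id} requires crossing-year data")
    random = [RandomEffect("F", "cross"), RandomEffect("LY", "env")]
    if not e14:
        random.insert(0, RandomEffect("Y", "year_f"))
    fixed_factors = [] if e14 else ["loc_f", "pop"]
    fixed_cov = (["E_hat", "cy_line"] if e14 else ["cy_line"])
    spec = ModelSpec(response="value", fixed_factors=fixed_factors,
                     fixed_covariates=fixed_cov, random=random, weights="se2")
    fit = _fit(spec, sub, opts)
    return _direct_result(model_id, fit, "cy_line")
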