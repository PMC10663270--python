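"""Truth-based evaluation of RGG estimators: bias, linearity, contrasts.

The simulated truth is the slope ``beta_T`` of parents' true breeding values
on their crossing years; the expected MET trend ``beta_R_true`` replaces
predicted genotype values with true ones for the lines actually present in
the regional trials, so ``beta_R_true - beta_T`` is the expected bias of
estimating gain from advanced trials without pedigree information.
Estimator bias is summarized by mean error, mean relative error (percent)
and RMSE across simulation runs; linearity is tested with an AR-sieve
bootstrap of the trend t-statistic for indirect estimators and a normal
z-ratio for direct ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KG_HA_PER_BU_AC",
    "BiasSummary",
    "true_rgg",
    "expected_rgg",
    "bias_metrics",
    "sieve_bootstrap_trend_test",
    "linearity_indirect",
    "linearity_direct",
    "model_contrasts",
    "containment_fraction",
    "convert_units",
]

#: soybean yield conversion: 1 bu/ac = 67.25 kg/ha (implied by 0.59 <-> 39.68)
KG_HA_PER_BU_AC = 67.25

#: relative bias is undefined near a zero truth; runs below this |beta_T|
#: are excluded from relative summaries (the no-selection scenario behaves
#: this way by design)
REL_BIAS_TRUTH_FLOOR = 1e-3


def convert_units(value_bu_ac):
    """bu/ac (per year) to kg/ha (per year)."""
    return np.asarray(value_bu_ac, float) * KG_HA_PER_BU_AC if np.ndim(value_bu_ac) else float(value_bu_ac) * KG_HA_PER_BU_AC


def _ols_slope(y, x):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    den = float(xc @ xc)
    if den == 0:
        raise ValueError("regressor has no variation")
    return float(xc @ (y - y.mean()) / den)


def true_rgg(truth: pd.DataFrame) -> float:
    """Slope of parents' true breeding values on crossing year (bu/ac/yr)."""
    par = truth[truth["w"].notna()]
    if par.empty:
        raise ValueError("truth log contains no parents")
    if par["w"].nunique() < 2:
        raise ValueError("need parents from at least two crossing years")
    return _ols_slope(par["bv"], par["w"])


def expected_rgg(truth: pd.DataFrame, met_lines=None,
                 year_range: tuple | None = None) -> float:
    """MET trend slope with predicted values replaced by true breeding values.

    ``met_lines`` optionally restricts to the line ids present in the MET
    records; otherwise every line with a first PYT year is used.
    """
    df = truth[truth["r"].notna()]
    if met_lines is not None:
        df = df[df["line"].isin(set(met_lines))]
    if year_range is not None:
        df = df[(df["r"] >= year_range[0]) & (df["r"] <= year_range[1])]
    if df["r"].nunique() < 2:
        raise ValueError("need MET lines across at least two first-test years")
    return _ols_slope(df["bv"], df["r"])


@dataclass
class BiasSummary:
    mean_bias: float            # Eq-style average error, bu/ac/yr
    rel_bias_pct: float         # mean of per-run error/truth, percent
    rmse: float
    n_runs: int
    n_excluded_rel: int         # runs excluded from the relative summary

    @property
    def mean_bias_kg_ha(self) -> float:
        return self.mean_bias * KG_HA_PER_BU_AC


def bias_metrics(estimates, truths) -> BiasSummary:
    """Average bias, relative bias (percent) and RMSE over paired runs."""
    est = np.asarray(estimates, float)
    tru = np.asarray(truths, float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must be paired")
    xi = est - tru
    ok = np.abs(tru) >= REL_BIAS_TRUTH_FLOOR
    rel = float(np.mean(xi[ok] / tru[ok]) * 100.0) if ok.any() else np.nan
    return BiasSummary(
        mean_bias=float(xi.mean()),
        rel_bias_pct=rel,
        rmse=float(np.sqrt(np.mean(xi ** 2))),
        n_runs=len(xi),
        n_excluded_rel=int((~ok).sum()),
    )


def containment_fraction(estimates_by_model: pd.DataFrame, truths,
                         drop_negative: bool = True) -> float:
    """Fraction of runs whose truth lies inside the models' min-max range.

    ``estimates_by_model``: rows = runs, columns = models.  Negative
    estimates are dropped before taking the range when ``drop_negative``
    (mirroring how a practitioner would discard implausible negative gain
    estimates); a run with no remaining estimate does not contain the truth.
    """
    tru = np.asarray(truths, float)
    hits = 0
    for i, (_, row) in enumerate(estimates_by_model.iterrows()):
        vals = row.to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if drop_negative:
            vals = vals[vals >= 0]
        if vals.size and vals.min() <= tru[i] <= vals.max():
            hits += 1
    return hits / len(estimates_by_model)


# ---------------------------------------------------------------------------
# linearity
# ---------------------------------------------------------------------------

def _trend_tstat(series: np.ndarray) -> float:
    n = len(series)
    t_idx = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t_idx])
    beta, res, *_ = np.linalg.lstsq(X, series, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((series - fitted) ** 2))
    dof = n - 2
    if dof <= 0 or rss <= 0:
        return np.inf if beta[1] != 0 else 0.0
    s2 = rss / dof
    sxx = float(np.sum((t_idx - t_idx.mean()) ** 2))
    return float(beta[1] / np.sqrt(s2 / sxx))


def _fit_ar(resid: np.ndarray, p_max: int = 4):
    """AR(p) by conditional least squares, order chosen by AIC."""
    n = len(resid)
    p_max = min(p_max, max(n // 4, 0))
    best = (0, np.array([]), resid - resid.mean())
    best_aic = np.inf
    for p in range(0, p_max + 1):
        if p == 0:
            e = resid - resid.mean()
            rss = float(e @ e)
            k = 1
            eps = e
            coef = np.array([])
        else:
            Y = resid[p:]
            X = np.column_stack([resid[p - j - 1:n - j - 1] for j in range(p)])
            X = np.column_stack([np.ones(len(Y)), X])
            beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
            eps = Y - X @ beta
            rss = float(eps @ eps)
            k = p + 1
            coef = beta[1:]
        n_eff = len(eps)
        if n_eff <= k or rss <= 0:
            continue
        aic = n_eff * np.log(rss / n_eff) + 2 * k
        if aic < best_aic:
            best_aic = aic
            best = (p, coef, eps - eps.mean())
    return best


def sieve_bootstrap_trend_test(series, n_boot: int = 1000,
                               rng: np.random.Generator | None = None,
                               p_max: int = 4) -> float:
    """P-value of the no-trend null for a short time series.

    The observed trend t-statistic is compared with its distribution under
    an AR(p) sieve: the series is detrended, an autoregression (order by
    AIC, p <= 4) is fitted to the residuals, and bootstrap series are
    rebuilt from resampled centered innovations.
    """
    x = np.asarray(series, float)
    n = len(x)
    if n < 3 or np.allclose(x, x[0]):
        return 1.0
    rng = np.random.default_rng(rng)
    t_obs = _trend_tstat(x)
    t_idx = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t_idx])
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    resid = x - X @ beta
    p, coef, eps = _fit_ar(resid, p_max)
    if eps.size < 2:
        return 1.0
    burn = 20 + p
    draws = rng.choice(eps, size=(n_boot, n + burn), replace=True)
    if p == 0:
        sims = draws[:, burn:]
    else:
        sims = np.zeros((n_boot, n + burn))
        for t in range(n + burn):
            acc = draws[:, t].copy()
            for j in range(1, min(p, t) + 1):
                acc += coef[j - 1] * sims[:, t - j]
            sims[:, t] = acc
        sims = sims[:, burn:]
    # vectorized trend t-stats under the null
    tc = t_idx - t_idx.mean()
    sxx = float(tc @ tc)
    slopes = sims @ tc / sxx
    fitted = (sims.mean(axis=1, keepdims=True)
              + slopes[:, None] * tc[None, :])
    rss = np.sum((sims - fitted) ** 2, axis=1)
    s2 = rss / max(n - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = slopes / np.sqrt(s2 / sxx)
    t_null = t_null[np.isfinite(t_null)]
    return float((1 + np.sum(np.abs(t_null) >= abs(t_obs))) / (len(t_null) + 1))


def linearity_indirect(g_hat, r, alpha: float = 0.05,
                       n_comparisons: int = 1, n_boot: int = 1000,
                       rng: np.random.Generator | None = None) -> tuple:
    """Sieve-bootstrap linearity decision for an indirect estimator.

    Aggregates per-line values to yearly means by first-test year and tests
    the trend; the significance level is Bonferroni-adjusted by
    ``n_comparisons``.  Returns (significant, p_value).
    """
    g = pd.Series(np.asarray(g_hat, float))
    yrs = pd.Series(np.asarray(r)).astype(int)
    series = g.groupby(yrs.values).mean().sort_index().to_numpy()
    p = sieve_bootstrap_trend_test(series, n_boot=n_boot, rng=rng)
    return bool(p < alpha / max(n_comparisons, 1)), p


def linearity_direct(slope: float, se: float) -> float:
    """Two-tailed p-value from the z-ratio of a direct estimate."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = slope / se
    return float(2.0 * (1.0 - stats.norm.cdf(abs(z))))


# ---------------------------------------------------------------------------
# model contrasts
# ---------------------------------------------------------------------------

def model_contrasts(estimates: pd.DataFrame, pairs=None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-adjusted pairwise model contrasts of estimated RGG values.

    ``estimates``: long table with columns run, model, estimate.  A two-way
    fixed-effects ANOVA (run + model) supplies the error variance; pairwise
    differences of model means use the studentized-range distribution.
    Models missing some runs are compared on the paired subset.
    """
    df = estimates.dropna(subset=["estimate"]).copy()
    wide = df.pivot_table(index="run", columns="model", values="estimate")
    wide = wide.dropna(axis=0)
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValueError("need >= 2 runs and >= 2 models in common")
    runs, k = wide.shape
    y = wide.to_numpy()
    grand = y.mean()
    run_means = y.mean(axis=1, keepdims=True)
    mod_means = y.mean(axis=0, keepdims=True)
    resid = y - run_means - mod_means + grand
    dfe = (runs - 1) * (k - 1)
    mse = float((resid ** 2).sum() / dfe)
    se_diff = np.sqrt(2.0 * mse / runs)
    models = list(wide.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(models) for b in models[i + 1:]]
    rows = []
    for a, b in pairs:
        diff = float(wide[a].mean() - wide[b].mean())
        q = abs(diff) / (se_diff / np.sqrt(2.0))
        pval = float(stats.studentized_range.sf(q, k, dfe))
        rows.append({"model_a": a, "model_b": b, "difference": diff,
                     "p_value": min(pval, 1.0),
                     "significant": pval < alpha})
    return pd.DataFrame(rows)
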