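"""Phenotype generation for simulated multi-environment trials (MET).

Plot-level yield phenotypes follow an additive decomposition

    Y_ijkl = mu + G_i + L_j + Y_k + GL_ij + GY_ik + LY_jk + GLY_ijk + eps_ijkl

with all genotype-related terms built from additive QTL effects (the dosage
matrix Theta times per-term effect vectors), locations fixed, years random,
and heterogeneous per-trial residual variances.  Six scenario variants are
supported:

* A1 / A2  -- independent GEI effects with fixed variance components
  (G 6.3, GL 4.8, GY 3.2, GLY 10.1, Y 15.3, LY 81.4 (bu/ac)^2);
  A2 adds the cumulative non-genetic location-year trend.
* B1 / B2  -- per-run variance draws from heavy-tailed distributions
  (log-logistic / gamma, medians at the fixed values above) and QTL-level
  GL/GY effects correlated across locations / years; B2 adds the trend.
* B2-M     -- B2 with the GL, GY, GLY draws divided by 10.
* B2-R     -- B2 with every selection step replaced by random sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import ConfigurationError, FounderPopulation, GeneticMap, QTLEffectSet

__all__ = [
    "TRAIT_MEAN",
    "VARIANCE_POINT_ESTIMATES",
    "ScenarioConfig",
    "VarianceDraws",
    "TrendState",
    "sample_run_variances",
    "build_interaction_effects",
    "ly_effect",
    "simulate_trial",
    "advance_locations",
]

TRAIT_MEAN = 46.0  # bu/ac

#: point estimates of the simulation variance components, (bu/ac)^2
VARIANCE_POINT_ESTIMATES = {
    "G": 6.3,
    "GL": 4.8,
    "GY": 3.2,
    "GLY": 10.1,
    "Y": 15.3,
    "LY": 81.4,
}

#: median plot-to-plot residual variance, (bu/ac)^2.  Not printed with the
#: other components; set from a typical ~10% trial CV at the 46 bu/ac trait
#: mean.  Per-trial draws are log-logistic around this median.
RESIDUAL_MEDIAN = 23.0

SCENARIOS = ("A1", "A2", "B1", "B2", "B2-M", "B2-R")


@dataclass
class ScenarioConfig:
    """One of the six MET simulation scenarios."""

    scenario_id: str
    mu: float = TRAIT_MEAN
    trend_enabled: bool = False
    per_run_variances: bool = False      # "B" family: unique draws per run
    correlated_gei: bool = False         # "B" family: Sigma_J / Sigma_K rows
    gei_shrink_factor: float = 1.0       # 10 for B2-M
    random_selection: bool = False       # B2-R
    loglogistic_shape: float = 5.0
    gamma_shape: float = 5.0
    residual_shape: float = 5.0
    residual_median: float = RESIDUAL_MEDIAN

    @classmethod
    def preset(cls, scenario_id: str) -> "ScenarioConfig":
        sid = scenario_id.upper()
        if sid not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {scenario_id!r}")
        b = sid.startswith("B")
        return cls(
            scenario_id=sid,
            trend_enabled=sid in ("A2", "B2", "B2-M", "B2-R"),
            per_run_variances=b,
            correlated_gei=b,
            gei_shrink_factor=10.0 if sid == "B2-M" else 1.0,
            random_selection=sid == "B2-R",
        )


@dataclass
class VarianceDraws:
    """Per-run variance components (bu/ac)^2 plus GEI correlation draws."""

    sigma2_G: float
    sigma2_GL: float
    sigma2_GY: float
    sigma2_GLY: float
    sigma2_Y: float
    sigma2_LY: float
    rho_J: float = 0.0
    rho_K: float = 0.0

    def __post_init__(self):
        for name in ("sigma2_G", "sigma2_GL", "sigma2_GY", "sigma2_GLY",
                     "sigma2_Y", "sigma2_LY"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def _loglogistic(median: float, shape: float, rng: np.random.Generator) -> float:
    """Fisk (log-logistic) draw with the given median (= scale)."""
    u = rng.random()
    return float(stats.fisk.ppf(u, c=shape, scale=median))


def _gamma_median(median: float, shape: float, rng: np.random.Generator) -> float:
    scale = median / stats.gamma.ppf(0.5, shape)
    return float(rng.gamma(shape, scale))


def sample_run_variances(scenario: ScenarioConfig,
                         rng: np.random.Generator) -> VarianceDraws:
    """Draw the run-level variance components for a scenario.

    A scenarios return the fixed point estimates; B scenarios draw G, GL, GY
    from log-logistic and GLY from gamma distributions whose medians equal
    the point estimates, plus compound-symmetry correlations for the
    across-location / across-year structure.  B2-M divides the GL/GY/GLY
    draws by its shrink factor.
    """
    v = VARIANCE_POINT_ESTIMATES
    if not scenario.per_run_variances:
        return VarianceDraws(v["G"], v["GL"], v["GY"], v["GLY"], v["Y"], v["LY"])
    c = scenario.loglogistic_shape
    g = _loglogistic(v["G"], c, rng)
    gl = _loglogistic(v["GL"], c, rng)
    gy = _loglogistic(v["GY"], c, rng)
    gly = _gamma_median(v["GLY"], scenario.gamma_shape, rng)
    rho_j = float(rng.uniform(0.2, 0.8))
    rho_k = float(rng.uniform(0.2, 0.8))
    f = scenario.gei_shrink_factor
    return VarianceDraws(g, gl / f, gy / f, gly / f, v["Y"], v["LY"],
                         rho_J=rho_j, rho_K=rho_k)


def draw_trial_residual_variance(scenario: ScenarioConfig,
                                 rng: np.random.Generator) -> float:
    """Heterogeneous per-trial plot error variance (log-logistic)."""
    return _loglogistic(scenario.residual_median, scenario.residual_shape, rng)


# ---------------------------------------------------------------------------
# QTL-level interaction effects
# ---------------------------------------------------------------------------

def _compound_symmetry(m: int, rho: float) -> np.ndarray:
    R = np.full((m, m), rho)
    np.fill_diagonal(R, 1.0)
    return R


def _rescale_columns(phi: np.ndarray, theta: np.ndarray,
                     target_var: np.ndarray) -> np.ndarray:
    """Scale each effect column so var(theta @ phi[:, j]) hits its target."""
    vals = theta @ phi
    v = vals.var(axis=0, ddof=0)
    scale = np.zeros_like(v)
    nz = v > 0
    scale[nz] = np.sqrt(np.asarray(target_var, float)[nz] / v[nz])
    return phi * scale


def build_interaction_effects(gmap: GeneticMap, founders: FounderPopulation,
                              draws: VarianceDraws, J: int, K: int,
                              rng: np.random.Generator,
                              correlated: bool = False,
                              phi_G: np.ndarray | None = None) -> QTLEffectSet:
    """Sample GL / GY / GLY QTL effect matrices for ``J`` locations and
    ``K`` years.

    Independent mode draws each column i.i.d.; correlated mode draws the
    per-QTL rows from compound-symmetry covariances ``Sigma_J`` / ``Sigma_K``
    so line-level GL (GY) effects are correlated across locations (years).
    Columns are rescaled so the realized variance of ``Theta @ phi`` among
    founders equals the drawn per-column target.
    """
    if J < 1 or K < 1:
        raise ConfigurationError("J and K must be >= 1")
    q = gmap.n_qtl
    theta = founders.qtl_dosages().astype(float)
    Sigma_J = Sigma_K = None

    def draw(m: int, var: float, rho: float) -> np.ndarray:
        if var == 0:
            return np.zeros((q, m))
        if correlated and m > 1:
            R = _compound_symmetry(m, rho)
            L = np.linalg.cholesky(R)
            raw = rng.standard_normal((q, m)) @ L.T
        else:
            raw = rng.standard_normal((q, m))
        return _rescale_columns(raw, theta, np.full(m, var))

    phi_GL = draw(J, draws.sigma2_GL, draws.rho_J)
    phi_GY = draw(K, draws.sigma2_GY, draws.rho_K)
    # three-way interactions are always independent across environments
    if draws.sigma2_GLY == 0:
        phi_GLY = np.zeros((q, J * K))
    else:
        phi_GLY = _rescale_columns(rng.standard_normal((q, J * K)), theta,
                                   np.full(J * K, draws.sigma2_GLY))
    if correlated:
        Sigma_J = draws.sigma2_GL * _compound_symmetry(J, draws.rho_J)
        Sigma_K = draws.sigma2_GY * _compound_symmetry(K, draws.rho_K)
        for S in (Sigma_J, Sigma_K):
            if np.linalg.eigvalsh(S)[0] <= 0 and S.shape[0] > 1 and S[0, 0] > 0:
                raise ConfigurationError("interaction covariance not positive-definite")
    return QTLEffectSet(phi_G if phi_G is not None else np.zeros(q),
                        phi_GL, phi_GY, phi_GLY, Sigma_J, Sigma_K)


# ---------------------------------------------------------------------------
# non-genetic location-year trend
# ---------------------------------------------------------------------------

ETA_CHOICES = (1 / 2, 1 / 3, 1 / 4, 1 / 5, 1 / 6)


@dataclass
class TrendState:
    """Cumulative non-genetic gain bookkeeping per location.

    Each location carries a constant eta (drawn once, uniform over
    {1/2, 1/3, 1/4, 1/5, 1/6}) and a usage counter; the covariate z_jk is
    the number of prior years the location was used (so the first use has
    z = 0 and every further use increments z by one).
    """

    eta: dict = field(default_factory=dict)
    used_years: dict = field(default_factory=dict)

    def ensure_eta(self, loc, rng: np.random.Generator) -> float:
        if loc not in self.eta:
            self.eta[loc] = float(rng.choice(ETA_CHOICES))
        return self.eta[loc]

    def record_usage(self, loc, year: int) -> None:
        ys = self.used_years.setdefault(loc, set())
        ys.add(year)

    def z(self, loc, year: int) -> int:
        """Usage covariate at ``year`` (counting usages up to and including it)."""
        ys = self.used_years.get(loc, set())
        n = sum(1 for y in ys if y <= year)
        return max(n - 1, 0)

    def trend_term(self, loc, year: int) -> float:
        return self.z(loc, year) * self.eta.get(loc, 0.0)


def ly_effect(loc, year: int, trend_state: TrendState, sigma2_LY: float,
              trend_enabled: bool, rng: np.random.Generator) -> float:
    """Location-year effect: u_jk ~ N(0, sigma2_LY), plus z_jk * eta_j when the
    cumulative non-genetic trend is simulated."""
    u = float(rng.normal(0.0, np.sqrt(sigma2_LY)))
    if trend_enabled:
        return u + trend_state.trend_term(loc, year)
    return u


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def simulate_trial(theta: np.ndarray, effects: QTLEffectSet, mu: float,
                   L_j: float, Y_k: float, LY_jk: float, j: int, k: int,
                   n_reps: int, sigma2_eps: float, rng: np.random.Generator,
                   max_missing: float = 0.12) -> dict:
    """Simulate one trial (one location-year, ``n_reps`` plots per line).

    ``theta`` is the (n_lines, q) QTL dosage matrix of the entries.  Returns
    plot values (n_lines, n_reps) with NaN for missing plots, plus the
    genetic components used (for truth logging).
    """
    n = theta.shape[0]
    J = effects.phi_GL.shape[1]
    g = theta @ effects.phi_G
    gl = theta @ effects.phi_GL[:, j]
    gy = theta @ effects.phi_GY[:, k]
    gly = theta @ effects.phi_GLY[:, k * J + j]
    mean = mu + g + L_j + Y_k + gl + gy + LY_jk + gly
    eps = rng.normal(0.0, np.sqrt(sigma2_eps), size=(n, n_reps))
    y = mean[:, None] + eps
    miss_frac = rng.uniform(0.0, max_missing)
    mask = rng.random((n, n_reps)) < miss_frac
    # never lose a line entirely from the trial
    all_gone = mask.all(axis=1)
    mask[all_gone, 0] = False
    y[mask] = np.nan
    return {"plots": y, "g": g, "gl": gl, "gy": gy, "gly": gly,
            "missing_fraction": float(miss_frac)}


def advance_locations(pool: list, current: list, n_active: int,
                      replacement_rate: float, rng: np.random.Generator) -> list:
    """Advance the active location set to the next year.

    A binomial number of active locations (rate ``replacement_rate``) is
    swapped for locations outside the current set, holding the count at
    ``n_active``; this mimics the practice of occasionally replacing trial
    locations from year to year.
    """
    pool = list(pool)
    if n_active > len(pool):
        raise ConfigurationError("location pool smaller than active set")
    if not current:
        return list(rng.choice(len(pool), size=n_active, replace=False))
    current = list(current)
    if len(current) != n_active:
        raise ConfigurationError("current set size mismatch")
    outside = [p for p in range(len(pool)) if p not in set(current)]
    n_swap = int(rng.binomial(n_active, replacement_rate))
    n_swap = min(n_swap, len(outside))
    if n_swap == 0:
        return current
    drop = rng.choice(n_active, size=n_swap, replace=False)
    add = rng.choice(len(outside), size=n_swap, replace=False)
    new = current.copy()
    for d, a in zip(drop, add):
        new[d] = outside[a]
    return new
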