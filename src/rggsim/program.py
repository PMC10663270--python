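"""Multi-stage soybean breeding-program simulation.

Drives the yearly pipeline: biparental crossing of selected parents, line
development to F4:5, staged evaluation BT1 -> BT2 -> BT3 -> PYT -> URT with
within-year eBLUP selection, and parent recycling on a five-year cycle
(crosses made in year t produce BT1 entries in year t+2, BT3 in t+4, and
PYT entries -- including the recycled parents themselves -- in year t+5).
The first five years use random founder crosses (burn-in) and are excluded
from gain estimation.

Outputs are a long-format MET table of trial entry means (the shape of
historical regional-trial records), the plot-level table, and a truth log
holding every line's true breeding value, first PYT year ``r_i``, crossing
year ``w_i`` and parentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import genome, phenotypes
from .genome import ConfigurationError
from .phenotypes import ScenarioConfig, TrendState

__all__ = ["StagePlan", "ProgramConfig", "ProgramResult", "run_program",
           "select_within_year", "select_parents", "DEFAULT_STAGES",
           "desk_scale_config", "desk_estimation_config"]


@dataclass(frozen=True)
class StagePlan:
    stage: str
    n_locations: int
    n_reps: int
    sel_fraction: float   # fraction advanced OUT of this stage


#: full-scale stage structure: locations (1, 2, 3, 8, 12), replicates
#: (1, 2, 3, 3, 3), 10% selected after BT1 and 20% thereafter.
DEFAULT_STAGES = (
    StagePlan("BT1", 1, 1, 0.10),
    StagePlan("BT2", 2, 2, 0.20),
    StagePlan("BT3", 3, 3, 0.20),
    StagePlan("PYT", 8, 3, 0.20),
    StagePlan("URT", 12, 3, 1.00),
)


@dataclass
class ProgramConfig:
    """Breeding-program settings; defaults are the full-scale study values."""

    scenario: ScenarioConfig
    years: int = 46
    n_founders: int = 499
    n_chrom: int = 20
    total_cM: float = 2145.5
    loci_per_chrom_range: tuple = (204, 349)
    n_qtl: int = 1000
    maf_min: float = 0.05
    n_crosses_range: tuple = (50, 80)
    family_size_range: tuple = (100, 234)   # BT1 cohort = crosses x family
    n_parents_range: tuple = (20, 30)
    n_checks_range: tuple = (3, 6)
    stages: tuple = DEFAULT_STAGES
    location_pool: int = 45
    location_replacement_rate: float = 0.2
    location_effect_sd: float = 6.0         # tau for fixed L_j ~ N(0, tau^2)
    burn_in_years: int = 5
    estimation_start: int | None = None     # default: first selected-parent PYT year
    check_reps_bt1: int = 3                 # replicated checks anchor BT1 residuals
    seed: int | None = None

    @property
    def stage_by_name(self) -> dict:
        return {s.stage: s for s in self.stages}


def desk_scale_config(scenario: ScenarioConfig, years: int = 26,
                      seed: int | None = None, **overrides) -> ProgramConfig:
    """A reduced-size program for desk experiments.

    Keeps the paper's selection fractions, the 20-30 parents per year and the
    five-year cycle, while shrinking the early-stage cohorts (BT1 ~ 1500),
    the genome (1000 loci, 500 QTL) and the trial network (PYT 3 locations,
    URT 4, pool of 20) so a full program simulates in seconds and the
    estimation mixed models stay under ~2000 entry-mean records.
    """
    cfg = ProgramConfig(
        scenario=scenario,
        years=years,
        n_founders=120,
        n_chrom=20,
        loci_per_chrom_range=(45, 55),
        n_qtl=500,
        n_crosses_range=(50, 80),
        family_size_range=(19, 30),
        n_parents_range=(20, 30),
        n_checks_range=(3, 6),
        stages=(
            StagePlan("BT1", 1, 1, 0.10),
            StagePlan("BT2", 2, 2, 0.20),
            StagePlan("BT3", 3, 3, 0.20),
            StagePlan("PYT", 3, 3, 0.20),
            StagePlan("URT", 4, 3, 1.00),
        ),
        location_pool=20,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def desk_estimation_config(scenario: ScenarioConfig, years: int = 24,
                           seed: int | None = None, **overrides) -> ProgramConfig:
    """A reduced-size program tuned for estimator benchmarking.

    BLUP-based estimators are sensitive to the number of trial records per
    line (shrinkage grows as per-line replication falls), so this variant
    keeps the regional trial network closer to the full-scale geometry
    (PYT 6 locations, URT 6) and scales the number of candidate lines down
    instead (10-14 parents per year); the early-stage funnel and selection
    fractions are unchanged.
    """
    cfg = ProgramConfig(
        scenario=scenario,
        years=years,
        n_founders=120,
        n_chrom=20,
        loci_per_chrom_range=(45, 55),
        n_qtl=500,
        n_crosses_range=(40, 60),
        family_size_range=(19, 30),
        n_parents_range=(10, 14),
        n_checks_range=(3, 6),
        stages=(
            StagePlan("BT1", 1, 1, 0.10),
            StagePlan("BT2", 2, 2, 0.20),
            StagePlan("BT3", 3, 3, 0.20),
            StagePlan("PYT", 6, 3, 0.20),
            StagePlan("URT", 6, 3, 1.00),
        ),
        location_pool=24,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class ProgramResult:
    met_means: pd.DataFrame
    met_plots: pd.DataFrame
    truth: pd.DataFrame
    meta: dict
    marker_ids: np.ndarray | None = None      # lines with marker genotypes
    marker_dosages: np.ndarray | None = None  # (n_lines, n_loci) in {0,1,2}

    @property
    def estimation_years(self) -> tuple:
        return (self.meta["estimation_start"], self.meta["years"])


# ---------------------------------------------------------------------------
# within-year selection
# ---------------------------------------------------------------------------

def select_within_year(stage_df: pd.DataFrame, fraction: float,
                       mode: str = "eblup",
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Select the top ``fraction`` of experimental lines in one stage-year.

    ``stage_df`` holds plot records (columns line, loc, value, resvar,
    is_check).  Ranking follows the within-year eBLUP of line means from a
    model with genotype random, location fixed and known per-trial residual
    variances: trial means are swept out, plot values averaged per line with
    inverse-variance weights, and the shrinkage (common to all equally
    replicated lines) applied.  ``mode="random"`` draws a uniform sample of
    the same size.  Check cultivars never enter the ranking; ties break by
    line id.
    """
    lines_df = stage_df[~stage_df["is_check"].astype(bool)]
    ids = np.array(sorted(lines_df["line"].unique()))
    n_sel = int(np.ceil(fraction * len(ids)))
    if n_sel >= len(ids):
        return ids
    if mode == "random":
        rng = np.random.default_rng(rng)
        return np.sort(rng.choice(ids, size=n_sel, replace=False))
    scores = _eblup_scores(stage_df)
    order = sorted(ids, key=lambda i: (-scores.get(i, -np.inf), i))
    return np.sort(np.array(order[:n_sel]))


def _eblup_scores(stage_df: pd.DataFrame) -> dict:
    """Line scores: inverse-variance weighted means of trial-centered plots.

    Centering each trial (location-year) by its own mean absorbs the fixed
    location effect plus all environment main effects; weighting by the known
    per-trial residual variance mirrors the heterogeneous-residual model.
    With equal replication the subsequent BLUP shrinkage is rank-preserving,
    so the weighted mean itself is the ranking statistic.
    """
    df = stage_df.dropna(subset=["value"]).copy()
    trial_mean = df.groupby("loc")["value"].transform("mean")
    df["adj"] = df["value"] - trial_mean
    df["wt"] = 1.0 / df["resvar"]
    df = df[~df["is_check"].astype(bool)]
    num = (df["adj"] * df["wt"]).groupby(df["line"]).sum()
    den = df.groupby("line")["wt"].sum()
    return (num / den).to_dict()


def _combined_parent_scores(frames: list) -> pd.Series:
    """Parent-selection scores from combined BT1+BT2+BT3 plot data."""
    df = pd.concat(frames, ignore_index=True).dropna(subset=["value"])
    df["adj"] = df["value"] - df.groupby(["stage", "year", "loc"])["value"].transform("mean")
    df["wt"] = 1.0 / df["resvar"]
    df = df[~df["is_check"].astype(bool)]
    num = (df["adj"] * df["wt"]).groupby(df["line"]).sum()
    den = df.groupby("line")["wt"].sum()
    return num / den


def select_parents(stage_frames: list, n_parents: int,
                   candidates=None, mode: str = "eblup",
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Select breeding (parental) lines on combined BT1+BT2+BT3 data.

    ``stage_frames`` are the plot tables of the cohort's three breeder-trial
    years; ``candidates`` restricts the choice (normally the BT3 entries).
    Ranking uses the combined-data eBLUP scores; ``mode="random"`` draws a
    uniform sample of the same size.  Returns at most ``n_parents`` ids.
    """
    scores = _combined_parent_scores(stage_frames)
    if candidates is not None:
        scores = scores[scores.index.isin(set(candidates))]
    k = min(n_parents, len(scores))
    if mode == "random":
        rng = np.random.default_rng(rng)
        return np.sort(rng.choice(np.array(sorted(scores.index)), size=k,
                                  replace=False))
    order = sorted(scores.index, key=lambda i: (-scores[i], i))
    return np.sort(np.array(order[:k]))


# ---------------------------------------------------------------------------
# program driver
# ---------------------------------------------------------------------------

class _Cohort:
    """One crossing cohort: ids, QTL dosages, haplotypes, pedigree."""

    def __init__(self, ids, theta, haps, parent1, parent2, cross_year):
        self.ids = np.asarray(ids)
        self.theta = theta
        self.haps = haps
        self.parent1 = np.asarray(parent1)
        self.parent2 = np.asarray(parent2)
        self.cross_year = cross_year
        self.survivors = {}

    def subset(self, ids):
        idx = {i: k for k, i in enumerate(self.ids)}
        sel = np.array([idx[i] for i in ids])
        return sel


def run_program(config: ProgramConfig, seed=None) -> ProgramResult:
    """Run one breeding program and return MET tables plus the truth log."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    scen = config.scenario
    mode = "random" if scen.random_selection else "eblup"
    years = config.years

    gmap = genome.build_genetic_map(config.n_chrom, config.total_cM,
                                    config.loci_per_chrom_range,
                                    config.n_qtl, rng)
    founders = genome.simulate_founders(config.n_founders, gmap,
                                        config.maf_min, rng)
    draws = phenotypes.sample_run_variances(scen, rng)
    effects = phenotypes.build_interaction_effects(
        gmap, founders, draws, J=config.location_pool, K=years, rng=rng,
        correlated=scen.correlated_gei)
    effects.phi_G = genome.sample_qtl_effects(gmap, draws.sigma2_G,
                                              founders, rng).phi_G

    loc_effects = rng.normal(0.0, config.location_effect_sd,
                             config.location_pool)
    year_effects = rng.normal(0.0, np.sqrt(draws.sigma2_Y), years + 1)
    trend = TrendState()
    ly_u: dict = {}

    def ly_value(loc: int, year: int) -> float:
        if (loc, year) not in ly_u:
            ly_u[(loc, year)] = float(rng.normal(0.0, np.sqrt(draws.sigma2_LY)))
        u = ly_u[(loc, year)]
        if scen.trend_enabled:
            return u + trend.trend_term(loc, year)
        return u

    # checks: fixed founder genotypes, present in every trial
    n_checks = int(rng.integers(config.n_checks_range[0],
                                config.n_checks_range[1] + 1))
    check_idx = rng.choice(config.n_founders, size=n_checks, replace=False)
    check_ids = np.array([f"CHK{j}" for j in range(n_checks)])
    check_theta = founders.qtl_dosages()[check_idx].astype(np.int8)

    stage_locs = {s.stage: [] for s in config.stages}
    cohorts: dict = {}          # cross_year -> _Cohort
    parents_by_year: dict = {}  # BT3 year -> list of (id, haps, theta)
    truth_rows: list = []
    mean_rows: list = []
    plot_rows: list = []
    first_pyt: dict = {}
    pedigree: dict = {}
    founder_theta = founders.qtl_dosages().astype(np.int8)

    stage_order = [s.stage for s in config.stages]
    plans = config.stage_by_name

    def make_crosses(year: int, parent_pool: list):
        """parent_pool: list of (id, haplotypes, theta_row)."""
        n_cross = int(rng.integers(config.n_crosses_range[0],
                                   config.n_crosses_range[1] + 1))
        fam = int(rng.integers(config.family_size_range[0],
                               config.family_size_range[1] + 1))
        k = len(parent_pool)
        pa = rng.integers(0, k, n_cross)
        pb = (pa + 1 + rng.integers(0, k - 1, n_cross)) % k
        pool_haps = np.stack([p[1] for p in parent_pool])
        ga = genome.gametes_batch(pool_haps[pa], gmap, rng)
        gb = genome.gametes_batch(pool_haps[pb], gmap, rng)
        f1 = np.stack([ga, gb], axis=1)
        # families of F2 (S0) seeds: self each F1 `fam` times
        f1_rep = np.repeat(f1, fam, axis=0)
        f2 = np.stack([genome.gametes_batch(f1_rep, gmap, rng),
                       genome.gametes_batch(f1_rep, gmap, rng)], axis=1)
        lines = genome.develop_lines_batch(f2, gmap, rng)
        n = lines.shape[0]
        ids = np.array([f"Y{year:02d}C{c:03d}F{f:03d}"
                        for c in range(n_cross) for f in range(fam)])
        p1 = np.repeat([parent_pool[a][0] for a in pa], fam)
        p2 = np.repeat([parent_pool[b][0] for b in pb], fam)
        theta = lines.sum(axis=1)[:, gmap.qtl_mask].astype(np.int8)
        return _Cohort(ids, theta, lines, p1, p2, year)

    def run_stage_trials(stage: str, year: int, cohort: _Cohort,
                         member_ids: np.ndarray) -> pd.DataFrame:
        plan = plans[stage]
        sel = cohort.subset(member_ids)
        theta = np.vstack([cohort.theta[sel], check_theta]).astype(float)
        all_ids = np.concatenate([member_ids, check_ids])
        is_check = np.concatenate([np.zeros(len(member_ids), bool),
                                   np.ones(n_checks, bool)])
        frames = []
        for loc in stage_locs[stage]:
            s2 = phenotypes.draw_trial_residual_variance(scen, rng)
            n_reps = plan.n_reps
            # replicated checks anchor the unreplicated BT1 trial
            if stage == "BT1" and config.check_reps_bt1 > n_reps:
                n_reps = config.check_reps_bt1
            sim = phenotypes.simulate_trial(
                theta, effects, scen.mu, loc_effects[loc],
                year_effects[year], ly_value(loc, year), loc, year - 1,
                n_reps, s2, rng)
            plots = sim["plots"]
            if stage == "BT1" and n_reps > plan.n_reps:
                plots[:len(member_ids), plan.n_reps:] = np.nan
            nrep = plots.shape[1]
            frame = pd.DataFrame({
                "line": np.repeat(all_ids, nrep),
                "loc": loc,
                "year": year,
                "stage": stage,
                "rep": np.tile(np.arange(nrep), len(all_ids)),
                "value": plots.ravel(),
                "resvar": s2,
                "is_check": np.repeat(is_check, nrep),
            })
            frames.append(frame)
            trend.ensure_eta(loc, rng)
            trend.record_usage(loc, year)
        return pd.concat(frames, ignore_index=True)

    for year in range(1, years + 1):
        # refresh stage location sets
        for s in config.stages:
            stage_locs[s.stage] = phenotypes.advance_locations(
                list(range(config.location_pool)), stage_locs[s.stage],
                s.n_locations, config.location_replacement_rate, rng)

        # ---- crossing block -------------------------------------------------
        if year + 2 <= years:
            if year <= config.burn_in_years or (year - 1) not in parents_by_year:
                k = int(rng.integers(config.n_parents_range[0],
                                     config.n_parents_range[1] + 1))
                idx = rng.choice(config.n_founders, size=min(k, config.n_founders),
                                 replace=False)
                pool = [(founders.ids[i], founders.haplotypes[i],
                         founder_theta[i]) for i in idx]
                w_rec = None
            else:
                pool = parents_by_year[year - 1]
                w_rec = year
            if w_rec is not None:
                for pid, haps, th in pool:
                    truth_rows.append({
                        "line": pid, "bv": float(th.astype(float) @ effects.phi_G),
                        "role": "parent", "w": year,
                        "r": first_pyt.get(pid, np.nan),
                    })
            cohorts[year] = make_crosses(year, pool)

        # ---- trials and selection ------------------------------------------
        year_stage_data = {}
        for si, stage in enumerate(stage_order):
            cross_year = year - 2 - si
            if cross_year not in cohorts:
                continue
            cohort = cohorts[cross_year]
            if stage == "BT1":
                member_ids = cohort.ids
            else:
                member_ids = cohort.survivors.get(stage)
                if member_ids is None or len(member_ids) == 0:
                    continue
            df = run_stage_trials(stage, year, cohort, member_ids)
            year_stage_data[stage] = (cohort, member_ids, df)
            plot_rows.append(df)

        for stage, (cohort, member_ids, df) in year_stage_data.items():
            plan = plans[stage]
            if stage in ("BT1", "BT2"):
                nxt = stage_order[stage_order.index(stage) + 1]
                cohort.survivors[nxt] = select_within_year(
                    df, plan.sel_fraction, mode, rng)
            elif stage == "BT3":
                # advance to PYT by within-year eBLUP ...
                advanced = select_within_year(df, plan.sel_fraction, mode, rng)
                # ... and select 20-30 parents on combined BT1+BT2+BT3 data
                frames = getattr(cohort, "stage_frames", []) + [df]
                k = int(rng.integers(config.n_parents_range[0],
                                     config.n_parents_range[1] + 1))
                par_ids = select_parents(frames, k, candidates=member_ids,
                                         mode=mode, rng=rng)
                sel = cohort.subset(par_ids)
                parents_by_year[year] = [
                    (pid, cohort.haps[s], cohort.theta[s])
                    for pid, s in zip(par_ids, sel)]
                cohort.survivors["PYT"] = np.sort(
                    np.unique(np.concatenate([advanced, par_ids])))
                cohort.parent_ids = par_ids
                surv = cohort.subset(cohort.survivors["PYT"])
                cohort.marker_dosages = cohort.haps[surv].sum(axis=1).astype(np.int8)
                cohort.haps = None  # haplotypes kept only via parents list
            elif stage == "PYT":
                cohort.survivors["URT"] = select_within_year(
                    df, plan.sel_fraction, mode, rng)
                for lid in member_ids:
                    first_pyt.setdefault(lid, year)
            # stash BT frames for later parent selection
            if stage in ("BT1", "BT2"):
                frames = getattr(cohort, "stage_frames", [])
                frames.append(df)
                cohort.stage_frames = frames

    # ---- assemble outputs ---------------------------------------------------
    plots = pd.concat(plot_rows, ignore_index=True)
    means = (plots.dropna(subset=["value"])
             .groupby(["line", "loc", "year", "stage", "is_check"],
                      as_index=False)
             .agg(value=("value", "mean"), n_plots=("value", "size"),
                  resvar=("resvar", "first")))
    means["se2"] = means["resvar"] / means["n_plots"]

    # truth log for every line that reached PYT, plus parents
    line_meta = {}
    for cy, cohort in cohorts.items():
        idx = {i: k for k, i in enumerate(cohort.ids)}
        for lid in cohort.survivors.get("PYT", []):
            k = idx[lid]
            line_meta[lid] = {
                "line": lid,
                "bv": float(cohort.theta[k].astype(float) @ effects.phi_G),
                "cross_year": cy,
                "parent1": cohort.parent1[k],
                "parent2": cohort.parent2[k],
                "r": first_pyt.get(lid, np.nan),
                "is_parent": lid in set(getattr(cohort, "parent_ids", [])),
                "w": np.nan,
            }
    for row in truth_rows:
        lid = row["line"]
        if lid in line_meta:
            line_meta[lid]["w"] = row["w"]
        else:
            line_meta[lid] = {"line": lid, "bv": row["bv"],
                              "cross_year": np.nan, "parent1": None,
                              "parent2": None, "r": row.get("r", np.nan),
                              "is_parent": True, "w": row["w"]}
    truth = pd.DataFrame(list(line_meta.values()))

    rmap = {**first_pyt}
    means["r"] = means["line"].map(rmap)
    wmap = truth.set_index("line")["w"].to_dict()
    means["w"] = means["line"].map(wmap)
    p1map = truth.set_index("line")["parent1"].to_dict()
    p2map = truth.set_index("line")["parent2"].to_dict()
    means["parent1"] = means["line"].map(p1map)
    means["parent2"] = means["line"].map(p2map)
    cymap = truth.set_index("line")["cross_year"].to_dict()
    means["cross_year"] = means["line"].map(cymap)

    est_start = config.estimation_start
    if est_start is None:
        est_start = config.burn_in_years + 6  # first PYT of selected parents
    # marker panel: founders (the genotyped base panel), checks, and every
    # line that reached PYT
    mk_ids = [*founders.ids, *check_ids]
    mk_rows = [founders.haplotypes.sum(axis=1).astype(np.int8),
               founders.haplotypes[check_idx].sum(axis=1).astype(np.int8)]
    for cy in sorted(cohorts):
        c = cohorts[cy]
        if getattr(c, "marker_dosages", None) is not None:
            mk_ids.extend(c.survivors["PYT"])
            mk_rows.append(c.marker_dosages)
    marker_ids = np.array(mk_ids)
    marker_dosages = np.vstack(mk_rows)

    meta = {
        "schema_version": 1,
        "scenario": scen.scenario_id,
        "years": years,
        "estimation_start": est_start,
        "variance_draws": draws.__dict__.copy(),
        "n_checks": n_checks,
        "eta": {int(k): float(v) for k, v in trend.eta.items()},
        "first_parent_crossing_year": config.burn_in_years + 1,
    }
    return ProgramResult(means, plots, truth, meta, marker_ids, marker_dosages)
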