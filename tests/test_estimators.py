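import numpy as np
import pandas as pd
import pytest

from rggsim import estimators as est
from rggsim.estimators import (CapabilityError, EstimationOptions,
                               indirect_slope, kappa_cumulative)

TABLE5_G = [2.1, 1.0, -0.7, 0.1, 3.4, 1.5, -1.0, -0.3, 3.9]
TABLE5_R = [1, 1, 1, 2, 2, 2, 2, 3, 3]


class TestKappa:
    def test_nine_line_worked_example(self):
        kap = kappa_cumulative(TABLE5_G, TABLE5_R)
        # yearly means 0.8 / 1.0 / 1.8, cumulative 0.8 / 1.8 / 3.6
        increments = kap.diff().fillna(kap.iloc[0])
        assert list(np.round(increments, 10)) == [0.8, 1.0, 1.8]
        assert list(np.round(kap, 10)) == [0.8, 1.8, 3.6]

    def test_all_zero_values_give_zero_kappa(self):
        kap = kappa_cumulative(np.zeros(6), [1, 1, 2, 2, 3, 3])
        assert np.allclose(kap, 0.0)

    def test_year_gap_is_an_error(self):
        with pytest.raises(ValueError, match="no lines first tested"):
            kappa_cumulative([1.0, 2.0], [1, 3])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            kappa_cumulative([1.0], [1, 2])


class TestIndirectSlope:
    def test_kappa_regression_slope(self):
        slope, _ = indirect_slope([0.8, 1.8, 3.6], [1, 2, 3])
        assert slope == pytest.approx(1.4)

    def test_per_line_regression_slope(self):
        slope, _ = indirect_slope(TABLE5_G, TABLE5_R)
        assert slope == pytest.approx(0.4727, abs=5e-4)

    def test_constant_values_give_zero_slope(self):
        slope, se = indirect_slope([2.0] * 6, [1, 1, 2, 2, 3, 3])
        assert slope == pytest.approx(0.0)

    def test_single_year_rejected(self):
        with pytest.raises(ValueError):
            indirect_slope([1.0, 2.0], [4, 4])


def synthetic_met(b=0.5, n_years=6, lines_per_year=4, locs=(0, 1, 2),
                  noise_sd=0.0, seed=0, trait_mean=46.0):
    """Deterministic MET fixture with known genetic trend ``b``.

    Line i first tested in year r has true value b*r plus a fixed within-
    cohort offset that averages zero; two checks are flat.  Locations add
    fixed offsets; optional iid noise.
    """
    rng = np.random.default_rng(seed)
    offs = np.linspace(-0.3, 0.3, lines_per_year)
    loc_eff = {j: 2.0 * j for j in locs}
    rows = []
    for r in range(1, n_years + 1):
        for i in range(lines_per_year):
            line = f"Y{r}L{i}"
            g = b * r + offs[i]
            for j in locs:
                rows.append({"line": line, "loc": j, "year": r, "stage": "PYT",
                             "value": trait_mean + g + loc_eff[j]
                             + rng.normal(0, noise_sd),
                             "se2": 0.5, "is_check": False, "r": r,
                             "w": np.nan, "parent1": "P1", "parent2": "P2",
                             "cross_year": r - 5, "n_plots": 3,
                             "resvar": 1.5})
    for chk in ("CHK0", "CHK1"):
        for yr in range(1, n_years + 1):
            for j in locs:
                rows.append({"line": chk, "loc": j, "year": yr, "stage": "PYT",
                             "value": trait_mean + loc_eff[j]
                             + rng.normal(0, noise_sd),
                             "se2": 0.5, "is_check": True, "r": np.nan,
                             "w": np.nan, "parent1": None, "parent2": None,
                             "cross_year": np.nan, "n_plots": 3,
                             "resvar": 1.5})
    return pd.DataFrame(rows)


class TestNoiselessRecovery:
    @pytest.mark.parametrize("model_id", ["E1", "E2"])
    def test_linear_trend_recovered_exactly(self, model_id):
        met = synthetic_met(b=0.5)
        r = est.estimate(model_id, met)
        assert r.slope == pytest.approx(0.5, abs=1e-5)

    def test_pheno_on_raw_means(self):
        met = synthetic_met(b=0.4)
        r = est.estimate("Pheno", met)
        assert r.slope == pytest.approx(0.4, abs=1e-8)
        assert r.kind == "indirect-regression"

    @pytest.mark.parametrize("model_id", ["E1", "E2"])
    def test_check_shift_invariance(self, model_id):
        met = synthetic_met(b=0.5, noise_sd=0.3, seed=3)
        r0 = est.estimate(model_id, met)
        shifted = met.copy()
        shifted.loc[shifted["is_check"], "value"] += 5.0
        r1 = est.estimate(model_id, shifted)
        assert r1.slope == pytest.approx(r0.slope, abs=1e-5)

    def test_e9_recovers_known_year_offsets(self):
        met = synthetic_met(b=0.5, noise_sd=0.0)
        # superimpose an arbitrary year effect profile; E9's chained
        # correction through shared checks must remove it exactly
        year_off = {y: 3.0 * np.sin(y) for y in met["year"].unique()}
        met["value"] = met["value"] + met["year"].map(year_off)
        r = est.estimate("E9", met)
        assert r.slope == pytest.approx(0.5, abs=1e-4)

    def test_e7_environment_prediction_recovers_offsets(self):
        met = synthetic_met(b=0.0, n_years=3)
        df = est.prepare_met(met)
        e_hat = est.predict_environment_effects(df)
        # noiseless checks: predicted environment effects reproduce the
        # location offsets up to shrinkage scale and a constant
        env = df.groupby("env")[["loc_f"]].first()
        env["e"] = e_hat.reindex(env.index)
        by_loc = env.groupby("loc_f")["e"].mean()
        assert by_loc.sort_values().index.tolist() == ["L0", "L1", "L2"]


class TestDispatchContracts:
    def test_unknown_model_rejected(self):
        with pytest.raises(CapabilityError):
            est.estimate("E99", synthetic_met())

    def test_e6_requires_checks(self):
        met = synthetic_met()
        with pytest.raises(CapabilityError, match="E6"):
            est.estimate("E6", met[~met["is_check"]])

    def test_grm_models_require_markers(self):
        with pytest.raises(CapabilityError, match="marker"):
            est.estimate("E0G", synthetic_met())

    def test_urt_subset_models_need_urt(self):
        with pytest.raises(CapabilityError):
            est.estimate("E4", synthetic_met())  # fixture has PYT only


class TestOnSimulatedProgram:
    def test_urt_models_use_strict_subset(self, tiny_program):
        yr = tiny_program.estimation_years
        r0 = est.estimate("E0", tiny_program.met_means, year_range=yr)
        r4 = est.estimate("E4", tiny_program.met_means, year_range=yr)
        assert r4.fit.n_obs < r0.fit.n_obs

    def test_e7_inflates_genotypic_variance(self, tiny_program):
        # with GL/GY absorbed by the environment covariate instead of their
        # own terms, the genotypic variance estimate picks up GEI variance
        from rggsim.lmm import ModelSpec, RandomEffect, fit_reml
        yr = tiny_program.estimation_years
        df = est.prepare_met(tiny_program.met_means, year_range=yr)
        sub = df[~df["is_check"]].reset_index(drop=True)
        full = fit_reml(ModelSpec(
            response="value", fixed_factors=["loc_f"],
            random=[RandomEffect("Y", "year_f", init=15.0),
                    RandomEffect("LY", "env", init=80.0),
                    RandomEffect("G", "line", init=6.0),
                    RandomEffect("GL", ("line", "loc_f"), init=5.0),
                    RandomEffect("GY", ("line", "year_f"), init=3.0)],
            weights="se2", residual_init=18.0), sub)
        e7 = est.estimate("E7", tiny_program.met_means, year_range=yr)
        assert (e7.fit.varcomp["G"]["sigma2"]
                >= full.varcomp["G"]["sigma2"])

    def test_direct_models_report_se_and_z(self, tiny_program):
        yr = tiny_program.estimation_years
        r = est.estimate("E2", tiny_program.met_means, year_range=yr)
        assert r.kind == "direct" and r.se > 0
        assert np.isfinite(r.z_ratio)

    @pytest.mark.parametrize("model_id", ["E10", "E11", "E12"])
    def test_pedigree_models_run_on_bt3_data(self, tiny_program, model_id):
        yr = tiny_program.estimation_years
        r = est.estimate(model_id, tiny_program.met_means, year_range=yr,
                         marker_ids=tiny_program.marker_ids,
                         marker_dosages=tiny_program.marker_dosages)
        assert np.isfinite(r.slope)

    def test_grm_variant_close_to_identity_variant(self, tiny_program):
        yr = tiny_program.estimation_years
        r7 = est.estimate("E7", tiny_program.met_means, year_range=yr)
        r7g = est.estimate("E7G", tiny_program.met_means, year_range=yr,
                           marker_ids=tiny_program.marker_ids,
                           marker_dosages=tiny_program.marker_dosages)
        assert np.isfinite(r7g.slope)
        assert abs(r7g.slope - r7.slope) < 0.5

    @pytest.mark.parametrize("model_id", [m for m in est.MODEL_IDS
                                          if m not in ("E1", "E2", "E7",
                                                       "EB", "E0", "E4",
                                                       "E10", "E11", "E12")])
    def test_whole_registry_produces_finite_slopes(self, tiny_program,
                                                   model_id):
        """Every registry model runs end-to-end on simulated records."""
        yr = tiny_program.estimation_years
        r = est.estimate(model_id, tiny_program.met_means,
                         options=EstimationOptions(maxiter=60),
                         year_range=yr,
                         marker_ids=tiny_program.marker_ids,
                         marker_dosages=tiny_program.marker_dosages)
        assert np.isfinite(r.slope)
        assert r.kind in ("direct", "indirect-regression", "indirect-kappa")

    def test_fa1_option_runs(self, tiny_program):
        yr = tiny_program.estimation_years
        r = est.estimate("E2V", tiny_program.met_means, year_range=yr,
                         options=EstimationOptions(v_structure="fa1",
                                                   maxiter=60))
        assert np.isfinite(r.slope)
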