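import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from rggsim.lmm import ModelSpec, RandomEffect, fit_reml


def one_way_data(g=12, n=8, sd_u=2.0, sd_e=1.5, seed=1):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sd_u, g)
    y = np.repeat(u, n) + rng.normal(0, sd_e, g * n)
    return pd.DataFrame({"y": y,
                         "grp": np.repeat([f"g{i:02d}" for i in range(g)], n)})


class TestBalancedOneWay:
    def test_reml_equals_anova_estimators(self):
        g, n = 12, 8
        df = one_way_data(g, n)
        fit = fit_reml(ModelSpec(response="y",
                                 random=[RandomEffect("grp", "grp")]), df)
        gm = df.groupby("grp")["y"].mean()
        msb = n * gm.var(ddof=1)
        msw = (df["y"] - df["grp"].map(gm)).pow(2).sum() / (g * (n - 1))
        assert fit.varcomp["grp"]["sigma2"] == pytest.approx((msb - msw) / n,
                                                             abs=1e-8)
        assert fit.varcomp["residual"]["sigma2"] == pytest.approx(msw, abs=1e-8)
        assert fit.converged

    def test_eblup_matches_closed_form_shrinkage(self):
        g, n = 10, 6
        df = one_way_data(g, n, seed=2)
        fit = fit_reml(ModelSpec(response="y",
                                 random=[RandomEffect("grp", "grp")]), df)
        lam = fit.varcomp["residual"]["sigma2"] / fit.varcomp["grp"]["sigma2"]
        mu = fit.fixed_effects["(Intercept)"]
        gm = df.groupby("grp")["y"].mean().sort_index()
        expected = (gm - mu) * n / (n + lam)
        assert np.allclose(fit.blups["grp"].sort_index(), expected, atol=1e-8)

    def test_constant_response_collapses_to_intercept(self):
        df = pd.DataFrame({"y": np.full(30, 5.0),
                           "grp": np.repeat(list("abcde"), 6)})
        fit = fit_reml(ModelSpec(response="y",
                                 random=[RandomEffect("grp", "grp")]), df)
        assert fit.fixed_effects["(Intercept)"] == pytest.approx(5.0)
        assert fit.varcomp["grp"]["sigma2"] < 1e-3
        assert fit.varcomp["residual"]["sigma2"] < 1e-3

    def test_blups_sum_to_zero(self):
        df = one_way_data(seed=3)
        fit = fit_reml(ModelSpec(response="y",
                                 random=[RandomEffect("grp", "grp")]), df)
        assert fit.blups["grp"].sum() == pytest.approx(0.0, abs=1e-6)


def crossed_data(seed=4, nl=30, ne=8):
    rng = np.random.default_rng(seed)
    lines = [f"L{i:02d}" for i in range(nl)]
    envs = [f"E{j}" for j in range(ne)]
    u = rng.normal(0, 1.5, nl)
    v = rng.normal(0, 2.5, ne)
    rows = []
    for i, li in enumerate(lines):
        for j, ej in enumerate(envs):
            rows.append((li, ej, 3.0 + u[i] + v[j] + rng.normal(0, 1.0)))
    return pd.DataFrame(rows, columns=["line", "env", "y"])


class TestStructures:
    def test_grm_identity_matches_identity_cov(self):
        df = crossed_data()
        nl = df["line"].nunique()
        ids = sorted(df["line"].unique())
        f_i = fit_reml(ModelSpec(response="y",
                                 random=[RandomEffect("G", "line"),
                                         RandomEffect("E", "env")]), df)
        f_g = fit_reml(ModelSpec(response="y",
                                 random=[RandomEffect("G", "line", cov="grm",
                                                      K=np.eye(nl), K_ids=ids),
                                         RandomEffect("E", "env")]), df)
        assert f_g.loglik == pytest.approx(f_i.loglik, abs=1e-6)
        assert f_g.varcomp["G"]["sigma2"] == pytest.approx(
            f_i.varcomp["G"]["sigma2"], abs=1e-6)
        assert np.allclose(f_g.blups["G"], f_i.blups["G"], atol=1e-6)

    def test_row_order_invariance(self):
        df = crossed_data(seed=5)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        f1 = fit_reml(ModelSpec(response="y",
                                random=[RandomEffect("G", "line"),
                                        RandomEffect("E", "env")]), df)
        f2 = fit_reml(ModelSpec(response="y",
                                random=[RandomEffect("G", "line"),
                                        RandomEffect("E", "env")]), shuffled)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-7)
        assert np.allclose(f1.blups["G"].sort_index(),
                           f2.blups["G"].sort_index(), atol=1e-7)

    def test_diagonal_covariance_recovers_heterogeneous_variances(self):
        rng = np.random.default_rng(6)
        nl, ne = 150, 4
        sig = np.array([0.4, 1.0, 2.5, 5.0])
        rows = []
        for i in range(nl):
            for j in range(ne):
                rows.append((f"L{i}", f"E{j}",
                             rng.normal(0, np.sqrt(sig[j])) + rng.normal(0, 0.3)))
        df = pd.DataFrame(rows, columns=["line", "env", "y"])
        fit = fit_reml(ModelSpec(
            response="y",
            random=[RandomEffect("GE", ("line", "env"), cov="diagonal",
                                 group_by="env")]), df)
        est = fit.varcomp["GE"]["sigma2_by_group"].sort_index().to_numpy()
        assert np.all(np.diff(est) > 0)  # ordering of variances recovered
        assert est[-1] / est[0] > 3

    def test_fa1_recovers_covariance_structure(self):
        rng = np.random.default_rng(7)
        nl, ne = 500, 5
        lam_t = rng.uniform(0.6, 1.4, ne)
        psi_t = rng.uniform(0.3, 0.6, ne)
        Sig = np.outer(lam_t, lam_t) + np.diag(psi_t)
        U = rng.multivariate_normal(np.zeros(ne), Sig, size=nl)
        rows = []
        for i in range(nl):
            for j in rng.choice(ne, size=2, replace=False):
                rows.append((f"L{i:03d}", f"E{j}",
                             1.0 + U[i, j] + rng.normal(0, 0.2)))
        df = pd.DataFrame(rows, columns=["line", "env", "y"])
        fit = fit_reml(ModelSpec(
            response="y",
            random=[RandomEffect("GE", ("line", "env"), cov="fa1",
                                 inner="env", block="line")]), df)
        est = fit.varcomp["GE"]["Sigma"].sort_index().sort_index(axis=1).to_numpy()
        c_est = est / np.sqrt(np.outer(np.diag(est), np.diag(est)))
        c_true = Sig / np.sqrt(np.outer(np.diag(Sig), np.diag(Sig)))
        rmse = np.sqrt(((c_est - c_true) ** 2).mean())
        assert rmse < 0.15

    def test_weighted_residuals_scale_with_known_variances(self):
        rng = np.random.default_rng(8)
        n = 300
        w = rng.uniform(0.5, 4.0, n)
        grp = np.repeat([f"g{i}" for i in range(30)], 10)
        u = dict(zip(sorted(set(grp)), rng.normal(0, 1.0, 30)))
        y = np.array([u[g] for g in grp]) + rng.normal(0, np.sqrt(2.0 * w))
        df = pd.DataFrame({"y": y, "grp": grp, "w": w})
        fit = fit_reml(ModelSpec(response="y", weights="w",
                                 random=[RandomEffect("grp", "grp")]), df)
        assert fit.varcomp["residual"]["sigma2"] == pytest.approx(2.0, rel=0.25)

    def test_heterogeneous_residual_groups(self):
        rng = np.random.default_rng(9)
        reps = 300
        df = pd.DataFrame({
            "y": np.concatenate([rng.normal(0, 1.0, reps),
                                 rng.normal(0, 3.0, reps)]),
            "trial": ["a"] * reps + ["b"] * reps,
        })
        fit = fit_reml(ModelSpec(response="y", residual_groups="trial"), df)
        s = fit.varcomp["residual"]["sigma2_by_group"]
        assert s["a"] == pytest.approx(1.0, rel=0.25)
        assert s["b"] == pytest.approx(9.0, rel=0.25)


class TestAgainstLme4:
    def test_crossed_random_model_matches_lme4(self, tmp_path):
        """Independent oracle: REML fit of a crossed two-factor model in R."""
        df = crossed_data(seed=10, nl=25, ne=6)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(y ~ 1 + (1|line) + (1|env), data = d, REML = TRUE)
            vc <- as.data.frame(VarCorr(m))
            cat(vc$vcov[vc$grp == "line"], vc$vcov[vc$grp == "env"],
                vc$vcov[vc$grp == "Residual"], fixef(m)[1], sep = "\\n")
        """))
        out = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, timeout=240)
        assert out.returncode == 0, out.stderr
        vline, venv, vres, mu = map(float, out.stdout.strip().split("\n"))
        fit = fit_reml(ModelSpec(response="y",
                                 random=[RandomEffect("G", "line"),
                                         RandomEffect("E", "env")]), df)
        assert fit.varcomp["G"]["sigma2"] == pytest.approx(vline, rel=1e-4, abs=1e-6)
        assert fit.varcomp["E"]["sigma2"] == pytest.approx(venv, rel=1e-4, abs=1e-6)
        assert fit.varcomp["residual"]["sigma2"] == pytest.approx(vres, rel=1e-4)
        assert fit.fixed_effects["(Intercept)"] == pytest.approx(mu, abs=1e-5)


class TestMonotoneLikelihood:
    def test_accepted_iterations_never_decrease_loglik(self, monkeypatch):
        # the step-halving driver must end at least as high as it starts
        df = crossed_data(seed=11)
        spec = ModelSpec(response="y", random=[RandomEffect("G", "line"),
                                               RandomEffect("E", "env")])
        bad_start = np.log(np.array([20.0, 0.01, 30.0]))
        fit = fit_reml(spec, df, start=bad_start)
        fit0 = fit_reml(spec, df, start=bad_start, maxiter=0)
        assert fit.loglik >= fit0.loglik - 1e-9
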