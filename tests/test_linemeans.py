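"""Variance partitioning, line means and heritability tests."""

import numpy as np
import pandas as pd
import pytest

from namqg import reml
from namqg.linemeans import (HeritabilityEstimate, ModelSpec,
                             fit_multienv_model, fit_single_env_model,
                             heritability_line_means, predict_line_means,
                             winsorize, _harmonic)
from namqg.simulate import (PlotTable, TraitArchitecture, TraitSpec,
                            simulate_map, simulate_plots, simulate_rils)


def _plot_frame(values, envs=None, lines=None, fams=None):
    n = len(values)
    envs = envs or ["e1"] * n
    lines = lines or [f"l{i}" for i in range(n)]
    fams = fams or ["F"] * n
    return pd.DataFrame({
        "line": lines, "family": fams, "env": envs,
        "row": np.arange(n), "col": 0, "block": 0,
        "trait": "t", "value": values, "n_plants": 1})


class TestWinsorize:
    def test_identity_when_within_bounds(self):
        df = _plot_frame(np.linspace(4, 6, 10))
        out, n = winsorize(PlotTable(df=df), 3.0)
        assert n == 0
        pd.testing.assert_frame_equal(out.df, df)

    def test_outlier_clipped_to_boundary(self):
        vals = np.concatenate([np.linspace(-1, 1, 100), [50.0]])
        df = _plot_frame(vals)
        out, n = winsorize(PlotTable(df=df), 3.0)
        m, s = vals.mean(), vals.std(ddof=1)
        assert n == 1
        assert out.df["value"].iloc[-1] == pytest.approx(m + 3 * s)
        assert np.allclose(out.df["value"].iloc[:-1], vals[:-1])

    def test_infinite_k_is_identity(self):
        vals = np.concatenate([np.linspace(-1, 1, 100), [50.0]])
        out, n = winsorize(PlotTable(df=_plot_frame(vals)), np.inf)
        assert n == 0

    def test_per_environment_limits(self):
        # same value is an outlier in one env, normal in the other
        v1 = np.concatenate([np.linspace(-1, 1, 100), [10.0]])
        v2 = np.full(101, 10.0) + np.linspace(-1, 1, 101)
        df = _plot_frame(np.concatenate([v1, v2]),
                         envs=["e1"] * 101 + ["e2"] * 101,
                         lines=[f"l{i}" for i in range(101)] * 2)
        out, n = winsorize(PlotTable(df=df), 3.0)
        assert n == 1

    def test_rejects_nonpositive_k(self):
        with pytest.raises(ValueError):
            winsorize(PlotTable(df=_plot_frame(np.arange(5.))), 0.0)


class TestRemlOracles:
    def test_balanced_reml_equals_anova(self):
        """On a balanced two-env design with replicate plots, REML matches
        the closed-form expected-mean-squares estimators to 1e-6."""
        rng = np.random.default_rng(42)
        G, E, r = 30, 2, 3
        sG, sGE, se = 2.0, 0.7, 1.0
        g = rng.normal(0, np.sqrt(sG), G)
        ge = rng.normal(0, np.sqrt(sGE), (G, E))
        y3 = g[:, None, None] + ge[:, :, None] + \
            rng.normal(0, np.sqrt(se), (G, E, r))
        y = y3.ravel()
        gi = np.repeat(np.arange(G), E * r)
        ei = np.tile(np.repeat(np.arange(E), r), G)
        Zg = np.eye(G)[gi]
        Zge = np.eye(G * E)[gi * E + ei]
        X = np.column_stack([np.ones(y.size), (ei == 1).astype(float)])
        fit = reml.reml_dense(y, X, {"G": Zg, "GxE": Zge})
        ybar_ge = y3.mean(2)
        ybar_g = ybar_ge.mean(1)
        ybar_e = ybar_ge.mean(0)
        MSE = ((y3 - ybar_ge[:, :, None]) ** 2).sum() / (G * E * (r - 1))
        MSG = E * r * ((ybar_g - ybar_ge.mean()) ** 2).sum() / (G - 1)
        MSGE = r * ((ybar_ge - ybar_g[:, None] - ybar_e[None, :]
                     + ybar_ge.mean()) ** 2).sum() / ((G - 1) * (E - 1))
        assert fit.variances["G"] == pytest.approx((MSG - MSGE) / (E * r),
                                                   abs=1e-6)
        assert fit.variances["GxE"] == pytest.approx((MSGE - MSE) / r,
                                                     abs=1e-6)
        assert fit.resid["resid"] == pytest.approx(MSE, abs=1e-6)

    def test_crossed_backend_matches_dense(self):
        rng = np.random.default_rng(3)
        F, nf, E = 5, 20, 3
        fam_of = np.repeat(np.arange(F), nf)
        L = F * nf
        Y = (4 + rng.normal(0, 0.7, F)[fam_of][:, None]
             + rng.normal(0, 0.8, L)[:, None]
             + rng.normal(0, 0.6, E)[None, :]
             + rng.normal(0, 0.5, (F, E))[fam_of]
             + rng.normal(0, 1.2, (L, E)))
        fit_c = reml.reml_crossed(Y, np.full(F, nf), per_family_ril=False)
        y = Y.ravel()
        li = np.repeat(np.arange(L), E)
        ei = np.tile(np.arange(E), L)
        terms = {"family": np.eye(F)[fam_of][li], "ril": np.eye(L)[li],
                 "env": np.eye(E)[ei],
                 "fam_env": np.eye(F * E)[fam_of[li] * E + ei]}
        fit_d = reml.reml_dense(y, np.ones((y.size, 1)), terms)
        assert fit_c.loglik == pytest.approx(fit_d.loglik, abs=1e-4)
        assert fit_c.sigma_fam == pytest.approx(fit_d.variances["family"],
                                                abs=1e-3)
        assert fit_c.sigma_ril[0] == pytest.approx(fit_d.variances["ril"],
                                                   abs=1e-3)
        assert fit_c.sigma_resid == pytest.approx(fit_d.resid["resid"],
                                                  abs=1e-3)

    def test_single_variance_source_recovered(self):
        rng = np.random.default_rng(6)
        F, nf, E = 10, 60, 2
        fam_of = np.repeat(np.arange(F), nf)
        L = F * nf
        Y = rng.normal(0, 1.0, L)[:, None] + rng.normal(0, 0.7, (L, E))
        fit = reml.reml_crossed(Y, np.full(F, nf), per_family_ril=False)
        assert fit.sigma_ril[0] == pytest.approx(1.0, rel=0.15)
        assert fit.sigma_fam < 0.05
        assert fit.sigma_fam_env < 0.05

    def test_all_constant_response_zero_components(self):
        Y = np.full((40, 3), 2.5)
        fit = reml.reml_crossed(Y, np.array([20, 20]))
        assert fit.sigma_fam == 0.0
        assert np.all(fit.sigma_ril == 0.0)
        assert fit.sigma_fam_env == 0.0
        assert fit.mu == pytest.approx(2.5, abs=1e-6)

    def test_ar1_grid_parameter_recovery(self):
        from namqg.simulate import _spatial_field
        rng = np.random.default_rng(9)
        Y = 3.0 + _spatial_field(rng, 50, 50, 2.0, 0.6, 0.6) \
            + rng.normal(0, 0.5, (50, 50))
        fit = reml.reml_ar1_grid(Y)
        assert fit.rho_row == pytest.approx(0.6, abs=0.1)
        assert fit.rho_col == pytest.approx(0.6, abs=0.1)

    def test_nonconvergence_is_reported_not_hidden(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(30, 2))
        fit = reml.reml_crossed(Y, np.array([15, 15]), maxiter=2)
        assert fit.converged is False


class TestModelFitting:
    def test_multienv_fit_recovers_targets(self, nam_plots):
        pop, plots, spec = nam_plots
        fit = fit_multienv_model(plots, ModelSpec(trait="RPR"))
        assert fit.converged
        # generous single-replicate tolerances; the acceptance suite does
        # the multi-replicate recovery study
        assert fit.mean_ril == pytest.approx(spec.ril, abs=0.25)
        assert fit.mean_resid == pytest.approx(spec.ril_env + spec.plant,
                                               abs=0.35)

    def test_requires_records(self, nam_plots):
        _, plots, _ = nam_plots
        with pytest.raises(ValueError, match="no records"):
            fit_multienv_model(plots, ModelSpec(trait="nope"))

    def test_dense_backward_selection_drops_null_terms(self):
        gmap = simulate_map(2, 8, 80.0, 1e8, seed=61)
        pop = simulate_rils(gmap, 4, 30, seed=62)
        spec = TraitSpec(family=0.3, ril=0.5, env=0.2, fam_env=0.2,
                         ril_env=0.3, block=2.0, row=0.0, col=0.0,
                         plant=0.5, mean=5.0)
        plots = simulate_plots(pop, TraitArchitecture(traits={"t": spec}),
                               2, (12, 10), 1, seed=63, block_rows=3)
        ms = ModelSpec(trait="t", per_family_ril=False,
                       env_terms=("block", "row"), backward=True,
                       method="dense")
        fit = fit_multienv_model(plots, ms)
        kept = [t for t in fit.retained if t.startswith(("block", "row"))]
        assert "block" in kept
        assert "row" not in kept

    def test_single_env_model_smoke(self, nam_plots):
        _, plots, _ = nam_plots
        fit = fit_single_env_model(plots, "env1",
                                   ModelSpec(trait="RPR",
                                             per_family_ril=False))
        assert fit.converged
        assert list(fit.resid) == ["env1"]

    def test_covariate_component_detected(self):
        # trait B's line means drive part of trait A: the random covariate
        # regression absorbs variance that otherwise lands in RIL(family)
        rng = np.random.default_rng(71)
        gmap = simulate_map(2, 8, 80.0, 1e8, seed=72)
        pop = simulate_rils(gmap, 5, 60, seed=73)
        n = len(pop.lines)
        b_vals = rng.normal(0, 1, n)
        rows = []
        for e in ("e1", "e2"):
            perm = rng.permutation(400)[:n]
            r, c = np.unravel_index(perm, (20, 20))
            noise = rng.normal(0, 0.7, n)
            rows.append(pd.DataFrame({
                "line": pop.lines, "family": pop.family.to_numpy(),
                "env": e, "row": r, "col": c, "block": 0, "trait": "A",
                "value": 5 + 0.8 * b_vals + noise, "n_plants": 1}))
            rows.append(pd.DataFrame({
                "line": pop.lines, "family": pop.family.to_numpy(),
                "env": e, "row": r, "col": c, "block": 0, "trait": "B",
                "value": b_vals + rng.normal(0, 0.1, n), "n_plants": 1}))
        plots = PlotTable(df=pd.concat(rows, ignore_index=True))
        plain = fit_multienv_model(plots, ModelSpec(trait="A",
                                                    per_family_ril=False))
        adj = fit_multienv_model(plots, ModelSpec(trait="A", covariate="B",
                                                  per_family_ril=False))
        assert adj.covariate > 0.0
        assert adj.mean_ril < plain.mean_ril


class TestLineMeans:
    def test_blue_equals_plot_mean_single_env_balanced(self):
        rng = np.random.default_rng(81)
        df = []
        for i in range(30):
            for r in range(2):
                df.append((f"l{i:02d}", "F", "e1", i, r, 0, "t",
                           rng.normal(5, 1), 1))
        plots = PlotTable(df=pd.DataFrame(
            df, columns=["line", "family", "env", "row", "col", "block",
                         "trait", "value", "n_plants"]))
        fit = fit_multienv_model(plots, ModelSpec(trait="t",
                                                  per_family_ril=False,
                                                  method="dense"))
        blue = predict_line_means(fit, plots, mode="BLUE")
        expect = plots.df.groupby("line")["value"].mean()
        got = blue.set_index("line")["value"]
        assert np.allclose(got, expect.loc[got.index], atol=1e-8)

    def test_blup_shrinks_toward_family_mean(self, nam_plots):
        _, plots, _ = nam_plots
        fit = fit_multienv_model(plots, ModelSpec(trait="RPR"))
        blup = predict_line_means(fit, plots, mode="BLUP")
        blue = predict_line_means(fit, plots, mode="BLUE")
        merged = blup.merge(blue, on=["line", "family"],
                            suffixes=("_blup", "_blue"))
        v = merged.groupby("family").agg(
            vb=("value_blup", "var"), ve=("value_blue", "var"))
        assert (v["vb"] <= v["ve"] + 1e-9).all()
        # shrunken and unshrunken means still rank lines similarly
        assert np.corrcoef(merged["value_blup"],
                           merged["value_blue"])[0, 1] > 0.5

    def test_blup_limits_no_shrinkage_and_full_shrinkage(self):
        rng = np.random.default_rng(91)
        F, nf, E = 3, 12, 2
        Y = rng.normal(5, 1, (F * nf, E))
        fit = reml.reml_crossed(Y, np.full(F, nf))
        # sigma_ril -> infinity: BLUP -> centered line means (BLUE)
        fit.sigma_ril = np.full(F, 1e8)
        fit.sigma_fam = 0.0
        fit.sigma_env = 0.0
        fit.sigma_fam_env = 0.0
        fit.sigma_resid = 1.0
        u = reml.crossed_blup(fit)
        expect = Y.mean(1) - fit.mu
        assert np.allclose(u, expect, atol=1e-5)
        # sigma_ril = 0: every BLUP collapses to its family's effect
        fit.sigma_ril = np.zeros(F)
        fit.sigma_fam = 1.0
        u0 = reml.crossed_blup(fit)
        for f in range(F):
            block = u0[f * nf:(f + 1) * nf]
            assert np.ptp(block) == pytest.approx(0.0, abs=1e-10)


class TestHeritability:
    def _fit(self, **kw):
        base = dict(trait="t", family=0.4, ril={"F01": 0.6, "F02": 0.6},
                    env=0.1, fam_env=0.3, ril_env=0.3, resid={"e1": 0.9,
                                                              "e2": 0.9},
                    lines=pd.Index(["a", "b"]),
                    line_family=pd.Series(["F01", "F02"],
                                          index=["a", "b"]),
                    n_env_per_line=pd.Series([2, 2], index=["a", "b"]),
                    n_env_per_family=pd.Series([2, 2],
                                               index=["F01", "F02"]),
                    n_plots_per_line=pd.Series([2, 2], index=["a", "b"]))
        base.update(kw)
        from namqg.linemeans import VarianceComponents
        return VarianceComponents(**base)

    def test_perfect_heritability(self):
        fit = self._fit(fam_env=0.0, ril_env=0.0,
                        resid={"e1": 0.0, "e2": 0.0})
        h = heritability_line_means(fit)
        assert h.H2 == pytest.approx(1.0)

    def test_known_component_arithmetic(self):
        fit = self._fit()
        h = heritability_line_means(fit)
        num = 0.4 + 0.6
        den = num + 0.3 / 2 + 0.3 / 2 + 0.9 / 2
        assert h.numerator == pytest.approx(num)
        assert h.H2 == pytest.approx(num / den)

    def test_within_family_uses_single_ril_variance(self):
        fit = self._fit(ril={"F01": 0.8, "F02": 0.2})
        h = heritability_line_means(fit, family="F01")
        assert h.numerator == pytest.approx(0.8)
        with pytest.raises(KeyError):
            heritability_line_means(fit, family="missing")

    def test_balanced_harmonic_equals_arithmetic(self):
        counts = np.array([3.0, 3.0, 3.0])
        assert _harmonic(counts) == pytest.approx(counts.mean())
        unbal = np.array([1.0, 3.0])
        assert _harmonic(unbal) < unbal.mean()

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            _harmonic(np.array([0.0, 2.0]))
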