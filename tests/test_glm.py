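"""Design matrices, likelihoods, posterior machinery and prediction contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import approx_fprime

from dmtrank import glm
from dmtrank.glm import (
    DesignTransform,
    MCMCConfig,
    ModelSpec,
    PosteriorFit,
    PriorConfig,
    build_design,
)

from conftest import make_cycles


class TestDesignMatrix:
    def test_non_personalized_columns(self):
        d = build_design(make_cycles(), ModelSpec("relapse", "non_personalized"))
        assert d.columns == [
            "index_dmt[FTY]", "index_dmt[GA]", "index_dmt[IF]",
            "index_dmt[NA]", "index_dmt[TERI]",
        ]
        assert np.allclose(d.offset, np.log(make_cycles()["index_duration"]))

    def test_column_counts_by_complexity(self):
        df = make_cycles()
        n_np = build_design(df, ModelSpec("relapse", "non_personalized")).X.shape[1]
        n_prog = build_design(df, ModelSpec("relapse", "prognostic")).X.shape[1]
        n_pred = build_design(df, ModelSpec("relapse", "predictive")).X.shape[1]
        assert n_np == 5
        # + age, gender, EDSS, second-line, current DMT (6), its duration,
        #   their interaction (6), and the four history distances/counts
        assert n_prog == n_np + 4 + 6 + 1 + 6 + 4
        # + four index-therapy interaction blocks of 5 dummies each
        assert n_pred == n_prog + 4 * 5

    def test_nesting_is_column_prefix(self):
        df = make_cycles()
        prog = build_design(df, ModelSpec("relapse", "prognostic"))
        pred = build_design(df, ModelSpec("relapse", "predictive"))
        assert pred.columns[: len(prog.columns)] == prog.columns
        assert np.allclose(pred.X[:, : prog.X.shape[1]], prog.X)

    def test_index_dmt_only_affects_its_own_columns(self):
        df = make_cycles(index_dmt=["DMF", "DMF", "DMF", "DMF"])
        df2 = df.copy()
        df2["index_dmt"] = "NA"
        d1 = build_design(df, ModelSpec("relapse", "prognostic"))
        d2 = build_design(df2, ModelSpec("relapse", "prognostic"), transform=d1.transform)
        keep = [j for j, c in enumerate(d1.columns) if not c.startswith("index_dmt")]
        assert np.allclose(d1.X[:, keep], d2.X[:, keep])

    def test_unseen_level_is_named_in_error(self):
        df = make_cycles(index_dmt=["DMF", "FTY", "QQQ", "NA"])
        with pytest.raises(ValueError, match="QQQ"):
            build_design(df, ModelSpec("relapse", "non_personalized"))

    def test_transform_reuse_is_exact(self):
        df = make_cycles()
        d1 = build_design(df, ModelSpec("relapse", "prognostic"))
        d2 = build_design(df.iloc[:2], ModelSpec("relapse", "prognostic"), transform=d1.transform)
        assert np.allclose(d2.X, d1.X[:2])

    def test_interaction_columns_are_products(self):
        df = make_cycles()
        d = build_design(df, ModelSpec("relapse", "predictive"))
        j = d.columns.index("index_dmt[NA]:relapses_count")
        jna = d.columns.index("index_dmt[NA]")
        jrc = d.columns.index("relapses_count")
        assert np.allclose(d.X[:, j], d.X[:, jna] * d.X[:, jrc])

    def test_zero_duration_rejected(self):
        df = make_cycles(index_duration=[0.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="index_duration"):
            build_design(df, ModelSpec("relapse", "non_personalized"))


class TestLikelihoods:
    def test_nb_logpmf_matches_scipy(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 20, 50)
        mu = rng.uniform(0.1, 5.0, 50)
        shape = 1.7
        ours = glm.nb_logpmf(y, mu, shape)
        ref = stats.nbinom.logpmf(y, shape, shape / (shape + mu))
        assert np.allclose(ours, ref, atol=1e-10)

    def test_bernoulli_logit_logpmf(self):
        eta = np.array([-2.0, 0.0, 3.0])
        y = np.array([0, 1, 1])
        from scipy.special import expit

        ref = stats.bernoulli.logpmf(y, expit(eta))
        assert np.allclose(glm.bernoulli_logit_logpmf(y, eta), ref, atol=1e-12)


class TestPosteriorInternals:
    @pytest.mark.parametrize("response", ["relapse", "cdp"])
    def test_analytic_gradient_matches_finite_difference(self, response):
        df = make_cycles()
        spec = ModelSpec(response, "prognostic")
        d = build_design(df, spec)
        y = df["n_relapses"].to_numpy() if response == "relapse" else df["cdp"].to_numpy().astype(int)
        post = glm._Posterior(d, y, spec)
        rng = np.random.default_rng(1)
        theta = 0.2 * rng.standard_normal(post.ndim)
        g_num = approx_fprime(theta, lambda t: post.neg_log_prob_grad(t)[0], 1e-6)
        g_ana = post.neg_log_prob_grad(theta)[1]
        assert np.allclose(g_num, g_ana, atol=1e-3)

    def test_batch_and_single_log_prob_agree(self):
        df = make_cycles()
        spec = ModelSpec("relapse", "non_personalized")
        d = build_design(df, spec)
        post = glm._Posterior(d, df["n_relapses"].to_numpy(), spec)
        rng = np.random.default_rng(2)
        thetas = 0.3 * rng.standard_normal((5, post.ndim))
        batch = post.log_prob_batch(thetas)
        singles = [-post.neg_log_prob_grad(t)[0] for t in thetas]
        assert np.allclose(batch, singles, rtol=1e-10)


class TestPriors:
    def test_default_priors_are_the_documented_ones(self, fit_relapse_prognostic):
        prior = fit_relapse_prognostic.spec.prior
        assert prior.intercept_scale == 10.0
        assert prior.coef_scale == 2.5
        assert prior.dispersion_scale == 5.0
        assert prior.site_sd_shape == 1.0 and prior.site_sd_rate == 1.0

    def test_scaled_variant(self):
        p = PriorConfig().scaled(2.0)
        assert p.intercept_scale == 20.0 and p.coef_scale == 5.0
        assert p.site_sd_shape == 1.0  # gamma prior untouched

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            PriorConfig(coef_scale=0.0)


class TestFit:
    def test_rhat_present_and_finite(self, fit_relapse_prognostic):
        rh = fit_relapse_prognostic.rhat
        assert "intercept" in rh and "site_sd" in rh and "dispersion" in rh
        assert all(np.isfinite(v) for v in rh.values())

    def test_convergence_error_lists_parameters(self, small_registry):
        cycles, _, _ = small_registry
        spec = ModelSpec("relapse", "non_personalized")
        mcmc = MCMCConfig(chains=2, warmup=50, post=30, draws=60, seed=0, rhat_threshold=1.0)
        with pytest.raises(glm.ConvergenceError, match="R-hat"):
            glm.fit(spec, cycles.head(200), mcmc=mcmc)

    def test_needs_two_sites(self):
        df = make_cycles(site_id=["A", "A", "A", "A"])
        with pytest.raises(ValueError, match="site"):
            glm.fit(ModelSpec("relapse", "non_personalized"), df)


class TestPrediction:
    def test_site_invariance_when_intercepts_zeroed(self, fit_relapse_predictive, small_registry):
        cycles, _, _ = small_registry
        a = cycles.head(20).copy()
        b = a.copy()
        b["site_id"] = "SOMEWHERE_NEW"
        pa = glm.predict_counterfactual(fit_relapse_predictive, a, dmt="FTY")
        pb = glm.predict_counterfactual(fit_relapse_predictive, b, dmt="FTY")
        assert np.array_equal(pa.mean, pb.mean)

    def test_mean_scales_linearly_with_duration(self, fit_relapse_predictive, small_registry):
        cycles, _, _ = small_registry
        s1 = glm.predict_counterfactual(fit_relapse_predictive, cycles.head(30), "DMF", duration=1.0)
        s2 = glm.predict_counterfactual(fit_relapse_predictive, cycles.head(30), "DMF", duration=2.0)
        assert np.allclose(s2.mean, 2.0 * s1.mean, rtol=1e-10)

    def test_observed_dmt_equals_default_prediction(self, fit_relapse_predictive, small_registry):
        cycles, _, _ = small_registry
        row = cycles.head(5)
        default = glm.predict_counterfactual(fit_relapse_predictive, row)
        same = glm.predict_counterfactual(
            fit_relapse_predictive, row.assign(index_dmt=row["index_dmt"].iloc[0]),
            dmt=row["index_dmt"].iloc[0],
        )
        # rows whose observed therapy equals the requested one agree exactly
        i = row["index_dmt"] == row["index_dmt"].iloc[0]
        assert np.allclose(default.mean[i.to_numpy()], same.mean[i.to_numpy()])

    def test_unseen_dmt_rejected(self, fit_relapse_predictive, small_registry):
        cycles, _, _ = small_registry
        with pytest.raises(ValueError, match="unseen level"):
            glm.predict_counterfactual(fit_relapse_predictive, cycles.head(2), dmt="ABC")

    def test_frac_favorable_within_unit_interval(self, fit_cdp_prognostic, small_registry):
        cycles, _, _ = small_registry
        s = glm.predict_counterfactual(fit_cdp_prognostic, cycles.head(50), "GA")
        assert np.all((s.frac_favorable >= 0) & (s.frac_favorable <= 1))
        assert np.allclose(s.mean, 1.0 - s.frac_favorable)  # P(CDP) = 1 - P(none)

    def test_sampled_outcomes_match_summary_mean(self, fit_relapse_prognostic, small_registry):
        cycles, _, _ = small_registry
        head = cycles.head(200)
        s = glm.predict_counterfactual(fit_relapse_prognostic, head, "DMF")
        draws = glm.sample_outcomes(
            fit_relapse_prognostic, head, "DMF", rng=np.random.default_rng(0)
        )
        se = draws.mean(axis=0).std() / np.sqrt(len(head))
        assert abs(draws.mean() - s.mean.mean()) < 5 * se


class TestNesting:
    def test_zeroed_interactions_reproduce_prognostic_predictions(
        self, fit_relapse_predictive, small_registry
    ):
        """The predictive model with interaction coefficients pinned to zero
        is exactly the prognostic model with the shared coefficients."""
        cycles, _, _ = small_registry
        pred_fit = fit_relapse_predictive
        zeroed = pred_fit.with_zeroed_coefficients(glm.INTERACTION_TERMS)

        n_shared = len(
            build_design(cycles, ModelSpec("relapse", "prognostic"), transform=pred_fit.transform).columns
        )
        from dataclasses import replace

        as_prognostic = replace(
            zeroed,
            spec=ModelSpec("relapse", "prognostic", pred_fit.spec.prior),
            columns=pred_fit.columns[:n_shared],
            beta=pred_fit.beta[:, :, :n_shared],
        )
        a = glm.predict_counterfactual(zeroed, cycles.head(40), "NA")
        b = glm.predict_counterfactual(as_prognostic, cycles.head(40), "NA")
        assert np.array_equal(a.mean, b.mean)

    def test_with_zeroed_coefficients_unknown_term(self, fit_relapse_predictive):
        with pytest.raises(KeyError):
            fit_relapse_predictive.with_zeroed_coefficients(["nope:nada"])


class TestPointwiseLogLik:
    def _one_cycle(self, **kw):
        base = dict(
            patient_id=["x"], site_id=["A"], index_dmt=["DMF"],
            index_duration=[1.0], cdp=[True], n_relapses=[2],
        )
        base.update(kw)
        return pd.DataFrame(base)

    def _point_fit(self, response, intercept=0.0, dispersion=None):
        cols = [f"index_dmt[{d}]" for d in ("FTY", "GA", "IF", "NA", "TERI")]
        return PosteriorFit.from_point(
            ModelSpec(response, "non_personalized"),
            cols, DesignTransform({}, {}), ["A", "B"],
            intercept=intercept, beta=np.zeros(5), dispersion=dispersion,
        )

    def test_bernoulli_closed_form(self):
        # single draw with p = 0.5 -> NLL = log 2
        fit = self._point_fit("cdp", intercept=0.0)
        _, total = glm.pointwise_log_lik(fit, self._one_cycle(index_duration=[1.0]))
        assert -total == pytest.approx(np.log(2.0), abs=1e-12)

    def test_nb_matches_pmf_oracle(self):
        fit = self._point_fit("relapse", intercept=np.log(0.7), dispersion=1.3)
        df = self._one_cycle(n_relapses=[3], index_duration=[2.0])
        _, total = glm.pointwise_log_lik(fit, df)
        mu = 2.0 * 0.7
        ref = stats.nbinom.logpmf(3, 1.3, 1.3 / (1.3 + mu))
        assert total == pytest.approx(ref, abs=1e-10)

    def test_total_is_sum_of_pointwise(self, fit_relapse_prognostic, small_registry):
        cycles, _, _ = small_registry
        per, total = glm.pointwise_log_lik(fit_relapse_prognostic, cycles.head(50))
        assert total == pytest.approx(per.sum())


class TestFitSerialization:
    def test_save_load_round_trip(self, fit_relapse_prognostic, small_registry, tmp_path):
        cycles, _, _ = small_registry
        fit = fit_relapse_prognostic
        fit.save(tmp_path / "fit")
        back = glm.PosteriorFit.load(tmp_path / "fit")
        assert back.columns == fit.columns
        assert back.spec == fit.spec
        assert np.allclose(back.flat("beta"), fit.flat("beta"))
        assert np.allclose(back.flat("site_sd"), fit.flat("site_sd"))
        a = glm.predict_counterfactual(fit, cycles.head(10), "GA")
        b = glm.predict_counterfactual(back, cycles.head(10), "GA")
        assert np.allclose(a.mean, b.mean)


class TestZeroSiteHeterogeneity:
    def test_site_sd_collapses_and_fixed_effects_survive(self):
        """With no between-site heterogeneity the posterior of the site SD
        concentrates near zero while fixed effects stay recovered."""
        from dmtrank import simulate

        cfg = simulate.SimConfig(n_patients=800, n_sites=8, site_sd=0.0, seed=14)
        cycles, _, truth = simulate.generate_registry(cfg)
        fit = glm.fit(
            ModelSpec("relapse", "non_personalized"), cycles,
            mcmc=MCMCConfig(chains=2, warmup=400, post=200, draws=400, seed=0),
        )
        # with 8 sites the intercept-estimation noise floors the SD around
        # 0.1-0.2; "collapsed" means well below the prior scale (1.0) and
        # the default-condition heterogeneity (0.25)
        assert fit.flat("site_sd").mean() < 0.25
        beta_true = truth.beta["relapse"][: len(fit.columns)]
        draws = fit.flat("beta")
        z = np.abs(draws.mean(axis=0) - beta_true) / draws.std(axis=0)
        assert np.max(z) < 3.5  # truth within posterior uncertainty
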