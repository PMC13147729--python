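"""Regression, variance moderation, FDR and sensitivity-scenario behaviour."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from spermage import (
    Dataset,
    GeneratorConfig,
    ShrinkageParams,
    adjust_fdr,
    beta_to_m,
    fit_probe_models,
    global_methylation_tests,
    make_annotation,
    make_beta_matrix,
    make_covariates,
    moderate_statistics,
    run_ewas,
    sensitivity_rerun,
)
from spermage.ewas import estimate_prior


def _cov(n=20, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"age": rng.integers(18, 36, n).astype(float),
         "bmi": rng.normal(24, 3, n),
         "patient": rng.integers(0, 2, n)},
        index=pd.Index([f"S{i}" for i in range(n)], name="subject_id"),
    )


class TestFitProbeModels:
    def test_noiseless_slope_is_exact(self):
        cov = _cov()
        m = pd.DataFrame([0.1 * cov["age"].to_numpy() + 2.0],
                         index=["p1"], columns=cov.index)
        fits = fit_probe_models(m, cov)
        assert fits.loc["p1", "slope_age"] == pytest.approx(0.1, abs=1e-10)
        assert fits.loc["p1", "s2"] == pytest.approx(0.0, abs=1e-18)

    def test_constant_probe(self):
        cov = _cov()
        m = pd.DataFrame(1.5, index=["p1", "p2"], columns=cov.index)
        fits = fit_probe_models(m, cov)
        assert np.allclose(fits["slope_age"], 0.0, atol=1e-12)
        assert np.allclose(fits["s2"], 0.0, atol=1e-18)
        assert fits.loc["p1", "mean_m"] == pytest.approx(1.5)

    def test_matches_statsmodels_per_probe(self, rng):
        cov = _cov(30, seed=3)
        m = pd.DataFrame(rng.normal(0, 1, (5, 30)),
                         index=[f"p{i}" for i in range(5)],
                         columns=cov.index)
        fits = fit_probe_models(m, cov)
        import statsmodels.api as sm

        X = sm.add_constant(cov[["age", "bmi", "patient"]].astype(float))
        for probe in m.index:
            ols = sm.OLS(m.loc[probe], X).fit()
            assert fits.loc[probe, "slope_age"] == pytest.approx(
                ols.params["age"], rel=1e-10)
            assert fits.loc[probe, "s2"] == pytest.approx(
                ols.mse_resid, rel=1e-10)

    def test_ols_slope_unbiased_monte_carlo(self):
        # 1,000 simulated probes, ΔM = -0.05/yr, sd 0.3, n = 63
        cfg = GeneratorConfig(seed=13)
        cov = make_covariates(63, cfg)
        rng = np.random.default_rng(99)
        age = cov["age"].to_numpy()
        m = pd.DataFrame(
            -0.05 * (age - age.mean()) + rng.normal(0, 0.3, (1000, 63)),
            index=[f"p{i}" for i in range(1000)], columns=cov.index)
        fits = fit_probe_models(m, cov)
        assert abs(fits["slope_age"].mean() + 0.05) <= 0.005

    def test_rank_deficient_design_named(self):
        cov = _cov()
        cov["bmi"] = cov["age"] * 2.0
        m = pd.DataFrame(0.5, index=["p1"], columns=cov.index)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_probe_models(m, cov)

    def test_too_few_subjects(self):
        cov = pd.DataFrame({"age": [18.0, 25.0, 30.0, 35.0],
                            "bmi": [22.0, 27.0, 21.0, 26.0],
                            "patient": [0, 1, 0, 1]},
                           index=["a", "b", "c", "d"])
        m = pd.DataFrame(0.5, index=["p1"], columns=cov.index)
        with pytest.raises(ValueError, match="subjects"):
            fit_probe_models(m, cov)


class TestModeration:
    def _fits(self, n_probes=50, seed=0):
        rng = np.random.default_rng(seed)
        cov = _cov(25, seed=seed)
        m = pd.DataFrame(rng.normal(0, rng.uniform(0.1, 0.6, (n_probes, 1)),
                                    (n_probes, 25)),
                         index=[f"p{i}" for i in range(n_probes)],
                         columns=cov.index)
        return fit_probe_models(m, cov)

    def test_d0_zero_recovers_ordinary_t(self):
        fits = self._fits()
        table, _ = moderate_statistics(
            fits, ShrinkageParams(prior_df=0.0, prior_variance=1.0))
        ordinary_t = fits["slope_age"] / (fits["se_unit"]
                                          * np.sqrt(fits["s2"]))
        np.testing.assert_allclose(table["mod_t"], ordinary_t, rtol=1e-12)
        assert (table["df_total"] == fits["df_resid"]).all()

    def test_d0_infinite_pins_posterior_at_prior(self):
        fits = self._fits()
        table, _ = moderate_statistics(
            fits, ShrinkageParams(prior_df=np.inf, prior_variance=0.123))
        assert np.allclose(table["s2_post"], 0.123)

    def test_posterior_is_convex_combination(self):
        # brute-force recomputation of (d0 s0^2 + d s^2)/(d0 + d)
        fits = self._fits(n_probes=10, seed=5)
        table, prior = moderate_statistics(fits)
        d0, s0 = prior.prior_df, prior.prior_variance
        for probe in fits.index:
            d = fits.loc[probe, "df_resid"]
            s2 = max(fits.loc[probe, "s2"], 1e-12)
            expected = (d0 * s0 + d * s2) / (d0 + d) if np.isfinite(d0) else s0
            assert table.loc[probe, "s2_post"] == pytest.approx(expected,
                                                                rel=1e-9)

    def test_posterior_bounded_by_sample_and_prior(self):
        fits = self._fits(n_probes=200, seed=8)
        table, prior = moderate_statistics(fits)
        s2 = np.maximum(fits["s2"].to_numpy(), 1e-12)
        lo = np.minimum(s2, prior.prior_variance) - 1e-15
        hi = np.maximum(s2, prior.prior_variance) + 1e-15
        assert ((table["s2_post"] >= lo) & (table["s2_post"] <= hi)).all()

    def test_prior_recovers_known_inverse_chisquare(self):
        # variances drawn from the model: d0=8, s0^2=0.09, d=21
        rng = np.random.default_rng(17)
        d0, s0_sq, d, n = 8.0, 0.09, 21, 20_000
        sigma2 = d0 * s0_sq / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        prior = estimate_prior(s2, np.full(n, float(d)))
        assert prior.prior_df == pytest.approx(d0, rel=0.15)
        assert prior.prior_variance == pytest.approx(s0_sq, rel=0.05)

    def test_all_zero_variances_degenerate(self):
        cov = _cov()
        m = pd.DataFrame(0.0, index=["p1", "p2"], columns=cov.index)
        fits = fit_probe_models(m, cov)
        with pytest.raises(ValueError, match="zero"):
            estimate_prior(fits["s2"].to_numpy(), fits["df_resid"].to_numpy())

    def test_agrees_with_limma_oracle(self, tmp_path):
        # independent cross-check of moderated t against the R reference
        rng = np.random.default_rng(23)
        cov = _cov(20, seed=23)
        m = pd.DataFrame(
            rng.normal(0, rng.uniform(0.2, 0.5, (60, 1)), (60, 20)),
            index=[f"p{i}" for i in range(60)], columns=cov.index)
        fits = fit_probe_models(m, cov)
        table, prior = moderate_statistics(fits)

        m.to_csv(tmp_path / "m.csv")
        cov.to_csv(tmp_path / "cov.csv")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            m <- as.matrix(read.csv(file.path(d, "m.csv"), row.names=1))
            cov <- read.csv(file.path(d, "cov.csv"), row.names=1)
            design <- model.matrix(~ age + bmi + patient, cov)
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(t=fit$t[,"age"], p=fit$p.value[,"age"],
                              d0=fit$df.prior, s02=fit$s2.prior)
            write.csv(out, file.path(d, "limma.csv"))
        """)
        subprocess.run(
            ["Rscript", "-e", f'd <- "{tmp_path}"; {script}'],
            check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        assert prior.prior_df == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert prior.prior_variance == pytest.approx(ref["s02"].iloc[0],
                                                     rel=1e-4)
        np.testing.assert_allclose(table["mod_t"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(table["p_raw"], ref["p"], rtol=1e-6)


class TestAdjustFdr:
    def test_hand_executed_step_up(self):
        # step-up: p_(i) * n / i, cummin from the largest rank
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_matches_manual_step_up_on_random_input(self, rng):
        p = rng.uniform(0, 1, 100)
        order = np.argsort(p)
        n = len(p)
        manual = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * n / rank)
            manual[idx] = running
        np.testing.assert_allclose(adjust_fdr(p), manual, rtol=1e-12)

    def test_permutation_equivariant(self, rng):
        p = rng.uniform(0, 1, 50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(adjust_fdr(p)[perm], adjust_fdr(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


class TestGlobalTests:
    def test_perfect_correlation(self):
        cov = _cov(10, seed=1)
        # global mean strictly increasing with age
        beta = pd.DataFrame([0.3 + 0.01 * (cov["age"] - 18)],
                            index=["p1"], columns=cov.index)
        res = global_methylation_tests(beta, cov)
        assert res.loc["all", "pearson_r"] == pytest.approx(1.0)

    def test_constant_global_mean_flagged_not_nan_propagated(self):
        cov = _cov(10, seed=1)
        beta = pd.DataFrame(0.5, index=["p1", "p2"], columns=cov.index)
        res = global_methylation_tests(beta, cov)
        assert bool(res.loc["all", "undefined"])

    def test_identical_groups_u_test_not_significant(self):
        cov = _cov(10, seed=2)
        cov["patient"] = [0, 1] * 5
        vals = np.tile(np.linspace(0.4, 0.6, 5), 2)  # same values per group
        beta = pd.DataFrame([vals], index=["p1"],
                            columns=cov.index)
        res = global_methylation_tests(beta, cov)
        assert res.loc["all", "u_p_patient"] > 0.9

    def test_null_generator_type_one_error(self):
        # no planted age effects: the age correlation should reject at the
        # nominal 5% rate; 11 is the one-sided 99.8% binomial bound for
        # 100 draws at p = 0.05
        hits = 0
        for seed in range(100):
            cfg = GeneratorConfig(n_subjects=63, n_probes=150,
                                  effect_fraction=0.0, seed=seed)
            cov = make_covariates(config=cfg)
            ann, _ = make_annotation(config=cfg)
            beta, _ = make_beta_matrix(ann, cov, cfg)
            res = global_methylation_tests(beta, cov)
            if res.loc["all", "pearson_p"] < 0.05:
                hits += 1
        assert hits <= 11


@pytest.fixture(scope="module")
def dataset():
    cfg = GeneratorConfig(n_subjects=63, n_probes=800,
                          effect_fraction=0.08, effect_size_mean=0.08,
                          snp_rate=0.0, seed=31)
    cov = make_covariates(config=cfg)
    ann, icrs = make_annotation(config=cfg)
    beta, truth = make_beta_matrix(ann, cov, cfg)
    ds = Dataset(beta=beta, covariates=cov, annotation=ann, icrs=icrs)
    table, _ = run_ewas(beta_to_m(beta), cov)
    return ds, truth, table


class TestSensitivity:
    def test_drop_snp_probes_is_identity_without_flags(self, dataset):
        ds, _, table = dataset
        res = sensitivity_rerun(ds, "drop_snp_probes", table)
        pd.testing.assert_frame_equal(res["table"], table)
        assert res["sign_agreement"] == 1.0

    def test_drop_patients_keeps_planted_slope_signs(self, dataset):
        ds, truth, table = dataset
        res = sensitivity_rerun(ds, "drop_patients", table)
        assert res["n_subjects"] == (ds.covariates["patient"] == 0).sum()
        planted = truth.index[truth["planted"]]
        a = np.sign(res["table"].loc[planted, "slope_age"])
        b = np.sign(truth.loc[planted, "true_delta_m_per_year"])
        assert (a == b).mean() >= 0.95

    def test_add_sperm_quality_covariate(self, dataset):
        ds, _, table = dataset
        res = sensitivity_rerun(ds, "add_sperm_quality", table)
        assert res["rank_correlation"] > 0.95

    def test_unknown_scenario(self, dataset):
        ds, _, _ = dataset
        with pytest.raises(ValueError, match="scenario"):
            sensitivity_rerun(ds, "drop_everything")

    def test_infeasible_scenario(self):
        cfg = GeneratorConfig(n_subjects=6, n_probes=30, seed=3,
                              patient_rate=0.5)
        cov = make_covariates(config=cfg)
        cov["patient"] = [1, 1, 1, 0, 0, 0]
        ann, _ = make_annotation(config=cfg)
        beta, _ = make_beta_matrix(ann, cov, cfg)
        ds = Dataset(beta=beta, covariates=cov, annotation=ann)
        with pytest.raises(ValueError, match="too few"):
            sensitivity_rerun(ds, "drop_patients")
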