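import json
import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

from wml_stager import phantom
from wml_stager import longitudinal_stats as ls
from wml_stager.longitudinal_stats import (
    ModelSpec,
    build_design,
    fit_and_test,
    fit_unstructured_covariance,
    log_transform_volume,
    reml_fit,
    run_model_grid,
)
from wml_stager.longitudinal_stats import test_effects as compute_effect_tests


def cohort(n=80, seed=0, **kw):
    cfg = phantom.CognitionSimConfig(n_subjects=n, rng_seed=seed, **kw)
    return phantom.simulate_cognition_cohort(cfg)


SPEC = ModelSpec(outcome="latent_executive", predictor="lesion_volume_cm3")


def quiet_fit(df, spec=SPEC, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_and_test(df, spec, **kw)


class TestLogTransform:
    def test_zero_volume_uses_epsilon_floor(self):
        assert log_transform_volume(0.0, 0.024) == pytest.approx(np.log(0.024))

    def test_strictly_increasing(self):
        v = np.linspace(0, 50, 200)
        out = log_transform_volume(v)
        assert np.all(np.diff(out) > 0)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            log_transform_volume(-1.0)


class TestDesign:
    def test_sum_to_zero_time_coding(self):
        df = cohort(20, seed=1, dropout_rate_last_visit=0.0)
        X, y, subj, t, names = build_design(df, SPEC)
        for k in range(3):
            col = X[:, names.index(f"time_s{k}")]
            # each contrast sums to zero over one subject's four visits
            assert np.allclose(col.reshape(-1, 4).sum(axis=1), 0.0)

    def test_missing_column_reported(self):
        df = cohort(15, seed=2).drop(columns=["education"])
        with pytest.raises(ValueError, match="education"):
            build_design(df, SPEC)

    def test_constant_predictor_is_singular(self):
        df = cohort(15, seed=3)
        df["lesion_volume_cm3"] = 5.0
        with pytest.raises(ValueError, match="singular"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reml_fit(df, SPEC)

    def test_duplicated_vflair_predictor_is_singular(self):
        df = cohort(15, seed=4)
        df["V_FLAIR"] = df["lesion_volume_cm3"]
        spec = ModelSpec(outcome="latent_executive",
                         predictor="lesion_volume_cm3", adjust_vflair=True)
        with pytest.raises(ValueError, match="singular"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reml_fit(df, spec)


class TestREMLFit:
    def test_noiseless_data_recovers_coefficients_exactly(self):
        df = cohort(30, seed=5, residual_cov=1e-14 * np.eye(4),
                    subtest_noise_sd=0.0, dropout_rate_last_visit=0.0,
                    effect_main=-0.2, effect_interaction=-0.05,
                    beta_age=-0.03, beta_sex=0.1, beta_education=0.02)
        # epsilon floor set to zero so log(V + eps) matches the generator exactly
        spec = ModelSpec(outcome="latent_executive",
                         predictor="lesion_volume_cm3", epsilon_log=0.0)
        res = quiet_fit(df, spec)
        est = dict(zip(res.column_names, res.beta))
        # exact interpolation: GLS reproduces the generating coefficients
        assert est["age"] == pytest.approx(-0.03, abs=1e-6)
        assert est["education"] == pytest.approx(0.02, abs=1e-6)
        assert est["sex_male"] == pytest.approx(-0.1, abs=1e-6)
        # per-year volume effects equal effect_main + effect_interaction * t
        for _, row in res.per_year.iterrows():
            expected = -0.2 + -0.05 * row["year"]
            assert row["estimate"] == pytest.approx(expected, abs=1e-4)

    def test_balanced_saturated_reml_equals_sample_covariance(self, rng):
        Sig = phantom._default_residual_cov()
        Y = np.array([0.5, 0.2, -0.1, -0.4]) + rng.multivariate_normal(
            np.zeros(4), Sig, size=50
        )
        S_hat = fit_unstructured_covariance(Y)
        S_sample = np.cov(Y.T, ddof=1)
        assert np.max(np.abs(S_hat - S_sample)) < 1e-6

    def test_scaled_identity_limit_reproduces_ols(self):
        df = cohort(40, seed=6, dropout_rate_last_visit=0.0)
        res = quiet_fit(df, structure="scaled_identity")
        X, y, *_ = build_design(df, SPEC)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(res.beta - beta_ols)) < 1e-8

    def test_estimated_covariance_converges_to_truth(self):
        Sig = phantom._default_residual_cov()
        df = cohort(500, seed=7, dropout_rate_last_visit=0.0)
        res = quiet_fit(df)
        rel = np.abs(res.sigma_hat - Sig) / np.abs(Sig)
        assert np.max(rel) < 0.15

    def test_reml_criterion_is_locally_optimal(self):
        df = cohort(60, seed=8)
        res = quiet_fit(df)
        X, y, subj, t, _ = build_design(df, SPEC)
        packed, _ = ls._pack_patterns(X, y, subj, t)
        p = X.shape[1]
        f_opt, _ = ls._neg2_reml(res.theta, packed, p, len(y), 4, "unstructured")
        rng = np.random.default_rng(0)
        for _ in range(20):
            pert = res.theta + rng.normal(0, 0.05, size=res.theta.size)
            try:
                f_pert, _ = ls._neg2_reml(pert, packed, p, len(y), 4, "unstructured")
            except np.linalg.LinAlgError:
                continue
            assert f_pert >= f_opt - 1e-8

    def test_sigma_hat_is_symmetric_positive_definite(self):
        res = quiet_fit(cohort(50, seed=9))
        S = res.sigma_hat
        assert np.allclose(S, S.T)
        assert np.min(np.linalg.eigvalsh(S)) > 0


class TestInference:
    def test_per_year_estimates_average_to_main_effect(self):
        res = quiet_fit(cohort(60, seed=10))
        avg = res.per_year["estimate"].mean()
        assert avg == pytest.approx(
            res.beta[res.column_index["log_volume"]], abs=1e-10
        )

    def test_interaction_test_has_three_numerator_df(self):
        res = quiet_fit(cohort(60, seed=11))
        assert res.tests["volume_by_time"]["num_df"] == 3

    def test_per_year_for_unobserved_year_raises(self):
        # a wholly unobserved visit level collapses the factor coding
        df = cohort(40, seed=12)
        with pytest.raises(ValueError, match="singular"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reml_fit(df[df.visit_year < 3], SPEC)
        # and the per-year guard refuses years outside the observed set
        res = quiet_fit(df)
        res.observed_years = (0, 1, 2)
        with pytest.raises(ValueError, match="year 3"):
            compute_effect_tests(res)

    def test_declining_effect_orders_per_year_estimates(self):
        df = cohort(600, seed=13, effect_main=-0.1, effect_interaction=-0.08,
                    dropout_rate_last_visit=0.0)
        res = quiet_fit(df)
        est = res.per_year["estimate"].to_numpy()
        assert np.all(np.diff(est) < 0)

    def test_residual_ddf_fallback(self):
        spec = ModelSpec(outcome="latent_executive",
                         predictor="lesion_volume_cm3", ddf_method="residual")
        res = quiet_fit(cohort(40, seed=14), spec)
        expected = res.n_observations - len(res.beta)
        assert res.tests["volume_by_time"]["den_df"] == pytest.approx(expected)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
class TestAgainstGLSOracle:
    def test_matches_nlme_gls_fixed_effects_and_covariance(self, tmp_path):
        df = cohort(40, seed=42)
        res = quiet_fit(df)
        X, y, subj, t, names = build_design(df, SPEC)
        fix = pd.DataFrame(X, columns=names)
        fix["y"] = y
        fix["subject"] = subj
        fix["tindex"] = t + 1
        fix.to_csv(tmp_path / "fixture.csv", index=False)
        rscript = tmp_path / "check.R"
        rscript.write_text(
            'suppressMessages(library(nlme))\n'
            f'd <- read.csv("{tmp_path}/fixture.csv")\n'
            'd$subject <- factor(d$subject)\n'
            'preds <- setdiff(names(d), c("y","subject","tindex","intercept"))\n'
            'f <- as.formula(paste("y ~", paste(preds, collapse=" + ")))\n'
            'fit <- gls(f, data=d, correlation=corSymm(form=~tindex|subject),\n'
            '           weights=varIdent(form=~1|tindex), method="REML",\n'
            '           control=glsControl(maxIter=200, msMaxIter=200, tolerance=1e-8))\n'
            'out <- list(beta=as.numeric(coef(fit)),\n'
            '            sigma=as.numeric(getVarCov(fit)))\n'
            f'writeLines(jsonlite::toJSON(out, digits=12), "{tmp_path}/out.json")\n'
        )
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        out = json.loads((tmp_path / "out.json").read_text())
        r_beta = np.asarray(out["beta"], dtype=float)
        r_sigma = np.asarray(out["sigma"], dtype=float).reshape(4, 4)
        assert np.max(np.abs(res.beta - r_beta)) < 1e-3
        assert np.max(np.abs(res.sigma_hat - r_sigma)) < 1e-3


class TestModelGrid:
    def test_grid_shape_and_failure_recording(self):
        df = cohort(60, seed=15)
        # provide the staged volume columns the grid expects
        rng = np.random.default_rng(0)
        base = df.drop_duplicates("subject_id")[["subject_id"]]
        for col in ("V_DC33", "V_DC66", "V_DC100", "V_FLAIR"):
            base[col] = phantom.sample_lesion_volumes(len(base), rng)
        df = df.merge(base, on="subject_id")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = run_model_grid(
                df,
                outcomes=("latent_executive", "latent_memory"),
                predictors=("V_DC33", "V_DC66"),
            )
        assert len(grid) == 2 * 2 * 2
        assert grid["error"].eq("").all()
        assert grid["converged"].all()
        for col in ("main_p", "interaction_p", "year0_p", "year3_p"):
            assert grid[col].between(0, 1).all()

    def test_failed_cell_recorded_and_grid_continues(self):
        df = cohort(40, seed=16)
        df["V_CONST"] = 3.0
        rng = np.random.default_rng(1)
        base = df.drop_duplicates("subject_id")[["subject_id"]]
        base["V_OK"] = phantom.sample_lesion_volumes(len(base), rng)
        df = df.merge(base, on="subject_id")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = run_model_grid(
                df, predictors=("V_CONST", "V_OK"),
                outcomes=("latent_executive",), adjust_vflair=(False,),
            )
        assert len(grid) == 2
        bad = grid[grid.predictor == "V_CONST"].iloc[0]
        good = grid[grid.predictor == "V_OK"].iloc[0]
        assert "singular" in bad["error"]
        assert good["error"] == ""
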