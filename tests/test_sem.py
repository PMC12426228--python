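import numpy as np
import pandas as pd
import pytest

from conftest import latent_cohort_frame

from exposome.scoring import DIMENSIONS
from exposome.sem import (
    SEMSpec,
    bootstrap_sem,
    compute_fit_indices,
    extract_factor_scores,
    fit_sem,
    fit_sem_ml,
    modification_index,
    top_modification_index,
)

SPEC = SEMSpec()


class TestSpecValidation:
    def test_fixed_indicator_must_be_indicator(self):
        with pytest.raises(ValueError, match="fixed indicator"):
            SEMSpec(fixed_indicator="cognition")

    def test_freed_pair_must_be_observed(self):
        with pytest.raises(ValueError, match="not observed"):
            SEMSpec(freed_residual_covariances=(("education", "nope"),))

    def test_freed_pair_must_be_distinct(self):
        with pytest.raises(ValueError, match="distinct"):
            SEMSpec(freed_residual_covariances=(("education", "education"),))


class TestFitSemMl:
    def test_just_identified_gives_zero_discrepancy(self):
        # three indicators, no outcomes: q = p(p+1)/2, F_ML = 0, chi2 = 0
        spec = SEMSpec(
            indicators=("education", "food_insecurity", "access_healthcare"),
            outcomes=(),
        )
        frame, _ = latent_cohort_frame(300, seed=1)
        S = frame[list(spec.observed)].cov().to_numpy()
        fit = fit_sem_ml(S, 300, spec)
        assert fit.df == 0
        assert fit.fml == pytest.approx(0.0, abs=1e-8)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-5)
        np.testing.assert_allclose(fit.sigma, S, atol=1e-6)

    def test_parameter_recovery_single_run(self, medium_cohort):
        frame, _ = medium_cohort
        fit = fit_sem(frame, SPEC)
        assert fit.converged and not fit.heywood
        np.testing.assert_allclose(fit.loadings().to_numpy(), 0.7, atol=0.05)
        np.testing.assert_allclose(fit.paths().to_numpy(), 0.3, atol=0.05)

    def test_oracle_equivalence_subset(self, sem_oracle_records):
        for rec in sem_oracle_records[:3]:
            S = np.array(rec["cov"])
            fit = fit_sem_ml(S, rec["n"], SPEC)
            lav = rec["lavaan"]
            assert fit.df == lav["df"]
            assert fit.chi2 == pytest.approx(lav["chi2"], abs=1e-2)
            for name in SPEC.indicators:
                if name == SPEC.fixed_indicator:
                    continue
                assert fit.estimate(f"{name}~MSE") == pytest.approx(
                    lav["params"][f"MSE=~{name}"], abs=1e-3
                )
            for name in SPEC.outcomes:
                assert fit.estimate(f"{name}~MSE") == pytest.approx(
                    lav["params"][f"{name}~MSE"], abs=1e-3
                )

    def test_rejects_non_pd_covariance(self):
        S = np.zeros((13, 13))
        with pytest.raises(ValueError, match="positive definite"):
            fit_sem_ml(S, 100, SPEC)

    def test_rejects_small_n(self):
        frame, _ = latent_cohort_frame(300, seed=2)
        S = frame[list(SPEC.observed)].cov().to_numpy()
        with pytest.raises(ValueError, match="n must exceed"):
            fit_sem_ml(S, 10, SPEC)

    def test_chi2_invariant_to_fixed_indicator(self):
        frame, _ = latent_cohort_frame(800, seed=3)
        fit_a = fit_sem(frame, SEMSpec(fixed_indicator="access_healthcare"), compute_se=False)
        fit_b = fit_sem(frame, SEMSpec(fixed_indicator="education"), compute_se=False)
        assert fit_a.chi2 == pytest.approx(fit_b.chi2, abs=1e-4)

    def test_fml_nonnegative_and_zero_iff_saturated(self):
        frame, _ = latent_cohort_frame(500, seed=4)
        fit = fit_sem(frame, SPEC, compute_se=False)
        assert fit.fml >= 0
        assert not np.allclose(fit.sigma, fit.sample_cov, atol=1e-10)

    def test_heywood_flagged_not_clipped(self):
        # two strongly collinear indicators push one residual negative
        rng = np.random.default_rng(5)
        n = 300
        lat = rng.normal(size=n)
        frame, _ = latent_cohort_frame(n, seed=5)
        frame["education"] = 0.95 * lat + 0.05 * rng.normal(size=n)
        frame["assets"] = 0.97 * lat + 0.04 * rng.normal(size=n)
        fit = fit_sem(frame, SPEC, compute_se=False)
        if fit.heywood:  # depends on draw; bounded refit must clear it
            bounded = fit_sem(frame, SPEC, bound_residuals=True, compute_se=False)
            assert not bounded.heywood


class TestFitIndices:
    def test_stated_arithmetic(self):
        idx = compute_fit_indices(100.0, 60, 1000.0, 78, 1001)
        assert idx.cfi == pytest.approx(1 - 40 / 922, abs=1e-12)
        assert idx.rmsea == pytest.approx(np.sqrt(40 / 60000), abs=1e-12)
        expected_tli = ((1000 / 78) - (100 / 60)) / ((1000 / 78) - 1)
        assert idx.tli == pytest.approx(expected_tli, abs=1e-12)

    def test_perfect_model(self):
        idx = compute_fit_indices(60.0, 60, 1000.0, 78, 500)
        assert idx.cfi == 1.0
        assert idx.rmsea == 0.0

    def test_srmr_zero_when_sigma_equals_s(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(5, 5))
        S = A @ A.T + 5 * np.eye(5)
        idx = compute_fit_indices(10.0, 5, 100.0, 10, 200, S=S, sigma=S.copy())
        assert idx.srmr == pytest.approx(0.0, abs=1e-14)

    def test_degenerate_baseline_flags_tli(self):
        idx = compute_fit_indices(10.0, 5, 7.0, 10, 200)
        assert not idx.tli_defined
        assert idx.tli is None

    def test_matches_external_oracle(self, sem_oracle_records):
        rec = sem_oracle_records[0]
        fit = fit_sem_ml(np.array(rec["cov"]), rec["n"], SPEC)
        lav = rec["lavaan"]
        assert fit.indices.cfi == pytest.approx(lav["cfi"], abs=1e-6)
        assert fit.indices.tli == pytest.approx(lav["tli"], abs=1e-6)
        assert fit.indices.rmsea == pytest.approx(lav["rmsea"], abs=1e-6)
        assert fit.indices.srmr == pytest.approx(lav["srmr"], abs=1e-6)


class TestStandardizedSolution:
    def test_standardization_recovers_generating_values(self):
        # the generating model is standardized (unit variances); the
        # standardized solution must recover its loadings and paths even
        # though fixed-indicator identification rescales the raw estimates
        frame, _ = latent_cohort_frame(3000, seed=7)
        fit = fit_sem(frame, SPEC, compute_se=False)
        np.testing.assert_allclose(fit.loadings().to_numpy(), 0.7, atol=0.05)
        np.testing.assert_allclose(fit.paths().to_numpy(), 0.3, atol=0.05)
        # raw estimates are on the fixed-indicator scale instead
        raw = fit.params.loc[fit.params["kind"] == "loading", "estimate"]
        np.testing.assert_allclose(raw, 1.0, atol=0.1)

    def test_scale_equivariance(self):
        frame, _ = latent_cohort_frame(1500, seed=8)
        fit = fit_sem(frame, SPEC, compute_se=False)
        rescaled = frame.copy()
        rescaled["education"] = rescaled["education"] * 2.0
        fit2 = fit_sem(rescaled, SPEC, compute_se=False)
        assert fit.standardized("education~MSE") == pytest.approx(
            fit2.standardized("education~MSE"), abs=1e-4
        )

    def test_equal_loading_symmetry(self):
        # population covariance of an equal-loading model: all standardized
        # loadings recovered equal
        p_ind = len(SPEC.indicators)
        lam = 0.6
        S = np.full((13, 13), 0.0)
        for i in range(13):
            S[i, i] = 1.0
        load = np.array([lam] * p_ind + [0.25] * 3)
        S = np.outer(load, load)
        np.fill_diagonal(S, 1.0)
        fit = fit_sem_ml(S, 5000, SPEC, compute_se=False)
        stds = fit.loadings().to_numpy()
        np.testing.assert_allclose(stds, stds[0], atol=1e-4)
        np.testing.assert_allclose(stds[0], lam, atol=1e-4)


class TestFactorScores:
    def test_near_deterministic_indicator(self):
        rng = np.random.default_rng(9)
        n = 400
        lat = rng.normal(size=n)
        frame = pd.DataFrame(
            {
                "education": lat + 0.01 * rng.normal(size=n),
                "food_insecurity": lat + 0.01 * rng.normal(size=n),
                "access_healthcare": lat + 0.01 * rng.normal(size=n),
            }
        )
        spec = SEMSpec(
            indicators=("education", "food_insecurity", "access_healthcare"), outcomes=()
        )
        fit = fit_sem(frame, spec, bound_residuals=True, compute_se=False)
        scores = extract_factor_scores(frame, fit)
        centered = frame["education"] - frame["education"].mean()
        np.testing.assert_allclose(scores, centered, atol=0.05)

    def test_recovery_correlation(self, medium_cohort):
        frame, lat = medium_cohort
        fit = fit_sem(frame, SPEC, compute_se=False)
        scores = extract_factor_scores(frame, fit)
        assert np.corrcoef(scores, lat)[0, 1] >= 0.9

    def test_regression_vs_bartlett_agreement(self, medium_cohort):
        frame, _ = medium_cohort
        fit = fit_sem(frame, SPEC, compute_se=False)
        reg = extract_factor_scores(frame, fit, "regression")
        bart = extract_factor_scores(frame, fit, "bartlett")
        assert np.corrcoef(reg, bart)[0, 1] > 0.99

    def test_affine_invariance_up_to_affine_map(self):
        frame, _ = latent_cohort_frame(600, seed=10)
        fit = fit_sem(frame, SPEC, compute_se=False)
        scores = extract_factor_scores(frame, fit)
        shifted = frame * 3.0 + 1.0
        fit2 = fit_sem(shifted, SPEC, compute_se=False)
        scores2 = extract_factor_scores(shifted, fit2)
        assert abs(np.corrcoef(scores, scores2)[0, 1]) > 1 - 1e-9

    def test_missing_data_rejected(self, medium_cohort):
        frame, _ = medium_cohort
        fit = fit_sem(frame, SPEC, compute_se=False)
        holed = frame.copy()
        holed.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            extract_factor_scores(holed, fit)


class TestModificationIndex:
    def test_detects_omitted_residual_covariance(self):
        hits = 0
        for r in range(5):
            n = 2000
            frame, _ = latent_cohort_frame(n, seed=20 + r)
            extra = np.random.default_rng(2000 + r).normal(size=n)
            frame["childhood_labor"] = frame["childhood_labor"] + 0.5 * extra
            frame["relations"] = frame["relations"] + 0.5 * extra
            fit = fit_sem(frame, SPEC, compute_se=False)
            pair, mi = top_modification_index(fit)
            if frozenset(pair) == frozenset(("childhood_labor", "relations")):
                hits += 1
        assert hits >= 4

    def test_null_calibration(self):
        below = 0
        n_rep = 10
        for r in range(n_rep):
            frame, _ = latent_cohort_frame(1000, seed=40 + r)
            fit = fit_sem(frame, SPEC, compute_se=False)
            mi = modification_index(fit, "S", "education", "food_insecurity")
            assert mi >= 0
            if mi < 3.841:
                below += 1
        assert below >= 9  # ~chi2(1) under the true model

    def test_freeing_top_parameter_drops_chi2(self):
        frame, _ = latent_cohort_frame(1000, seed=50)
        rng = np.random.default_rng(50)
        extra = rng.normal(size=len(frame))
        frame["education"] += 0.4 * extra
        frame["assets"] += 0.4 * extra
        fit = fit_sem(frame, SPEC, compute_se=False)
        pair, mi = top_modification_index(fit)
        freed = fit_sem(
            frame, SEMSpec(freed_residual_covariances=(tuple(pair),)), compute_se=False
        )
        assert fit.chi2 - freed.chi2 >= 0
        assert mi >= 0

    def test_already_free_parameter_rejected(self):
        frame, _ = latent_cohort_frame(500, seed=60)
        spec = SEMSpec(freed_residual_covariances=(("education", "assets"),))
        fit = fit_sem(frame, spec, compute_se=False)
        with pytest.raises(ValueError, match="already free"):
            modification_index(fit, "S", "education", "assets")


class TestBootstrap:
    def test_deterministic_under_seed(self):
        frame, _ = latent_cohort_frame(300, seed=70)
        a = bootstrap_sem(frame, SPEC, B=2, seed=5)
        b = bootstrap_sem(frame, SPEC, B=2, seed=5)
        pd.testing.assert_frame_equal(a.paths, b.paths)

    def test_null_path_ci_covers_zero(self):
        covered = 0
        n_rep = 8
        for r in range(n_rep):
            frame, _ = latent_cohort_frame(
                500, paths={"cognition": 0.0, "functional_ability": 0.0, "neuropsychiatric": 0.0},
                seed=80 + r,
            )
            boot = bootstrap_sem(frame, SPEC, B=60, seed=r)
            lo, hi = boot.percentile_ci("cognition")
            if lo <= 0 <= hi:
                covered += 1
        assert covered >= 6

    def test_bootstrap_mean_consistency(self, medium_cohort):
        frame, _ = medium_cohort
        full = fit_sem(frame, SPEC, compute_se=False)
        boot = bootstrap_sem(frame, SPEC, B=200, seed=9)
        for out in SPEC.outcomes:
            assert boot.paths[out].mean() == pytest.approx(
                full.paths()[out], abs=0.03
            )

    def test_b_must_be_at_least_two(self):
        frame, _ = latent_cohort_frame(200, seed=90)
        with pytest.raises(ValueError):
            bootstrap_sem(frame, SPEC, B=1)


class TestCovariateModel:
    def test_sensitivity_covariates_recovered(self):
        rng = np.random.default_rng(100)
        n = 2000
        age = rng.normal(size=n)
        sex = (rng.random(n) < 0.6).astype(float)
        lat = 0.4 * age + np.sqrt(1 - 0.16) * rng.normal(size=n)
        cols = {d: 0.7 * lat + 0.71 * rng.normal(size=n) for d in DIMENSIONS}
        cols["cognition"] = 0.3 * lat - 0.2 * age + 0.9 * rng.normal(size=n)
        cols["functional_ability"] = 0.1 * lat + rng.normal(size=n)
        cols["neuropsychiatric"] = 0.1 * lat + rng.normal(size=n)
        cols["age"], cols["sex"] = age, sex
        frame = pd.DataFrame(cols)
        spec = SEMSpec(covariates=("age", "sex"))
        fit = fit_sem(frame, spec, compute_se=False)
        assert fit.converged
        # standardized scale: the raw latent is on the fixed indicator's scale
        assert fit.standardized("MSE~age") == pytest.approx(0.4, abs=0.07)
        assert fit.standardized("cognition~age") == pytest.approx(-0.21, abs=0.07)
        assert fit.standardized("MSE~sex") == pytest.approx(0.0, abs=0.07)
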