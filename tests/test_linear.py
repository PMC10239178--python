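"""Design building, OLS against oracles, residualisation, VIF."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm_api

from smokemed import ModelSpec, build_design, compute_vif, fit_ols, residualize_on_age
from smokemed.linear import default_covariates
from smokemed.exceptions import (
    CollinearityError,
    ConfigurationError,
    DegenerateInputError,
    InsufficientDataError,
)

from conftest import make_mini_cohort


class TestBuildDesign:
    def test_dummy_coding_against_nonsmoker_reference(self):
        cohort = make_mini_cohort(["non", "former", "current"] * 2)
        spec = ModelSpec(exposures=("FS", "CS"), mediator="grim_eaa",
                         covariates=())
        X, y = build_design(cohort, spec)
        assert list(X["FS"]) == [0, 1, 0, 0, 1, 0]
        assert list(X["CS"]) == [0, 0, 1, 0, 0, 1]
        assert (X["intercept"] == 1).all()

    def test_cessation_model_subsets_former_with_packyears_covariate(self):
        cohort = make_mini_cohort(["non", "former", "current"] * 8)
        spec = ModelSpec(exposures=("YSC",), mediator="grim_eaa",
                         covariates=("age", "FPY"), subset="former")
        X, y = build_design(cohort, spec)
        assert len(X) == 8
        assert "FPY" in X.columns
        with pytest.raises(ConfigurationError):
            ModelSpec(exposures=("YSC",), mediator="grim_eaa",
                      covariates=("age", "FPY"), subset="all")
        with pytest.raises(ConfigurationError):
            ModelSpec(exposures=("YSC",), mediator="grim_eaa",
                      covariates=("age",), subset="former")

    def test_listwise_deletion_is_per_model(self):
        cohort = make_mini_cohort(["non"] * 10 + ["former"] * 5 + ["current"] * 5)
        cohort.loc[[0, 1], ["fev1", "fvc"]] = np.nan
        med_spec = ModelSpec(exposures=("FS", "CS"), mediator="grim_eaa",
                             covariates=("age",))
        out_spec = ModelSpec(exposures=("FS", "CS"), mediator="grim_eaa",
                             outcome="fev1", covariates=("age",))
        Xm, _ = build_design(cohort, med_spec)
        Xo, _ = build_design(cohort, out_spec)
        assert len(Xm) == 20 and len(Xo) == 18  # rows kept in the mediator model

    def test_insufficient_rows_raise(self):
        cohort = make_mini_cohort(["non", "former", "current"])
        spec = ModelSpec(exposures=("FS", "CS"), mediator="grim_eaa",
                         covariates=())
        with pytest.raises(InsufficientDataError):
            build_design(cohort, spec)

    def test_male_subset_drops_sex_covariate(self):
        assert "sex_male" not in default_covariates(subset="male")
        assert "FPY" in default_covariates(family="cessation")


class TestFitOLS:
    def test_exact_line(self):
        x = np.arange(5.0)
        X = np.column_stack([np.ones(5), x])
        fit = fit_ols(X, 2 * x + 1)
        assert np.allclose(fit.coef, [1.0, 2.0], atol=1e-12)
        assert np.allclose(fit.residuals, 0, atol=1e-12)

    def test_matches_normal_equations_and_statsmodels(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = rng.normal(size=20)
        fit = fit_ols(X, y)
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coef, beta_ne, atol=1e-8)
        ref = sm_api.OLS(y, X).fit()
        assert np.allclose(fit.coef, ref.params, atol=1e-10)
        assert np.allclose(fit.se, ref.bse, atol=1e-10)
        assert np.allclose(fit.pvalues, ref.pvalues, atol=1e-10)
        assert fit.r_squared == pytest.approx(ref.rsquared, abs=1e-10)

    def test_residuals_orthogonal_to_design(self, cohort_small):
        spec = ModelSpec(exposures=("FS", "CS"), mediator="grim_eaa")
        X, y = build_design(cohort_small, spec)
        fit = fit_ols(X, y)
        dots = X.to_numpy().T @ fit.residuals
        scale = np.abs(X.to_numpy()).sum(axis=0) * np.abs(fit.residuals).max()
        assert (np.abs(dots) <= 1e-6 * np.maximum(scale, 1)).all()

    def test_rank_deficiency_names_column(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"intercept": np.ones(30),
                          "a": rng.normal(size=30)})
        X["b"] = 2 * X["a"]
        with pytest.raises(CollinearityError, match="b"):
            fit_ols(X, rng.normal(size=30))

    def test_constant_shift_moves_only_intercept(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
        y = rng.normal(size=40)
        f0, f1 = fit_ols(X, y), fit_ols(X, y + 5.0)
        assert f1.coef[0] == pytest.approx(f0.coef[0] + 5.0, abs=1e-10)
        assert np.allclose(f1.coef[1:], f0.coef[1:], atol=1e-10)

    def test_frisch_waugh_partialling_out(self):
        rng = np.random.default_rng(8)
        n = 60
        Z = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        full = fit_ols(np.column_stack([Z, x]), y)
        rx = x - Z @ np.linalg.solve(Z.T @ Z, Z.T @ x)
        ry = y - Z @ np.linalg.solve(Z.T @ Z, Z.T @ y)
        partial = float(rx @ ry / (rx @ rx))
        assert full.coef[3] == pytest.approx(partial, abs=1e-10)


class TestResidualizeOnAge:
    def test_perfect_prediction_gives_zero_residuals(self):
        age = np.linspace(30, 70, 50)
        assert np.allclose(residualize_on_age(age, age), 0, atol=1e-10)
        # an additive offset is absorbed by the intercept
        assert np.allclose(residualize_on_age(age + 7.3, age), 0, atol=1e-10)

    def test_output_uncorrelated_with_age(self):
        rng = np.random.default_rng(9)
        age = rng.uniform(30, 70, 500)
        epi = age + rng.normal(0, 5, 500)
        eaa = residualize_on_age(epi, age)
        assert abs(np.corrcoef(eaa, age)[0, 1]) < 1e-10

    def test_constant_age_raises(self):
        with pytest.raises(DegenerateInputError):
            residualize_on_age([50.0, 51.0, 52.0], [40.0, 40.0, 40.0])


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        X = pd.DataFrame({
            "intercept": np.ones(4),
            "a": [1, -1, 1, -1],
            "b": [1, 1, -1, -1]})
        vif = compute_vif(X)
        assert np.allclose(vif, 1.0, atol=1e-10)

    def test_known_pairwise_correlation_closed_form(self):
        # exact sample correlation 0.8 by construction from orthonormal parts
        z1 = np.array([1.0, -1.0, 1.0, -1.0]) / 2
        z2 = np.array([1.0, 1.0, -1.0, -1.0]) / 2
        X = pd.DataFrame({"intercept": np.ones(4),
                          "x1": z1, "x2": 0.8 * z1 + 0.6 * z2})
        vif = compute_vif(X)
        assert vif["x1"] == pytest.approx(1 / (1 - 0.64), abs=1e-10)
        assert vif["x2"] == pytest.approx(1 / (1 - 0.64), abs=1e-10)

    def test_duplicated_column_raises(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=30)
        X = pd.DataFrame({"intercept": np.ones(30), "a": a, "dup": a,
                          "c": rng.normal(size=30)})
        with pytest.raises(CollinearityError):
            compute_vif(X)

    def test_model_grid_vifs_finite_on_synthetic_cohort(self, cohort_small):
        spec = ModelSpec(exposures=("FS", "CS"), mediator="grim_eaa",
                         outcome="fg")
        X, _ = build_design(cohort_small, spec)
        vif = compute_vif(X)
        assert np.isfinite(vif).all()
        assert (vif >= 1 - 1e-9).all()
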