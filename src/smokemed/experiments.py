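"""Designed simulation experiments: operating characteristics of the pipeline.

These are the calibration studies the package runs on its own generator:

* OLS / mediation-identity oracle gaps on random small problems,
* type-I error of the bootstrap mediation test under the complete null,
* coverage of the 95% bootstrap CI for the generator's true indirect effect,
* false-discovery fraction of the BH-controlled grid under an all-null grid.

The recovery and null experiments use *model-faithful* reduced truths: the
tested mediator loads only on the exposure terms its fitted model contains,
and the outcome loads only on the tested mediator.  The rich default
generator deliberately includes pack-year loadings and multiple mediator
pathways, which the single-mediator status-family model does not condition
on — exactly the mild misspecification real cohort data carry — so it is
the study condition, not the recovery benchmark.  See docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpec, run_grid
from .linear import fit_ols
from .mediation import MediationOptions, bootstrap_mediation
from .simulate import MediatorEquation, OutcomeEquation, SimTruth, generate_cohort, truth_acme


def _seed(base: int, k: int) -> int:
    return int(np.random.SeedSequence([int(base), int(k)]).generate_state(1)[0] % (2**31))


def null_truth(n: int, seed: int = 0) -> SimTruth:
    """Complete null for CS -> hannum_eaa -> fev1: both paths zero.

    The marker keeps its residual SD and covariate structure; lung exams are
    always observed so the nominal n is the analysis n.
    """
    t = SimTruth(n=n, seed=seed, lung_missing_rate=0.0)
    t.mediator_model["hannum_eaa"] = MediatorEquation(
        intercept=0.0, covariates={"bmi": 0.05}, resid_sd=4.0)
    # fev1 already has no hannum_eaa loading by default; make it exactly null
    # with respect to every mediator so the tested pair is a complete null.
    t.outcome_model["fev1"] = OutcomeEquation(
        intercept=4.4, covariates={"age": -0.030, "sex_male": 0.80, "bmi": -0.005},
        resid_sd=0.45, log_scale=False)
    return t


def recovery_truth(n: int, seed: int = 0) -> SimTruth:
    """Model-faithful truth for CS -> grim_eaa -> fvc recovery.

    grim_eaa keeps its status coefficients (current-smoking effect 5.650
    years) but no pack-year/cessation loadings; fvc loads only on grim_eaa
    (-0.025 SD-of-lung-function per year of age acceleration); covariate
    confounding is retained in both equations.
    """
    t = SimTruth(n=n, seed=seed, lung_missing_rate=0.0)
    t.mediator_model["grim_eaa"] = MediatorEquation(
        intercept=-1.9, fs=1.446, cs=5.650,
        covariates={"bmi": 0.06, "sex_male": 1.0, "drinking": 0.5}, resid_sd=3.0)
    t.outcome_model["fvc"] = OutcomeEquation(
        intercept=5.2, mediators={"grim_eaa": -0.025},
        covariates={"age": -0.030, "sex_male": 1.00, "bmi": -0.003},
        resid_sd=0.50, log_scale=False)
    return t


def all_null_grid_truth(n: int, seed: int = 0) -> SimTruth:
    """Truth whose hannum_eaa/ieaa -> fev1/fvc indirect effects are all zero
    (no mediator loads on either lung outcome)."""
    t = SimTruth(n=n, seed=seed, lung_missing_rate=0.0)
    for outcome in ("fev1", "fvc"):
        eq = t.outcome_model[outcome]
        eq.mediators = {}
    return t


def ols_oracle_max_gap(n_problems: int = 100, seed: int = 0) -> float:
    """Max |beta_QR - beta_normal-equations| over random small OLS problems."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_problems):
        n = int(rng.integers(20, 60))
        p = int(rng.integers(2, 6))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = rng.normal(size=n)
        fit = fit_ols(X, y)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        worst = max(worst, float(np.max(np.abs(fit.coef - beta_oracle))))
    return worst


def mediation_identity_max_gap(n_problems: int = 100, seed: int = 0) -> float:
    """Max |product-of-coefficients - difference-of-coefficients| over random
    single-mediator problems on identical samples (an exact OLS identity)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_problems):
        n = int(rng.integers(30, 80))
        x = rng.normal(size=n)
        c = rng.normal(size=n)
        m = 0.8 * x + 0.3 * c + rng.normal(size=n)
        y = 0.5 * x + 0.6 * m + 0.2 * c + rng.normal(size=n)
        ones = np.ones(n)
        med_fit = fit_ols(np.column_stack([ones, x, c]), m)
        out_fit = fit_ols(np.column_stack([ones, x, c, m]), y)
        est = med_fit.coef[1] * out_fit.coef[3]         # product of coefficients
        red_fit = fit_ols(np.column_stack([ones, x, c]), y)
        diff = red_fit.coef[1] - out_fit.coef[1]        # difference of coefficients
        worst = max(worst, abs(est - diff))
    return worst


def type_i_error_rate(n_sims: int = 500, n: int = 500, n_boot: int = 200,
                      seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate of the bootstrap mediation test under the complete null."""
    rejections = 0
    for k in range(n_sims):
        cohort = generate_cohort(null_truth(n, seed=_seed(seed, k)))
        res = bootstrap_mediation(
            cohort, ("FS", "CS"), "hannum_eaa", "fev1",
            MediationOptions(n_boot=n_boot, seed=_seed(seed, 10_000 + k),
                             transform="none"))
        if res["CS"].p_acme < alpha:
            rejections += 1
    return rejections / n_sims


def acme_coverage(n_reps: int = 100, n: int = 2000, n_boot: int = 200,
                  seed: int = 0) -> float:
    """Fraction of replicates whose 95% bootstrap CI covers the true ACME."""
    covered = 0
    for k in range(n_reps):
        t = recovery_truth(n, seed=_seed(seed, k))
        truth = truth_acme(t, "CS", "grim_eaa", "fvc")
        cohort = generate_cohort(t)
        res = bootstrap_mediation(
            cohort, ("FS", "CS"), "grim_eaa", "fvc",
            MediationOptions(n_boot=n_boot, seed=_seed(seed, 20_000 + k),
                             transform="none"))
        lo, hi = res["CS"].ci_acme
        if lo <= truth <= hi:
            covered += 1
    return covered / n_reps


def null_grid_fdr_fraction(n_runs: int = 50, n: int = 500, n_boot: int = 200,
                           seed: int = 0) -> float:
    """Fraction of FDR-significant cells over repeated all-null reduced grids
    (2 mediators x 2 status exposures x 2 lung outcomes, screen disabled)."""
    sig = 0
    total = 0
    for k in range(n_runs):
        cohort = generate_cohort(all_null_grid_truth(n, seed=_seed(seed, k)))
        spec = GridSpec(
            mediators=("hannum_eaa", "ieaa"), outcomes=("fev1", "fvc"),
            exposures=("FS", "CS"), run_screen=False,
            options=MediationOptions(n_boot=n_boot, seed=_seed(seed, 30_000 + k),
                                     transform="none"))
        results = run_grid(cohort, spec)
        sig += int(results.cells["significant"].sum())
        total += len(results.cells)
    return sig / total
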