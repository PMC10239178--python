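"""Product-of-coefficients mediation with nonparametric bootstrap inference.

For one exposure family X (smoking-status dummies, group-specific pack-years,
or years since cessation), one DNAm mediator M, and one outcome Y, two linear
models are fitted on the same analysis sample:

    M = b0M + a * X + bCM' * C + eM                (mediator model)
    Y = b0Y + c' * X + b * M + bCY' * C + eY       (outcome model)

The indirect effect (ACME) of an exposure term is a_hat * b_hat, the direct
effect (ADE) is c'_hat, and the total effect is their sum.  The proportion
mediated is 100 * ACME / total; it can be negative or exceed 100% when the
two components have opposite signs.

Inference is by nonparametric case resampling: rows of the analysis sample
are resampled with replacement, BOTH models are refitted per replicate, and
95% percentile intervals / two-sided tail-fraction p-values are taken over
the replicate distribution.  The analysis sample itself (outlier fences,
outcome z-scoring, listwise deletion) is fixed preprocessing, computed once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import LOG_OUTCOMES, add_exposure_columns
from .exceptions import (
    CollinearityError,
    InstabilityError,
    InsufficientDataError,
    SpecificationError,
)
from .linear import (
    EXPOSURE_FAMILIES,
    FitResult,
    apply_subset,
    default_covariates,
    family_of,
    fit_ols,
    ols_beta,
)
from .preprocessing import TransformSpec, flag_extreme_outliers, transform_outcome

#: |total| below this floor marks the proportion mediated as undefined.
PROP_MEDIATED_FLOOR = 1e-10


def proportion_mediated(acme: float, total: float,
                        floor: float = PROP_MEDIATED_FLOOR) -> tuple[float, bool]:
    """Percent of the total effect carried by the indirect path.

    Returns ``(percent, defined)``; when |total| < floor the percent is NaN
    and the flag is False (no exception -- the caller reports the flag).
    """
    if abs(total) < floor:
        return float("nan"), False
    return 100.0 * acme / total, True


@dataclass(frozen=True)
class MediationEstimate:
    """Point decomposition of one exposure-mediator-outcome cell."""

    acme: float
    ade: float

    @property
    def total(self) -> float:
        return self.acme + self.ade

    @property
    def prop_mediated(self) -> float:
        return proportion_mediated(self.acme, self.total)[0]

    @property
    def prop_defined(self) -> bool:
        return proportion_mediated(self.acme, self.total)[1]


def point_mediation(mediator_fit: FitResult, outcome_fit: FitResult,
                    exposure_term: str) -> MediationEstimate:
    """Product-of-coefficients decomposition from a fitted model pair."""
    if exposure_term not in mediator_fit.terms or exposure_term not in outcome_fit.terms:
        raise SpecificationError(
            f"exposure term {exposure_term!r} absent from a fit")
    mediator_name = None
    for t in outcome_fit.terms:
        if t not in mediator_fit.terms:
            mediator_name = t
            break
    if mediator_name is None:
        raise SpecificationError("outcome fit contains no mediator term")
    acme = mediator_fit[exposure_term] * outcome_fit[mediator_name]
    ade = outcome_fit[exposure_term]
    return MediationEstimate(acme=acme, ade=ade)


@dataclass(frozen=True)
class MediationOptions:
    """Tuning knobs for one mediation analysis."""

    n_boot: int = 2000
    seed: int = 0
    subset: str = "all"            # all | male (YSC analyses add the former filter)
    transform: str = "auto"        # auto: log for fg/hba1c then z-score; none: raw
    outlier_multiplier: float = 3.0
    stratify_by_group: bool = False
    max_fail_frac: float = 0.05


@dataclass
class MediationResult:
    """One cell's estimates with bootstrap CIs and p-values."""

    exposure: str
    mediator: str
    outcome: str
    point: MediationEstimate
    ci_acme: tuple
    ci_ade: tuple
    ci_total: tuple
    p_acme: float
    p_ade: float
    p_total: float
    n_boot: int
    n_analysis: int
    seed: int
    n_failed: int = 0

    @property
    def prop_mediated(self) -> float:
        return self.point.prop_mediated

    @property
    def prop_defined(self) -> bool:
        return self.point.prop_defined


@dataclass
class TotalEffectResult:
    """Exposure -> outcome regression (no mediator): Tables' top blocks."""

    exposure: str
    outcome: str
    effect: float
    ci: tuple
    p: float
    n_analysis: int


@dataclass
class PreparedAnalysis:
    """Frozen analysis sample and numeric design for one model pair."""

    Z: np.ndarray                  # base design: intercept, exposures, covariates
    m: np.ndarray | None           # mediator values (None for total-effect runs)
    y: np.ndarray
    terms: list                    # column names of Z
    exposures: tuple
    n_analysis: int
    index: pd.Index
    mediator: str | None
    outcome: str
    group_codes: np.ndarray | None = None


def _resolve_family(exposures) -> tuple[str, tuple]:
    if isinstance(exposures, str):
        fam = family_of(exposures) if exposures not in EXPOSURE_FAMILIES else exposures
    else:
        fams = {family_of(t) for t in exposures}
        if len(fams) != 1:
            raise SpecificationError(
                f"exposure terms {exposures} span multiple model families")
        fam = fams.pop()
    return fam, EXPOSURE_FAMILIES[fam]


def _transform_spec(outcome: str, mode: str) -> TransformSpec | None:
    if mode == "none":
        return None
    if mode != "auto":
        raise SpecificationError(f"unknown transform mode {mode!r}")
    return TransformSpec(log_transform=outcome in LOG_OUTCOMES, standardize=True)


def prepare_analysis(cohort: pd.DataFrame, exposures, mediator: str | None,
                     outcome: str, options: MediationOptions) -> PreparedAnalysis:
    """Fix the analysis sample: outlier fences, subset, deletion, transform.

    The mediator's extreme-outlier fence is computed on the full cohort's
    non-missing values (one fence per marker for the whole study), then the
    subset rule, listwise deletion, and outcome transformation are applied
    to produce the per-cell analysis sample.
    """
    fam, terms = _resolve_family(exposures)
    df = add_exposure_columns(cohort)

    if mediator is not None:
        keep = flag_extreme_outliers(df[mediator], multiplier=options.outlier_multiplier)
        df = df[keep | df[mediator].isna()]

    covs = default_covariates(subset=options.subset, family=fam)
    if options.subset == "male":
        df = apply_subset(df, "male")
    if fam == "cessation":
        df = apply_subset(df, "former")

    needed = list(terms) + ([mediator] if mediator else []) + list(covs) + [outcome]
    df = df.dropna(subset=list(dict.fromkeys(needed)))
    p = 1 + len(terms) + (1 if mediator else 0) + len(covs)
    if len(df) <= p:
        raise InsufficientDataError(
            f"{len(df)} rows after preprocessing for {p} design columns "
            f"({mediator} -> {outcome})")

    tspec = _transform_spec(outcome, options.transform)
    y = df[outcome].astype(float)
    if tspec is not None:
        y = transform_outcome(y, tspec)

    z_terms = ["intercept", *terms, *covs]
    Z = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in z_terms[1:]])
    m = df[mediator].to_numpy(dtype=float) if mediator else None
    codes = None
    if options.stratify_by_group:
        codes = pd.Categorical(df["smoking_status"]).codes.astype(np.int64)
    return PreparedAnalysis(Z=Z, m=m, y=y.to_numpy(dtype=float), terms=z_terms,
                            exposures=terms, n_analysis=len(df), index=df.index,
                            mediator=mediator, outcome=outcome, group_codes=codes)


def _resample_indices(rng: np.random.Generator, n: int,
                      group_codes: np.ndarray | None) -> np.ndarray:
    if group_codes is None:
        return rng.integers(0, n, size=n)
    idx = np.empty(n, dtype=np.int64)
    pos = 0
    for g in np.unique(group_codes):
        members = np.flatnonzero(group_codes == g)
        k = members.size
        idx[pos:pos + k] = members[rng.integers(0, k, size=k)]
        pos += k
    return idx


def _tail_pvalue(stats_vec: np.ndarray, n_boot: int) -> float:
    lo = float(np.mean(stats_vec <= 0))
    hi = float(np.mean(stats_vec >= 0))
    return float(min(1.0, max(2.0 * min(lo, hi), 1.0 / n_boot)))


def _percentile_ci(stats_vec: np.ndarray) -> tuple:
    lo, hi = np.percentile(stats_vec, [2.5, 97.5])
    return float(lo), float(hi)


def bootstrap_mediation(cohort: pd.DataFrame, exposures, mediator: str,
                        outcome: str,
                        options: MediationOptions = MediationOptions(),
                        ) -> dict[str, MediationResult]:
    """Case-resampling bootstrap for one model pair; results for every
    exposure term of the family (both terms share each replicate's refits).
    """
    if options.n_boot < 100:
        raise SpecificationError("n_boot must be >= 100")
    prep = prepare_analysis(cohort, exposures, mediator, outcome, options)
    Z, m, y = prep.Z, prep.m, prep.y
    n, p = Z.shape
    e_idx = {t: prep.terms.index(t) for t in prep.exposures}
    m_idx = p  # mediator appended as last outcome-design column

    # Point fits carry names/SEs for reporting.
    Xy = np.concatenate([Z, m[:, None]], axis=1)
    med_fit = fit_ols(pd.DataFrame(Z, columns=prep.terms), m)
    out_fit = fit_ols(pd.DataFrame(Xy, columns=prep.terms + [mediator]), y)
    points = {t: point_mediation(med_fit, out_fit, t) for t in prep.exposures}

    rng = np.random.default_rng(options.seed)
    n_boot = options.n_boot
    acme_b = {t: np.empty(n_boot) for t in prep.exposures}
    ade_b = {t: np.empty(n_boot) for t in prep.exposures}
    kept = 0
    failed = 0
    Xyb = np.empty((n, p + 1))
    for _ in range(n_boot):
        idx = _resample_indices(rng, n, prep.group_codes)
        Zb = Z[idx]
        try:
            beta_m = ols_beta(Zb, m[idx])
            Xyb[:, :p] = Zb
            Xyb[:, p] = m[idx]
            beta_y = ols_beta(Xyb, y[idx])
        except CollinearityError:
            failed += 1
            continue
        for t, j in e_idx.items():
            acme_b[t][kept] = beta_m[j] * beta_y[m_idx]
            ade_b[t][kept] = beta_y[j]
        kept += 1
    if failed > options.max_fail_frac * n_boot:
        raise InstabilityError(
            f"{failed}/{n_boot} bootstrap replicates failed to refit")

    results = {}
    for t in prep.exposures:
        a = acme_b[t][:kept]
        d = ade_b[t][:kept]
        tot = a + d
        results[t] = MediationResult(
            exposure=t, mediator=mediator, outcome=outcome, point=points[t],
            ci_acme=_percentile_ci(a), ci_ade=_percentile_ci(d),
            ci_total=_percentile_ci(tot),
            p_acme=_tail_pvalue(a, kept), p_ade=_tail_pvalue(d, kept),
            p_total=_tail_pvalue(tot, kept),
            n_boot=n_boot, n_analysis=prep.n_analysis, seed=options.seed,
            n_failed=failed)
    return results


def total_effect_analysis(cohort: pd.DataFrame, exposures, outcome: str,
                          options: MediationOptions = MediationOptions(),
                          ) -> dict[str, TotalEffectResult]:
    """Exposure -> outcome regressions (no mediator, no outlier exclusion),
    with bootstrap CIs and p-values for each exposure term of the family."""
    prep = prepare_analysis(cohort, exposures, None, outcome, options)
    Z, y = prep.Z, prep.y
    n, p = Z.shape
    e_idx = {t: prep.terms.index(t) for t in prep.exposures}
    beta = ols_beta(Z, y)

    rng = np.random.default_rng(options.seed)
    n_boot = options.n_boot
    eff_b = {t: np.empty(n_boot) for t in prep.exposures}
    kept = 0
    for _ in range(n_boot):
        idx = _resample_indices(rng, n, prep.group_codes)
        try:
            bb = ols_beta(Z[idx], y[idx])
        except CollinearityError:
            continue
        for t, j in e_idx.items():
            eff_b[t][kept] = bb[j]
        kept += 1
    return {
        t: TotalEffectResult(
            exposure=t, outcome=outcome, effect=float(beta[j]),
            ci=_percentile_ci(eff_b[t][:kept]),
            p=_tail_pvalue(eff_b[t][:kept], kept), n_analysis=prep.n_analysis)
        for t, j in e_idx.items()}


def run_mediation_analysis(cohort: pd.DataFrame, exposure: str, mediator: str,
                           outcome: str,
                           options: MediationOptions = MediationOptions(),
                           ) -> MediationResult:
    """Full single-cell pipeline: preprocessing, the appropriate model pair,
    and bootstrap inference; returns the requested exposure term's result."""
    fam, terms = _resolve_family(exposure)
    results = bootstrap_mediation(cohort, terms, mediator, outcome, options)
    if isinstance(exposure, str) and exposure in results:
        return results[exposure]
    return results[terms[0]]
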