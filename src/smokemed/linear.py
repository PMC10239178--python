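"""Design matrices, OLS fitting, age residualisation, and VIF diagnostics.

The mediation machinery is built on pairs of ordinary least-squares fits:

* mediator model -- marker ~ exposure terms + covariates,
* outcome model  -- outcome ~ exposure terms + marker + covariates,

with former/current smoking dummy-coded against the non-smoker reference,
pack-years carried in group-specific columns that are 0 for non-smokers, and
the years-since-cessation model restricted to former smokers (with their
pack-years as an extra covariate).

``fit_ols`` solves the least-squares problem by Householder QR for numerical
stability; the bootstrap refits it tens of thousands of times, so it stays a
thin wrapper around the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .cohort import COVARIATES, EXPOSURE_TERMS, add_exposure_columns
from .exceptions import (
    CollinearityError,
    ConfigurationError,
    DegenerateInputError,
    InsufficientDataError,
    SpecificationError,
)

#: Exposure-term families: each mediation analysis fits one family jointly.
EXPOSURE_FAMILIES = {
    "status": ("FS", "CS"),
    "packyears": ("FPY", "CPY"),
    "cessation": ("YSC",),
}

SUBSETS = ("all", "former", "male")

# Relative tolerance on the QR diagonal used to declare rank deficiency.
_RANK_RTOL = 1e-10


def family_of(exposure_term: str) -> str:
    for fam, terms in EXPOSURE_FAMILIES.items():
        if exposure_term in terms:
            return fam
    raise SpecificationError(f"unknown exposure term {exposure_term!r}")


def default_covariates(subset: str = "all", family: str = "status") -> tuple:
    """Covariate list for a model: the standard set, plus former pack-years
    for cessation models, minus sex in male-only subsets (where it is constant)."""
    covs = list(COVARIATES)
    if subset == "male":
        covs.remove("sex_male")
    if family == "cessation":
        covs.append("FPY")
    return tuple(covs)


@dataclass(frozen=True)
class ModelSpec:
    """One mediator-model or outcome-model specification.

    ``outcome`` is None for a mediator model (response = mediator);
    otherwise the mediator enters the design and the outcome is the response.
    """

    exposures: tuple
    mediator: str
    outcome: str | None = None
    covariates: tuple = COVARIATES
    subset: str = "all"

    def __post_init__(self):
        if self.subset not in SUBSETS:
            raise ConfigurationError(f"unknown subset {self.subset!r}")
        for t in self.exposures:
            if t not in EXPOSURE_TERMS:
                raise SpecificationError(f"unknown exposure term {t!r}")
        if "YSC" in self.exposures:
            if self.subset == "all":
                raise ConfigurationError(
                    "years-since-cessation models must subset to former smokers")
            if "FPY" not in self.covariates:
                raise ConfigurationError(
                    "years-since-cessation models require FPY among covariates")

    @property
    def role(self) -> str:
        return "mediator-model" if self.outcome is None else "outcome-model"

    @property
    def response(self) -> str:
        return self.mediator if self.outcome is None else self.outcome

    def design_columns(self) -> list:
        cols = ["intercept", *self.exposures]
        if self.outcome is not None:
            cols.append(self.mediator)
        cols.extend(self.covariates)
        return cols


def apply_subset(cohort: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "all":
        return cohort
    if subset == "former":
        return cohort[cohort["smoking_status"] == "former"]
    if subset == "male":
        return cohort[cohort["sex_male"] == 1]
    raise ConfigurationError(f"unknown subset {subset!r}")


def build_design(cohort: pd.DataFrame, spec: ModelSpec):
    """Build (design DataFrame, response Series) with listwise deletion.

    Rows failing the subset rule or missing any required value are dropped;
    the returned index identifies the analysis sample.
    """
    df = add_exposure_columns(cohort) if "FS" not in cohort.columns else cohort
    df = apply_subset(df, spec.subset)
    needed = [c for c in spec.design_columns() if c != "intercept"] + [spec.response]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise SpecificationError(f"cohort lacks columns: {missing_cols}")
    df = df.dropna(subset=list(dict.fromkeys(needed)))
    n, p = len(df), len(spec.design_columns())
    if n == 0 or n <= p:
        raise InsufficientDataError(
            f"{n} rows after subset/listwise deletion for {p} design columns")
    X = pd.DataFrame({"intercept": np.ones(n)}, index=df.index)
    for c in spec.design_columns()[1:]:
        X[c] = df[c].astype(float)
    return X, df[spec.response].astype(float)


@dataclass
class FitResult:
    """OLS fit summary: estimates, classical SEs, residuals, diagnostics."""

    terms: list
    coef: np.ndarray
    se: np.ndarray
    residuals: np.ndarray
    n: int
    r_squared: float
    df_resid: int
    pvalues: np.ndarray = field(default=None)

    def __getitem__(self, term: str) -> float:
        return float(self.coef[self.terms.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def p_of(self, term: str) -> float:
        return float(self.pvalues[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "p": self.pvalues}, index=self.terms)


def ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients only, by QR; raises CollinearityError on rank deficiency.

    This is the bootstrap's hot path: no SEs, no residual vector allocation
    beyond what the solve needs.
    """
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= _RANK_RTOL * max(diag.max(), 1.0):
        bad = int(np.argmin(diag))
        raise CollinearityError(
            f"design is rank deficient at column {bad}", columns=(bad,))
    return sla.solve_triangular(R, Q.T @ y, lower=False)


def fit_ols(X, y) -> FitResult:
    """Ordinary least squares with classical (homoskedastic) standard errors.

    ``X`` may be a DataFrame (term names kept) or array; an intercept is NOT
    added implicitly.  Raises ``CollinearityError`` naming the dependent
    column on rank deficiency and ``InsufficientDataError`` when n <= p.
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        terms = [f"x{j}" for j in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n <= p:
        raise InsufficientDataError(f"n={n} rows for p={p} columns")

    Q, R = np.linalg.qr(Xv)
    diag = np.abs(np.diag(R))
    if diag.min() <= _RANK_RTOL * max(diag.max(), 1.0):
        bad = int(np.argmin(diag))
        raise CollinearityError(
            f"design is rank deficient: column {terms[bad]!r} is linearly "
            f"dependent on the others", columns=(terms[bad],))
    beta = sla.solve_triangular(R, Q.T @ yv, lower=False)
    resid = yv - Xv @ beta
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid
    Rinv = sla.solve_triangular(R, np.eye(p), lower=False)
    se = np.sqrt(sigma2 * np.sum(Rinv**2, axis=1))
    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf)
    pvals = 2 * stats.t.sf(np.abs(tstat), df_resid)
    return FitResult(terms=terms, coef=beta, se=se, residuals=resid, n=n,
                     r_squared=r2, df_resid=df_resid, pvalues=pvals)


def residualize_on_age(epigenetic_age, chron_age) -> pd.Series:
    """Age acceleration: residuals of epigenetic age regressed on chronological age.

    The output is uncorrelated with chronological age by construction.
    """
    ea = pd.Series(epigenetic_age, dtype=float)
    ca = np.asarray(chron_age, dtype=float)
    if len(ea) != len(ca):
        raise SpecificationError("series lengths differ")
    if np.std(ca) == 0:
        raise DegenerateInputError("chronological age is constant: cannot residualize")
    X = np.column_stack([np.ones(len(ca)), ca])
    beta = ols_beta(X, ea.to_numpy())
    return pd.Series(ea.to_numpy() - X @ beta, index=ea.index)


def compute_vif(X) -> pd.Series:
    """Variance inflation factor per non-intercept design column.

    VIF_j = 1 / (1 - R^2_j) where R^2_j comes from regressing column j on
    all remaining columns (intercept included).  Perfect collinearity raises
    ``CollinearityError`` naming the column.
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        terms = [f"x{j}" for j in range(Xv.shape[1])]
    keep = [j for j, t in enumerate(terms)
            if not (t == "intercept" or np.ptp(Xv[:, j]) == 0)]
    if len(keep) < 2:
        raise DegenerateInputError("need >= 2 non-intercept columns for VIF")
    out = {}
    for j in keep:
        others = [k for k in range(Xv.shape[1]) if k != j]
        fit = fit_ols(Xv[:, others], Xv[:, j])
        r2 = fit.r_squared
        if r2 >= 1 - 1e-12:
            raise CollinearityError(
                f"column {terms[j]!r} is perfectly explained by the others "
                "(infinite VIF)", columns=(terms[j],))
        out[terms[j]] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
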