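"""Synthetic cohort generator with known causal structure.

The generator draws a smoking-stratified cohort whose marginal structure
matches a population-based biobank sample of 2474 adults aged 30-70:
three smoking groups with fixed prevalences, strongly sex-imbalanced
smoking, group-specific pack-years / cessation-time / covariate
distributions, seven DNA-methylation aging markers generated from linear
structural equations in the exposure terms and covariates, and four health
outcomes (fasting glucose and HbA1c on the log scale, spirometric FEV1/FVC
with joint lung-exam missingness).

Because the mediators and outcomes follow *linear* structural equations,
the generator's true indirect (mediation) effect of an exposure term
through a mediator is the closed-form product of the two path
coefficients; :func:`truth_acme` exposes it for parameter-recovery tests.

Pack-years and years-since-cessation are drawn from gamma distributions
whose mean and SD exactly match the configured values (a zero-truncated
normal cannot reproduce both moments when SD > mean, as it is for former
smokers' pack-years); see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CELL_PROPS,
    COHORT_COLUMNS,
    EXPOSURE_TERMS,
    MEDIATORS,
    OUTCOMES,
    STATUS_LEVELS,
    add_exposure_columns,
)
from .exceptions import ConfigurationError, SpecificationError

_EXPOSURE_FIELDS = ("fs", "cs", "fpy", "cpy", "ysc")
_TERM_TO_FIELD = dict(zip(EXPOSURE_TERMS, _EXPOSURE_FIELDS))


@dataclass
class MediatorEquation:
    """Linear structural equation for one DNAm marker.

    marker = intercept + fs*FS + cs*CS + fpy*FPY + cpy*CPY + ysc*YSC
             + sum_c covariates[c]*c + Normal(0, resid_sd)
    """

    intercept: float = 0.0
    fs: float = 0.0
    cs: float = 0.0
    fpy: float = 0.0
    cpy: float = 0.0
    ysc: float = 0.0
    covariates: dict = field(default_factory=dict)
    resid_sd: float = 1.0

    def exposure_coef(self, term: str) -> float:
        if term not in _TERM_TO_FIELD:
            raise SpecificationError(f"unknown exposure term {term!r}")
        return getattr(self, _TERM_TO_FIELD[term])


@dataclass
class OutcomeEquation:
    """Linear structural equation for one health outcome.

    When ``log_scale`` is set the linear predictor and noise act on
    log(outcome) and the result is exponentiated, producing the
    right-skewed marginal that a natural-log transform exactly linearises.
    """

    intercept: float = 0.0
    fs: float = 0.0
    cs: float = 0.0
    fpy: float = 0.0
    cpy: float = 0.0
    ysc: float = 0.0
    mediators: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    resid_sd: float = 1.0
    log_scale: bool = False

    def exposure_coef(self, term: str) -> float:
        if term not in _TERM_TO_FIELD:
            raise SpecificationError(f"unknown exposure term {term!r}")
        return getattr(self, _TERM_TO_FIELD[term])


def _default_mediator_model() -> dict:
    # Exposure coefficients: per-marker associations with former/current
    # status, former/current pack-years and years since cessation, on each
    # marker's natural scale (years for the age-acceleration residuals,
    # pack-years for the DNAm smoking marker, pg/mL for DNAm PAI-1,
    # years-per-year for the pace-of-aging marker).  Residual SDs and
    # covariate effects are free parameters of the generator.
    return {
        "hannum_eaa": MediatorEquation(
            -1.2, 0.426, 1.205, 0.021, 0.027, -0.029, {"bmi": 0.05}, 4.0
        ),
        "ieaa": MediatorEquation(
            0.0, 0.214, 0.367, 0.021, 0.003, -0.038, {}, 4.5
        ),
        "pheno_eaa": MediatorEquation(
            -2.6, 1.011, 1.930, 0.051, 0.043, -0.091, {"bmi": 0.10, "sex_male": 0.5}, 5.0
        ),
        "grim_eaa": MediatorEquation(
            -1.9, 1.446, 5.650, 0.087, 0.174, -0.108,
            {"bmi": 0.06, "sex_male": 1.0, "drinking": 0.5}, 3.0,
        ),
        "dnam_packyears": MediatorEquation(
            6.0, 4.705, 14.916, 0.255, 0.567, -0.313,
            {"age": 0.05, "sex_male": 1.5}, 5.5,
        ),
        "dnam_pai1": MediatorEquation(
            14000.0, 263.389, 1002.309, 12.694, 28.240, -16.028,
            {"age": 40.0, "bmi": 150.0, "sex_male": 800.0}, 2200.0,
        ),
        "dunedin_pace": MediatorEquation(
            0.85, 0.019, 0.084, 0.001, 0.002, -0.001,
            {"age": 0.002, "bmi": 0.004}, 0.10,
        ),
    }


def _default_outcome_model() -> dict:
    # Mediator effects: second-generation aging markers carry the indirect
    # smoking signal into glycaemic outcomes (positively) and lung function
    # (negatively); the first-generation markers (hannum_eaa, ieaa) carry
    # none.  fg/hba1c equations act on the log scale.
    return {
        "fg": OutcomeEquation(
            intercept=np.log(55.0), cs=-0.010,
            mediators={"grim_eaa": 0.006, "dnam_packyears": 0.002,
                       "dnam_pai1": 5e-6, "dunedin_pace": 0.15,
                       "pheno_eaa": 0.002},
            covariates={"age": 0.0012, "bmi": 0.008, "sex_male": 0.02},
            resid_sd=0.12, log_scale=True,
        ),
        "hba1c": OutcomeEquation(
            intercept=np.log(4.0), cs=-0.010,
            mediators={"grim_eaa": 0.004, "dnam_packyears": 0.0015,
                       "dnam_pai1": 3e-6, "dunedin_pace": 0.10,
                       "pheno_eaa": 0.0015},
            covariates={"age": 0.0012, "bmi": 0.004},
            resid_sd=0.09, log_scale=True,
        ),
        "fev1": OutcomeEquation(
            intercept=4.4,
            mediators={"grim_eaa": -0.020, "dnam_packyears": -0.005,
                       "dnam_pai1": -2e-5, "dunedin_pace": -0.30,
                       "pheno_eaa": -0.010},
            covariates={"age": -0.030, "sex_male": 0.80, "bmi": -0.005},
            resid_sd=0.45, log_scale=False,
        ),
        "fvc": OutcomeEquation(
            intercept=5.2,
            mediators={"grim_eaa": -0.025, "dnam_packyears": -0.006,
                       "dnam_pai1": -3e-5, "dunedin_pace": -0.35,
                       "pheno_eaa": -0.008},
            covariates={"age": -0.030, "sex_male": 1.00, "bmi": -0.003},
            resid_sd=0.50, log_scale=False,
        ),
    }


@dataclass
class SimTruth:
    """Full parameterisation of the synthetic cohort, with ground truth.

    Defaults reproduce the study sample's marginal structure: smoking-group
    prevalences 75.95% / 12.61% / 11.44%, male fractions 39.2% / 87.2% /
    83.0%, former smokers' pack-years 12.9 +/- 14.1 and cessation time
    12.9 +/- 10.0 years, current smokers' pack-years 20.8 +/- 19.9, ages
    uniform on 30-70, group-specific BMI / drinking / exercise / education,
    and 36.3% joint missingness of the spirometry outcomes.
    """

    n: int = 2474
    prevalence: tuple = (0.7595, 0.1261, 0.1144)
    age_range: tuple = (30.0, 70.0)
    sex_male_prob_by_group: tuple = (0.392, 0.872, 0.830)
    # (mean, sd) pairs; pack-years for non-smokers are structurally 0.
    packyear_dist: dict = field(default_factory=lambda: {
        "former": (12.9, 14.1), "current": (20.8, 19.9)})
    ysc_dist: tuple = (12.9, 10.0)
    bmi_dist: dict = field(default_factory=lambda: {
        "non": (24.1, 3.7), "former": (25.3, 3.2), "current": (25.4, 3.7)})
    drinking_prob: tuple = (0.038, 0.096, 0.244)
    exercise_prob: tuple = (0.436, 0.571, 0.336)
    education_dist: dict = field(default_factory=lambda: {
        "non": (5.6, 0.9), "former": (5.6, 0.9), "current": (5.4, 0.8)})
    # Dirichlet concentrations for six blood fractions (B, CD4T, CD8T,
    # monocytes, NK, granulocytes); the sixth is implicit in the output.
    cell_alpha: tuple = (9.0, 20.0, 14.0, 10.0, 8.0, 59.0)
    mediator_model: dict = field(default_factory=_default_mediator_model)
    outcome_model: dict = field(default_factory=_default_outcome_model)
    lung_missing_rate: float = 0.363
    seed: int = 0

    def validate(self) -> None:
        prev = np.asarray(self.prevalence, dtype=float)
        if prev.shape != (3,) or (prev < 0).any():
            raise ConfigurationError("prevalence: need 3 nonnegative entries")
        if abs(prev.sum() - 1.0) > 1e-12:
            raise ConfigurationError("prevalence: entries must sum to 1")
        if not (0 <= self.lung_missing_rate <= 1):
            raise ConfigurationError("lung_missing_rate: must be in [0, 1]")
        if self.n <= 0:
            raise ConfigurationError("n: must be a positive integer")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range: lower bound must be < upper")
        for grp, (m, s) in self.packyear_dist.items():
            if s < 0 or m < 0:
                raise ConfigurationError(f"packyear_dist[{grp}]: mean/SD must be >= 0")
        if self.ysc_dist[1] < 0:
            raise ConfigurationError("ysc_dist: SD must be >= 0")
        if any(a <= 0 for a in self.cell_alpha):
            raise ConfigurationError("cell_alpha: concentrations must be > 0")
        for name, eq in self.mediator_model.items():
            if eq.resid_sd < 0:
                raise ConfigurationError(f"mediator_model[{name}].resid_sd: must be >= 0")
        for name, eq in self.outcome_model.items():
            if eq.resid_sd < 0:
                raise ConfigurationError(f"outcome_model[{name}].resid_sd: must be >= 0")

    def replace(self, **kw) -> "SimTruth":
        return dataclasses.replace(self, **kw)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def pyify(obj):
            if isinstance(obj, dict):
                return {k: pyify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return type(obj)(pyify(v) for v in obj)
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        d = pyify(dataclasses.asdict(self))
        for key in ("prevalence", "age_range", "sex_male_prob_by_group",
                    "ysc_dist", "drinking_prob", "exercise_prob", "cell_alpha"):
            d[key] = list(d[key])
        d["packyear_dist"] = {k: list(v) for k, v in d["packyear_dist"].items()}
        d["bmi_dist"] = {k: list(v) for k, v in d["bmi_dist"].items()}
        d["education_dist"] = {k: list(v) for k, v in d["education_dist"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        d = dict(d)
        for key in ("prevalence", "age_range", "sex_male_prob_by_group",
                    "ysc_dist", "drinking_prob", "exercise_prob", "cell_alpha"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("packyear_dist", "bmi_dist", "education_dist"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        if "mediator_model" in d:
            d["mediator_model"] = {
                k: v if isinstance(v, MediatorEquation) else MediatorEquation(**v)
                for k, v in d["mediator_model"].items()}
        if "outcome_model" in d:
            d["outcome_model"] = {
                k: v if isinstance(v, OutcomeEquation) else OutcomeEquation(**v)
                for k, v in d["outcome_model"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _gamma_moments(rng: np.random.Generator, mean: float, sd: float, size: int):
    """Gamma draw with the given mean and SD (degenerate at ``mean`` if sd=0)."""
    if sd == 0 or mean == 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=size)


def _education(rng, mean, sd, size):
    return np.clip(np.rint(rng.normal(mean, sd, size=size)), 1, 7).astype(int)


def generate_cohort(truth: SimTruth) -> pd.DataFrame:
    """Draw a cohort of ``truth.n`` participants from the structural model.

    Deterministic given ``truth`` (including its seed).  Covariates are
    drawn independently within smoking group; mediators and outcomes follow
    the linear structural equations in ``truth`` plus Gaussian noise.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    n = truth.n

    status_idx = rng.choice(3, size=n, p=np.asarray(truth.prevalence, float))
    status = np.asarray(STATUS_LEVELS)[status_idx]
    is_former = status == "former"
    is_current = status == "current"

    age = rng.uniform(*truth.age_range, size=n)
    sex_male = (rng.random(n) < np.asarray(truth.sex_male_prob_by_group)[status_idx]
                ).astype(int)

    pack_years = np.zeros(n)
    for grp, mask in (("former", is_former), ("current", is_current)):
        m, s = truth.packyear_dist[grp]
        pack_years[mask] = _gamma_moments(rng, m, s, int(mask.sum()))

    ysc = np.full(n, np.nan)
    ysc[is_former] = _gamma_moments(rng, *truth.ysc_dist, int(is_former.sum()))

    bmi = np.empty(n)
    education = np.empty(n, dtype=int)
    for gi, grp in enumerate(STATUS_LEVELS):
        mask = status_idx == gi
        k = int(mask.sum())
        bmi[mask] = np.maximum(rng.normal(*truth.bmi_dist[grp], size=k), 12.0)
        education[mask] = _education(rng, *truth.education_dist[grp], k)
    drinking = (rng.random(n) < np.asarray(truth.drinking_prob)[status_idx]).astype(int)
    exercise = (rng.random(n) < np.asarray(truth.exercise_prob)[status_idx]).astype(int)

    cells = rng.dirichlet(np.asarray(truth.cell_alpha, float), size=n)

    cohort = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "smoking_status": status,
        "pack_years": pack_years,
        "years_since_cessation": ysc,
        "age": age,
        "sex_male": sex_male,
        "bmi": bmi,
        "drinking": drinking,
        "regular_exercise": exercise,
        "education": education,
    })
    for j, col in enumerate(CELL_PROPS):
        cohort[col] = cells[:, j]

    design = add_exposure_columns(cohort)

    def linear_predictor(eq, extra_terms=()):
        lp = np.full(n, float(eq.intercept))
        for term, fld in _TERM_TO_FIELD.items():
            lp += getattr(eq, fld) * design[term].to_numpy()
        for cov, coef in eq.covariates.items():
            lp += coef * design[cov].to_numpy(dtype=float)
        for name, coef in extra_terms:
            lp += coef * cohort[name].to_numpy(dtype=float)
        return lp

    for name in MEDIATORS:
        eq = truth.mediator_model[name]
        cohort[name] = linear_predictor(eq) + rng.normal(0, eq.resid_sd, size=n)

    for name in OUTCOMES:
        eq = truth.outcome_model[name]
        med_terms = [(m, c) for m, c in eq.mediators.items()]
        y = linear_predictor(eq, med_terms) + rng.normal(0, eq.resid_sd, size=n)
        cohort[name] = np.exp(y) if eq.log_scale else y

    lung_missing = rng.random(n) < truth.lung_missing_rate
    cohort.loc[lung_missing, ["fev1", "fvc"]] = np.nan

    return cohort[list(COHORT_COLUMNS)]


def truth_acme(truth: SimTruth, exposure_term: str, mediator: str, outcome: str) -> float:
    """Closed-form true indirect effect of ``exposure_term`` through ``mediator``.

    Under the generator's linear structural equations this is the product of
    the exposure->mediator and mediator->outcome coefficients, in outcome
    units (log-outcome units for the log-scale outcomes) per exposure unit.
    """
    if mediator not in truth.mediator_model:
        raise SpecificationError(f"unknown mediator {mediator!r}")
    if outcome not in truth.outcome_model:
        raise SpecificationError(f"unknown outcome {outcome!r}")
    a = truth.mediator_model[mediator].exposure_coef(exposure_term)
    b = truth.outcome_model[outcome].mediators.get(mediator, 0.0)
    return a * b
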