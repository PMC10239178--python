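"""Cohort table schema: column names, validation, and delimited-text I/O.

A cohort is a plain :class:`pandas.DataFrame`, one row per participant, with
the columns listed in :data:`COHORT_COLUMNS`.  Missing values are empty fields
on disk and NaN in memory.  Exposure design variables (FS, CS, FPY, CPY, YSC)
are *derived* from ``smoking_status`` / ``pack_years`` / ``years_since_cessation``
by :func:`add_exposure_columns`; they are never stored.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import ConfigurationError

#: Smoking-status levels, non-smokers first (the reference group).
STATUS_LEVELS = ("non", "former", "current")

#: Seven DNA-methylation mediators, in reporting order.
MEDIATORS = (
    "hannum_eaa",
    "ieaa",
    "pheno_eaa",
    "grim_eaa",
    "dnam_packyears",
    "dnam_pai1",
    "dunedin_pace",
)

#: Four health outcomes.  fg (mg/dL) and hba1c (%) are right-skewed and are
#: log-transformed before modelling; fev1/fvc (litres) may be jointly missing.
OUTCOMES = ("fg", "hba1c", "fev1", "fvc")

#: Outcomes that get a natural-log transform before z-scoring.
LOG_OUTCOMES = ("fg", "hba1c")

#: Immune cell-type proportion columns (sixth fraction is implicit).
CELL_PROPS = (
    "cell_prop_b",
    "cell_prop_cd4t",
    "cell_prop_cd8t",
    "cell_prop_mono",
    "cell_prop_nk",
)

#: Model covariates, in the order they enter every design matrix.
COVARIATES = (
    "age",
    "sex_male",
    "bmi",
    "drinking",
    "regular_exercise",
    "education",
) + CELL_PROPS

#: Exposure design terms.
EXPOSURE_TERMS = ("FS", "CS", "FPY", "CPY", "YSC")

COHORT_COLUMNS = (
    ("participant_id", "smoking_status", "pack_years", "years_since_cessation")
    + COVARIATES
    + MEDIATORS
    + OUTCOMES
)


def add_exposure_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the five exposure design variables appended.

    FS/CS dummy-code former/current status against the non-smoker reference;
    FPY/CPY carry pack-years for former/current smokers with non-smokers (and
    the other group) coded 0; YSC is years since cessation, defined only for
    former smokers (0 elsewhere so the column is numeric — YSC models subset
    to former smokers anyway).
    """
    out = cohort.copy()
    status = out["smoking_status"]
    out["FS"] = (status == "former").astype(float)
    out["CS"] = (status == "current").astype(float)
    out["FPY"] = out["pack_years"].where(status == "former", 0.0).fillna(0.0)
    out["CPY"] = out["pack_years"].where(status == "current", 0.0).fillna(0.0)
    out["YSC"] = out["years_since_cessation"].where(status == "former", 0.0).fillna(0.0)
    return out


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the cohort-table invariants; raise ``ConfigurationError`` on failure."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ConfigurationError(f"cohort is missing columns: {missing}")
    bad_status = set(cohort["smoking_status"].dropna()) - set(STATUS_LEVELS)
    if bad_status:
        raise ConfigurationError(f"unknown smoking_status levels: {sorted(bad_status)}")
    non = cohort["smoking_status"] == "non"
    if (cohort.loc[non, "pack_years"].fillna(0) != 0).any():
        raise ConfigurationError("pack_years must be 0 for non-smokers")
    not_former = cohort["smoking_status"] != "former"
    if cohort.loc[not_former, "years_since_cessation"].notna().any():
        raise ConfigurationError("years_since_cessation only defined for former smokers")
    if (cohort["fev1"].isna() != cohort["fvc"].isna()).any():
        raise ConfigurationError("fev1 and fvc must be jointly missing (one lung exam)")
    for col in ("fg", "hba1c", "bmi"):
        vals = cohort[col].dropna()
        if (vals <= 0).any():
            raise ConfigurationError(f"{col} must be strictly positive when present")
    cp = cohort[list(CELL_PROPS)]
    if (cp < -1e-12).any().any() or (cp.sum(axis=1) > 1 + 1e-9).any():
        raise ConfigurationError("cell proportions must be >= 0 and sum to <= 1")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort as CSV, missing values as empty fields."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` and validate it."""
    cohort = pd.read_csv(path)
    validate_cohort(cohort)
    return cohort
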