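import numpy as np
import pandas as pd
import pytest

from smokemed import SimTruth, generate_cohort
from smokemed.cohort import CELL_PROPS


@pytest.fixture(scope="session")
def default_truth():
    return SimTruth(n=800, seed=42)


@pytest.fixture(scope="session")
def cohort_small(default_truth):
    return generate_cohort(default_truth)


@pytest.fixture(scope="session")
def cohort_full():
    """Default-size cohort (2474 participants) for screen-scale tests."""
    return generate_cohort(SimTruth(seed=7))


def make_mini_cohort(statuses, seed=0, **overrides):
    """Tiny hand-buildable cohort with the full column schema."""
    rng = np.random.default_rng(seed)
    n = len(statuses)
    statuses = np.asarray(statuses)
    df = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "smoking_status": statuses,
        "pack_years": np.where(statuses == "non", 0.0, rng.uniform(1, 30, n)),
        "years_since_cessation": np.where(statuses == "former",
                                          rng.uniform(1, 25, n), np.nan),
        "age": rng.uniform(30, 70, n),
        "sex_male": rng.integers(0, 2, n),
        "bmi": rng.normal(24, 3, n).clip(15),
        "drinking": rng.integers(0, 2, n),
        "regular_exercise": rng.integers(0, 2, n),
        "education": rng.integers(1, 8, n),
    })
    cells = rng.dirichlet(np.ones(6), size=n)
    for j, col in enumerate(CELL_PROPS):
        df[col] = cells[:, j]
    for col in ("hannum_eaa", "ieaa", "pheno_eaa", "grim_eaa",
                "dnam_packyears", "dnam_pai1", "dunedin_pace"):
        df[col] = rng.normal(size=n)
    df["fg"] = rng.uniform(80, 110, n)
    df["hba1c"] = rng.uniform(5, 7, n)
    df["fev1"] = rng.uniform(1.5, 3.5, n)
    df["fvc"] = rng.uniform(2.5, 4.5, n)
    for k, v in overrides.items():
        df[k] = v
    return df
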