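"""Exposure-mediator screen, full mediation grid, and FDR control.

Two distinct multiplicity rules, mirroring the two analysis stages:

* the exposure->mediator screen uses a Bonferroni threshold
  alpha / (#mediators x #exposure variables); a marker is dropped only when
  NONE of its exposure associations passes, and
* the mediation stage collects every cell's indirect-effect p-value into one
  family and applies Benjamini-Hochberg step-up FDR control (optionally
  grouped per exposure family, the way publication tables print it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import MEDIATORS, OUTCOMES, add_exposure_columns
from .exceptions import SmokemedError, SpecificationError
from .linear import EXPOSURE_FAMILIES, ModelSpec, build_design, default_covariates, fit_ols
from .mediation import MediationOptions, bootstrap_mediation, total_effect_analysis
from .preprocessing import flag_extreme_outliers

#: All five exposure design variables, in reporting order.
ALL_EXPOSURES = ("FS", "CS", "FPY", "CPY", "YSC")


def _pair_seed(base: int, *parts: str) -> int:
    """Deterministic per-model-pair bootstrap seed, independent of grid order."""
    import zlib
    tag = zlib.crc32("/".join(parts).encode())
    return int(np.random.SeedSequence([int(base), tag]).generate_state(1)[0] % (2**31))


def bonferroni_threshold(alpha: float, n_mediators: int, n_exposures: int) -> float:
    """Screen threshold alpha / (n_mediators * n_exposures)."""
    if not 0 < alpha < 1:
        raise SpecificationError("alpha must be in (0, 1)")
    if n_mediators < 1 or n_exposures < 1:
        raise SpecificationError("counts must be positive integers")
    return alpha / (n_mediators * n_exposures)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise SpecificationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class GridSpec:
    """The full exposure x mediator x outcome analysis grid."""

    mediators: tuple = MEDIATORS
    outcomes: tuple = OUTCOMES
    exposures: tuple = ALL_EXPOSURES
    screen_alpha: float = 0.05
    run_screen: bool = True
    fdr_alpha: float = 0.05
    fdr_family: str = "single"      # single | per_exposure
    options: MediationOptions = field(default_factory=MediationOptions)

    @property
    def screen_threshold(self) -> float:
        return bonferroni_threshold(
            self.screen_alpha, len(self.mediators), len(self.exposures))

    def families(self) -> list:
        fams = []
        for fam, terms in EXPOSURE_FAMILIES.items():
            kept = tuple(t for t in terms if t in self.exposures)
            if kept:
                fams.append((fam, EXPOSURE_FAMILIES[fam], kept))
        return fams


@dataclass
class GridResults:
    """Screen table, kept mediators, per-cell mediation results, FDR flags."""

    screen_table: pd.DataFrame
    kept_mediators: tuple
    cells: pd.DataFrame
    total_effects: pd.DataFrame
    results: dict                      # (exposure, mediator, outcome) -> MediationResult
    errors: list
    spec: GridSpec

    @property
    def n_tests(self) -> int:
        return len(self.cells)


def screen_mediators(cohort: pd.DataFrame, grid: GridSpec):
    """Regress each marker on each exposure family (with covariates and the
    marker's own outlier exclusion); a marker is kept iff ANY exposure
    coefficient passes the Bonferroni threshold.

    Returns ``(screen_table, kept_mediators)``; the table has one row per
    mediator x exposure with the coefficient, SE, p, and pass flag.
    """
    threshold = grid.screen_threshold
    df_full = add_exposure_columns(cohort)
    rows = []
    kept = []
    for mediator in grid.mediators:
        keep = flag_extreme_outliers(
            df_full[mediator], multiplier=grid.options.outlier_multiplier)
        df = df_full[keep | df_full[mediator].isna()]
        if grid.options.subset == "male":
            df = df[df["sex_male"] == 1]
        any_pass = False
        for fam, terms, wanted in grid.families():
            subset = "former" if fam == "cessation" else "all"
            covs = default_covariates(subset=grid.options.subset, family=fam)
            spec = ModelSpec(exposures=terms, mediator=mediator, outcome=None,
                             covariates=covs, subset=subset)
            try:
                X, y = build_design(df, spec)
                fit = fit_ols(X, y)
            except SmokemedError as err:
                raise type(err)(f"screen {mediator} ~ {fam}: {err}") from err
            for term in wanted:
                p = fit.p_of(term)
                passed = bool(p < threshold)
                any_pass = any_pass or passed
                rows.append({
                    "mediator": mediator, "exposure": term,
                    "coef": fit[term], "se": fit.se_of(term), "p": p,
                    "pass": passed, "n": fit.n})
        if any_pass:
            kept.append(mediator)
    table = pd.DataFrame(rows)
    return table, tuple(kept)


def run_grid(cohort: pd.DataFrame, grid: GridSpec = GridSpec()) -> GridResults:
    """Screen, then run every kept mediator x exposure x outcome mediation
    cell, then BH-adjust all indirect-effect p-values as one family.

    Bootstrap seeds are derived deterministically per model pair from the
    options seed, so cells are independent of grid iteration order.  A
    failing cell is recorded and the grid continues; more than 10% failures
    aborts.
    """
    if grid.run_screen:
        screen_table, kept = screen_mediators(cohort, grid)
    else:
        screen_table, kept = pd.DataFrame(), tuple(grid.mediators)

    errors: list = []
    results: dict = {}
    total_rows = []

    # Per (family, outcome) total-effect block (no mediator).
    pair_keys = [(fam, terms, wanted, outcome)
                 for fam, terms, wanted in grid.families()
                 for outcome in grid.outcomes]
    for fam, terms, wanted, outcome in pair_keys:
        opts = replace(grid.options,
                       seed=_pair_seed(grid.options.seed, "total", fam, outcome))
        try:
            res = total_effect_analysis(cohort, terms, outcome, opts)
        except SmokemedError as err:
            errors.append(("total", fam, outcome, str(err)))
            continue
        for t in wanted:
            r = res[t]
            total_rows.append({"exposure": t, "outcome": outcome,
                               "effect": r.effect, "ci_low": r.ci[0],
                               "ci_high": r.ci[1], "p": r.p, "n": r.n_analysis})

    n_cells_expected = len(kept) * len(grid.exposures) * len(grid.outcomes)
    for mediator in kept:
        for fam, terms, wanted in grid.families():
            for outcome in grid.outcomes:
                opts = replace(
                    grid.options,
                    seed=_pair_seed(grid.options.seed, mediator, fam, outcome))
                try:
                    res = bootstrap_mediation(cohort, terms, mediator, outcome, opts)
                except SmokemedError as err:
                    errors.append((mediator, fam, outcome, str(err)))
                    continue
                for t in wanted:
                    results[(t, mediator, outcome)] = res[t]

    if n_cells_expected and len(errors) > 0.1 * n_cells_expected:
        raise SmokemedError(
            f"{len(errors)} of ~{n_cells_expected} grid cells failed: {errors[:3]}")

    rows = []
    for (t, mediator, outcome), r in results.items():
        rows.append({
            "exposure": t, "mediator": mediator, "outcome": outcome,
            "acme": r.point.acme, "ci_low": r.ci_acme[0], "ci_high": r.ci_acme[1],
            "ade": r.point.ade, "total": r.point.total,
            "p": r.p_acme, "prop_mediated_pct": r.prop_mediated,
            "prop_defined": r.prop_defined, "n": r.n_analysis})
    cells = pd.DataFrame(rows)
    if len(cells):
        if grid.fdr_family == "per_exposure":
            cells["fdr"] = np.nan
            for t in cells["exposure"].unique():
                mask = cells["exposure"] == t
                cells.loc[mask, "fdr"] = bh_adjust(cells.loc[mask, "p"])
        else:
            cells["fdr"] = bh_adjust(cells["p"])
        cells["significant"] = cells["fdr"] < grid.fdr_alpha
    else:
        cells = pd.DataFrame(columns=["exposure", "mediator", "outcome", "acme",
                                      "ci_low", "ci_high", "ade", "total", "p",
                                      "prop_mediated_pct", "prop_defined", "n",
                                      "fdr", "significant"])
    return GridResults(screen_table=screen_table, kept_mediators=kept,
                       cells=cells, total_effects=pd.DataFrame(total_rows),
                       results=results, errors=errors, spec=grid)
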