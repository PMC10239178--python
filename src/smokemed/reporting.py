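"""Descriptive statistics, correlation structure, and publication-style tables.

The cohort summary mirrors a baseline-characteristics table: per smoking
group, n (%) for the categorical rows and mean (SD) for the continuous rows,
with a Kruskal-Wallis test (tie-corrected, chi-square reference) across
groups for continuous variables and a Pearson chi-square test of
independence (no continuity correction) for categorical ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import STATUS_LEVELS
from .exceptions import DegenerateInputError
from .grid import GridResults

#: (column, kind, restrict-to-group) rows of the baseline table.
_SUMMARY_ROWS = (
    ("age", "continuous", None),
    ("sex_male", "categorical", None),
    ("drinking", "categorical", None),
    ("pack_years", "continuous", "former"),
    ("pack_years", "continuous", "current"),
    ("years_since_cessation", "continuous", "former"),
    ("regular_exercise", "categorical", None),
    ("education", "continuous", None),
    ("bmi", "continuous", None),
    ("fg", "continuous", None),
    ("hba1c", "continuous", None),
    ("fev1", "continuous", None),
    ("fvc", "continuous", None),
)


@dataclass
class CohortSummary:
    """Baseline table with per-group columns and a cross-group test p-value."""

    table: pd.DataFrame
    group_n: dict

    @property
    def n(self) -> int:
        return int(sum(self.group_n.values()))


def _kruskal_p(groups) -> float:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    arrays = [a for a in arrays if a.size > 0]
    if len(arrays) < 2:
        return float("nan")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 1.0  # identical values in every group: H = 0
    try:
        return float(stats.kruskal(*arrays).pvalue)
    except ValueError:
        return 1.0


def _chi2_p(statuses, binary) -> float:
    tab = pd.crosstab(statuses, binary)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return float("nan")
    return float(stats.chi2_contingency(tab, correction=False)[1])


def cohort_summary(cohort: pd.DataFrame) -> CohortSummary:
    """Baseline characteristics stratified by smoking status."""
    groups = [g for g in STATUS_LEVELS
              if (cohort["smoking_status"] == g).any()]
    for g in set(STATUS_LEVELS) - set(groups):
        warnings.warn(f"smoking group {g!r} is empty and omitted", stacklevel=2)
    if len(groups) < 2:
        raise DegenerateInputError("need >= 2 non-empty smoking groups")

    total = len(cohort)
    group_n = {g: int((cohort["smoking_status"] == g).sum()) for g in groups}
    rows = [{"variable": "n", "restrict": "",
             **{g: f"{group_n[g]} ({100 * group_n[g] / total:.2f}%)" for g in groups},
             "p": np.nan}]
    for col, kind, restrict in _SUMMARY_ROWS:
        row = {"variable": col, "restrict": restrict or ""}
        sub = cohort if restrict is None else cohort[cohort["smoking_status"] == restrict]
        for g in groups:
            vals = sub.loc[sub["smoking_status"] == g, col].dropna()
            if len(vals) == 0:
                row[g] = ""
            elif kind == "continuous":
                row[g] = f"{vals.mean():.1f} ({vals.std(ddof=1):.1f})"
            else:
                k = int((vals == 1).sum())
                row[g] = f"{k} ({100 * k / len(vals):.1f}%)"
        if restrict is not None:
            row["p"] = np.nan
        elif kind == "continuous":
            row["p"] = _kruskal_p(
                [cohort.loc[cohort["smoking_status"] == g, col] for g in groups])
        else:
            obs = cohort.dropna(subset=[col])
            row["p"] = _chi2_p(obs["smoking_status"], obs[col])
        rows.append(row)
    return CohortSummary(table=pd.DataFrame(rows), group_n=group_n)


def correlation_matrix(cohort: pd.DataFrame, variables) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations among the named variables.

    Zero-variance variables yield NaN rows/columns (flagged, not raised);
    the diagonal is exactly 1 for variables with variance.
    """
    if len(variables) < 2:
        raise DegenerateInputError("need >= 2 variables")
    df = cohort[list(variables)].astype(float)
    corr = df.corr(method="pearson", min_periods=3)
    for v in variables:
        if df[v].std(ddof=0) > 0 and df[v].notna().sum() >= 3:
            corr.loc[v, v] = 1.0
    return corr


def plot_correlation_heatmap(corr: pd.DataFrame, path) -> None:
    """Optional heatmap rendering (matplotlib imported lazily)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.6 * len(corr) + 2,) * 2)
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90)
    ax.set_yticks(range(len(corr)), corr.index)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_tables(grid_results: GridResults, summary: CohortSummary | None,
                  outdir) -> dict:
    """Write the report tables as CSV; returns {name: path}.

    Effects are rounded to 4 decimals and proportions to 1, matching the
    printed precision of the source tables; FDR significance is encoded as
    a boolean column.  Output is a pure function of its inputs (identical
    results give identical bytes).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    if summary is not None:
        p = outdir / "table_cohort_summary.csv"
        tab = summary.table.copy()
        tab["p"] = tab["p"].map(lambda v: "" if pd.isna(v) else f"{v:.2e}")
        tab.to_csv(p, index=False)
        paths["cohort_summary"] = p

    screen = grid_results.screen_table.copy()
    p = outdir / "table_exposure_mediator_screen.csv"
    if len(screen):
        for c in ("coef", "se"):
            screen[c] = screen[c].round(4)
        screen["p"] = screen["p"].map(lambda v: f"{v:.2e}")
    screen.to_csv(p, index=False)
    paths["screen"] = p

    totals = grid_results.total_effects.copy()
    p = outdir / "table_total_effects.csv"
    if len(totals):
        for c in ("effect", "ci_low", "ci_high"):
            totals[c] = totals[c].round(4)
        totals["p"] = totals["p"].round(4)
    totals.to_csv(p, index=False)
    paths["total_effects"] = p

    cells = grid_results.cells.copy()
    p = outdir / "table_mediation_grid.csv"
    if len(cells):
        for c in ("acme", "ci_low", "ci_high", "ade", "total", "p", "fdr"):
            cells[c] = cells[c].round(4)
        cells["prop_mediated_pct"] = cells["prop_mediated_pct"].round(1)
    cells.to_csv(p, index=False)
    paths["mediation_grid"] = p
    return paths
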