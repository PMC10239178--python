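"""Baseline characteristics and correlation structure of the simulated cohort.

Reads results/cohort.csv (run 01_simulate_cohort.py first), writes the
group-stratified summary table (Kruskal-Wallis / chi-square cross-group
tests) and the pairwise-complete Pearson correlation matrix among age, the
seven DNAm markers and the four outcomes.
"""

from pathlib import Path

from smokemed import MEDIATORS, OUTCOMES, cohort_summary, correlation_matrix, read_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.csv")
    summary = cohort_summary(cohort)
    summary.table.to_csv(RESULTS / "table_cohort_summary.csv", index=False)

    corr = correlation_matrix(cohort, ("age",) + MEDIATORS + OUTCOMES)
    corr.round(3).to_csv(RESULTS / "correlation_matrix.csv")

    print("cohort summary (first rows):")
    print(summary.table.head(6).to_string(index=False))
    print("\ncorrelations with age:")
    print(corr["age"].drop("age").round(3).to_string())
    print(f"\nwrote {RESULTS / 'table_cohort_summary.csv'} and correlation_matrix.csv")


if __name__ == "__main__":
    main()
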