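"""Exposure -> mediator screen: which DNAm markers are plausible mediators?

Regresses each of the seven markers on the five smoking variables (status
dummies; group-specific pack-years; years since cessation among former
smokers), adjusting for the full covariate set and excluding each marker's
3x-IQR extreme outliers.  A marker survives if ANY exposure association
passes the Bonferroni threshold 0.05 / (7 x 5) = 0.0014.
"""

from pathlib import Path

from smokemed import GridSpec, read_cohort, screen_mediators

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.csv")
    spec = GridSpec()
    table, kept = screen_mediators(cohort, spec)
    table.to_csv(RESULTS / "table_exposure_mediator_screen.csv", index=False)

    print(f"Bonferroni threshold: {spec.screen_threshold:.6f}")
    passes = table.groupby("mediator")["pass"].sum()
    for mediator in spec.mediators:
        status = "kept" if mediator in kept else "DROPPED"
        print(f"  {mediator:16s} {int(passes[mediator])}/5 exposures pass -> {status}")
    print(f"wrote {RESULTS / 'table_exposure_mediator_screen.csv'}")


if __name__ == "__main__":
    main()
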