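# Methods

## Scientific setting

Cigarette smoke alters DNA methylation at thousands of CpG sites, and several
composite DNAm indices — epigenetic "clocks" and clock components — summarise
those changes as measures of biological aging.  The pipeline asks how much of
smoking's association with glycaemic control (fasting glucose, HbA1c) and
ventilatory lung function (FEV1, FVC) is transmitted through seven such
markers: Hannum epigenetic age acceleration (EAA), intrinsic EAA, PhenoAge
EAA, GrimAge EAA, DNAm-estimated smoking pack-years, DNAm PAI-1, and
DunedinPACE.  EAA measures are residuals of a DNAm-predicted age regressed on
chronological age (`residualize_on_age`), hence uncorrelated with age by
construction.

Computing the markers from CpG β-values (clock calculators, cell-type
deconvolution, array QC) is out of scope: the pipeline starts from a tidy
per-participant table in which the markers are columns.

## Mediation model

For each exposure family, mediator M and outcome Y, two OLS models are fitted
on one analysis sample:

* mediator model: M ~ exposure terms + covariates,
* outcome model:  Y ~ exposure terms + M + covariates.

Exposure families and their design terms:

| family | terms | sample |
|---|---|---|
| smoking status | FS, CS dummies (non-smoker reference) | all |
| pack-years | FPY, CPY (group-specific, 0 for non-smokers) | all |
| cessation | YSC (years since cessation) | former smokers, FPY as extra covariate |

Covariates: age (years), sex, BMI (kg/m²), drinking, regular exercise,
education (integer 1–7, treated numerically), and five blood cell-type
proportions.  In male-only sensitivity runs the sex covariate is dropped
(it would be constant).

ACME = β̂(X→M)·β̂(M→Y), ADE = β̂(X→Y | M), total = ACME + ADE (an exact
identity of the decomposition, conserved to floating precision), proportion
mediated = 100·ACME/total, reported with an `undefined` flag when
|total| < 1e-10 rather than as an exception.  For a single mediator with
identical covariates and sample, the product of coefficients equals the
difference of coefficients β̂(X→Y without M) − β̂(X→Y with M) exactly; the
test suite verifies this identity to 1e-10, and it serves as the independent
oracle for the point estimator.

Both exposure terms of a joint family (FS+CS, FPY+CPY) are read from the
same fitted pair, so one bootstrap refit per replicate serves both.

## Preprocessing

Order of operations, applied once per analysis cell before any bootstrap:

1. **Extreme outliers.** A marker's fence [Q1 − 3·IQR, Q3 + 3·IQR] is
   computed on the full cohort's non-missing values of that marker
   (quartiles by linear interpolation between order statistics,
   configurable) and rows outside it are excluded for every analysis using
   that marker.  Missing values are never flagged.  Under a normal marker
   distribution these fences exclude essentially nothing (< 0.1%); they act
   on heavy right tails such as DNAm pack-years.
2. **Subset.** Cessation models keep former smokers; male-only runs keep
   males.
3. **Listwise deletion** over every model variable — no imputation, so the
   analysis n differs per cell (lung-function cells lose the ~36% of
   participants without spirometry, and each marker loses its own outliers).
4. **Outcome transform.** FG and HbA1c are natural-log transformed (they are
   generated log-normally, so the log exactly linearises the model), then
   all four outcomes are z-scored on the analysis sample with the sample SD
   (n−1).  Effects are therefore in SD units of the (possibly logged)
   outcome.

Treating fences and z-scores as fixed preprocessing (not recomputed inside
each bootstrap replicate) matches the convention that outlier exclusion and
standardisation precede the mediation analysis.

Skewness is reported as the population-moment Fisher–Pearson g1 (no
small-sample correction).

## Bootstrap inference

Nonparametric case resampling of whole rows, unstratified by default
(stratified-by-smoking-group available as an option).  Each of n_boot
(default 2000) replicates refits both models by QR least squares; replicates
whose resample is rank-deficient are dropped and counted, and more than 5%
failures aborts the cell.  95% CIs are percentile intervals (2.5/97.5); the
two-sided p-value is 2·min(fraction of replicates ≤ 0, fraction ≥ 0),
floored at 1/n_boot and capped at 1.  BCa intervals were not implemented:
percentile intervals are the common default for this analysis style and keep
the replicate loop allocation-free.  Point estimates come from the original
sample and are invariant to the bootstrap seed; only CIs and p-values vary.

The proportion mediated is reported as a point estimate only (no CI).

## Multiplicity

Two stages, two rules:

* **Screen.** Each marker is regressed on each exposure family; a marker is
  dropped only if *none* of its five exposure coefficients has
  p < α/(7 × 5) = 0.0014 (classical OLS t-tests).  Screen p-values are not
  part of the FDR family.
* **Grid.** All indirect-effect p-values of kept-mediator × exposure ×
  outcome cells form one Benjamini–Hochberg family (per-exposure grouping
  available as an option).  With six survivors the family has
  6 × 5 × 4 = 120 tests.  `bh_adjust` delegates to statsmodels'
  step-up implementation; an independent brute-force step-up oracle checks
  it in the tests.

VIF diagnostics (1/(1−R²) of each predictor on the rest, flagging > 5) are
available for every design; on default synthetic cohorts all grid VIFs are
finite and small.

## Synthetic cohort generator

One row per participant; all structure is parameterised by `SimTruth`, whose
defaults are the package's study conditions:

* smoking-group prevalences 0.7595 / 0.1261 / 0.1144 (multinomial draw);
* age uniform on 30–70 for every group (real cohorts show small group
  differences in mean age; a common age distribution keeps age a confounder
  through the marker equations only);
* male fraction 0.392 / 0.872 / 0.830 by group; group-specific BMI,
  drinking, exercise, education (rounded clipped normal on 1–7);
* pack-years: former 12.9 ± 14.1, current 20.8 ± 19.9; years since
  cessation 12.9 ± 10.0 (former only).  These are drawn from **gamma
  distributions with moment-matched mean and SD**: a zero-truncated normal
  cannot reproduce both moments when SD > mean (the former-smoker case),
  whereas the gamma matches them exactly and is right-skewed and
  nonnegative, as real pack-year distributions are;
* six Dirichlet blood-cell fractions (concentrations approximating adult
  leukocyte composition), five emitted, the granulocyte fraction implicit;
* mediators: linear structural equations in FS, CS, FPY, CPY, YSC and
  covariates plus Gaussian noise.  Exposure coefficients default to the
  observed-scale associations the screen emulates (e.g. current smoking
  shifts GrimAge acceleration by 5.650 years; each current pack-year by
  0.174 years).  Residual SDs and covariate loadings are free parameters
  (marker-scale summaries are not publicly tabulated); defaults were chosen
  once for realistic marker variance (e.g. GrimEAA residual SD 3 years,
  DunedinPACE 0.10) and are documented here, not presented as observed
  values;
* outcomes: linear structural equations in exposures, mediators and
  covariates; FG and HbA1c are generated on the log scale and
  exponentiated.  Default mediator→outcome loadings give the
  second-generation markers (PhenoAge, GrimAge, DNAm pack-years, PAI-1,
  DunedinPACE) positive glycaemic and negative lung-function effects and
  the first-generation markers none, mirroring the qualitative pattern the
  pipeline is designed to detect;
* FEV1/FVC jointly missing with probability 0.363 (one lung exam per
  participant).

`truth_acme` returns the closed-form true indirect effect — the product of
the two path coefficients — in generator units (log-outcome units for
FG/HbA1c).

**What the generator does not emulate:** joint covariate dependence beyond
smoking-group conditioning (covariates are drawn independently within
group), measurement error in self-reported exposures, age-dependent marker
variance, and any nonlinearity.  Passing tests therefore demonstrate
correctness of the pipeline's computations and calibration under its own
assumptions, not robustness to real-data violations of them.

### Model-faithful experiment truths

The default generator gives every marker pack-year loadings and every
outcome several mediator loadings.  A status-family single-mediator model
pair conditions on neither the pack-years nor the other markers, so on
default data the estimated ACME absorbs those correlated pathways — the
same mild misspecification a real cohort implies.  The operating-
characteristic experiments in `smokemed.experiments` therefore use reduced
truths under which the fitted models are correctly specified:

* **Type-I error** (complete null): the tested marker has zero exposure
  coefficients and the outcome has zero mediator loadings; 500 cohorts of
  n = 500, 200 bootstrap replicates each.  Measured rejection ≈ 0.2–0.4% at
  nominal 5% — strongly conservative, as product-of-coefficients tests are
  under the joint null.
* **CI coverage:** GrimAge-like marker with status coefficients only
  (current-smoking effect 5.650 years), lung outcome loading only on it
  (−0.025 per year); 100 cohorts of n = 2000.  Measured coverage ≈ 0.93–0.95.
* **Null-grid FDR:** 2 markers × 2 status exposures × 2 outcomes with all
  indirect paths zero, 50 grids; the FDR-significant fraction is ~0.

Problem sizes (n = 500–2474, 100–2000 bootstrap replicates, 50–500
simulation repetitions) were chosen so the full study and its calibration
suite run in minutes on a single core while leaving Monte-Carlo error well
inside the margins being tested.

## Numerical choices

* OLS by Householder QR with a relative rank tolerance of 1e-10 on the R
  diagonal; rank deficiency raises an error naming the dependent column.
  Classical homoskedastic SEs (the bootstrap is the inferential workhorse).
  The solver is cross-checked against the normal-equations brute force and
  statsmodels OLS to 1e-8/1e-10 in the tests.
* Quartiles: `numpy.quantile` linear interpolation (configurable).
* z-scores: sample SD (n−1).
* Kruskal–Wallis with tie correction and chi-square reference; Pearson
  chi-square without continuity correction (conventions are documented
  choices; the baseline-table p-values are not externally comparable).
* Per-cell bootstrap seeds derive from the grid seed and the cell's names
  (CRC-keyed `SeedSequence`), so results are independent of grid iteration
  order and byte-identical across runs.
* Report tables round effects to 4 decimals and proportions to 1 decimal.

## Known limitations

* Cross-sectional structure only: like the analysis style it implements,
  the pipeline cannot rule out reverse causation from outcome to marker.
* Single-mediator models: with several correlated markers truly active, a
  one-at-a-time ACME mixes their pathways (see the model-faithful note
  above); joint-mediator decompositions are not implemented.
* Listwise deletion assumes missingness unrelated to unobserved values
  (the generator's lung-exam missingness is completely at random).
* Percentile CIs can undercover slightly for strongly skewed replicate
  distributions at small n; the coverage experiment quantifies this at the
  default design.
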