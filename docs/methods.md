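# Methods

This note documents the models implemented in `reperr`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Measurement model and repeatability

Each time-invariant phenotype is modelled as classical test theory's
true-score-plus-error: observed reports at two occasions are
`P_T1 = T + e1`, `P_T2 = T + e2` with occasion errors independent given the
individual. Reliability is the variance ratio
`ρ = Var(T)/Var(P)`, which equals the T1–T2 correlation; the repeatability
index reported by `fit_repeatability` is the R² of the OLS regression
`P_T2 ~ P_T1 + time_T2−T1`, which for a bivariate relation converges to
ρ². The two scales coexist deliberately: the generator is parameterized by
the variance-ratio reliability (the quantity with a generative identity),
while the analysis reports the regression R², the quantity a practitioner
sees in cohort data. R² is the plain (unadjusted) coefficient of
determination; with n in the tens of thousands and ≤ 3 regressors the
adjustment is irrelevant, and R² is interpreted throughout as explained
variance.

Outlier handling: for variables with more than 10 levels, rows whose T1
*or* T2 value deviates ≥ 10 s.d. from the baseline (T1) mean are dropped in
a single pass, with the mean and s.d. computed before any exclusion. Both
occasions are screened against the baseline moments; the s.d. is not
re-estimated after exclusion. A consequence worth knowing: in small
samples a gross outlier inflates the baseline s.d. enough to save itself —
the rule is designed for biobank-scale n, where it behaves as intended.

Covariates are a parameter (default: follow-up time; the genetics contrast
adds baseline age). Missing rows are dropped listwise per phenotype; each
phenotype is analysed marginally.

## Error scores and RE_sum

Stage 1 fits `P_T2 ~ P_T1` (no covariates — the stage-1 score is meant to
capture *all* inconsistency, including the part explained by elapsed time,
which is then residualized out at the summary stage) and takes
`|residual| / s.d._T1,T2`. The pooled s.d. is that of the concatenated
non-missing T1 and T2 observations: it makes scores unit-free and
symmetric in the two visits.

Stage 2 keeps phenotypes with at least `min_n` (default 50,000) non-missing
scores, drops individuals with no scores, imputes remaining gaps with the
individual's own row mean (preserving between-person ordering), and runs
PCA on the correlation matrix of the imputed scores so that no indicator
dominates by scale. Loadings are reported on the correlation scale
(eigenvector × √eigenvalue) with PC₁'s sign fixed so the mean loading is
positive; RE_sum is the PC₁ projection residualized on the per-individual
mean follow-up time across contributing phenotypes. Under a weak shared
error factor (pairwise score correlations near 0.0125) this construction
yields PC₁ variance fractions near 21% and loadings near 0.46 for five
indicators — the two summaries are mutually consistent on the correlation
scale, which is why that scale was chosen.

## Weights

* Participation: `w_P = 1/p` for probabilities in (0, 1], supplied as an
  input column (estimating them from a reference sample is out of scope).
* Reporting error: per phenotype, z-standardize each occasion, regress
  standardized T2 on standardized T1, square the residual; `σ²_RE` is the
  individual's mean over available PCA-selected phenotypes (phenotypes the
  individual is missing are simply skipped), and `w_RE = 1/(1 + σ²_RE)`.
  The stage regression excludes follow-up time by default (configurable).
* Combined: elementwise product of the two, renormalized.

All weights are normalized to mean 1 before anything else is computed, and
the effective sample size uses the Kish form `ESS = n/(Var(w) + 1)` with
the population (ddof = 0) variance — the only convention under which equal
weights give exactly `ESS = n`, `Var(w) = 1` gives `n/2`, and rescaling by
a positive constant changes nothing. Weighted repeatability uses WLS with
the same design and defines
`R²_w = 1 − wSS_res / wSS_tot` about the *weighted* mean, the standard WLS
analogue. Mean shifts are standardized by the unweighted s.d. (ddof = 1).

## Bias simulation

Per replicate, the exposure is N(0, 1) and the outcome
`v·exposure + N(0, 1 − v²)` (so its variance is exactly 1 in expectation),
with v = −0.2. Reporting error attaches to education only:
`R_sim = −0.48E + 0.03B + ε` with ε ~ N(0, 1) — post-scaling makes results
insensitive to the ε variance — then `R = (R_sim + |min R_sim|)/s.d.(R_sim)`
using the replicate's sample min and s.d. (so min(R) = 0 and s.d.(R) = 1
hold exactly per replicate). The added noise is N(0, R) with R read as a
variance by default; an `error_scale="sd"` flag implements the alternative
reading, which satisfies the same unbiasedness/attenuation properties with
larger magnitudes. Selection is Bernoulli with
`P_sim = logistic(β0 + 0.42E − 0.12B)` and
`β0 = −log(|1 − 1/0.055|) ≈ −2.84`, always computed from the response rate,
never hard-coded. The estimate per replicate is the bivariate OLS slope
among selected individuals (no covariates; the design is a bivariate
regression). Aggregates: bias = mean estimate − v,
`RMSE = √(mean (v̂_k − v)²)`, and normal-approximation 95% CIs over
replicates. Each replicate draws from `default_rng([seed, replicate])`, so
scenarios are reproducible and trivially parallelizable; a replicate with
fewer than 30 selected individuals is resimulated once, then errors.

Default problem size is n = 90,000 individuals per replicate and k = 200
replicates, preserving the ~5.5% selected fraction (≈ 5,000 selected per
replicate) of the full-scale configuration (n = 9,000,000, k = 1,000),
which remains available through the `SimScenario` constructor.

Expected behaviour, all verified by the test suite: error in the outcome
leaves the slope unbiased but inflates RMSE; error in the exposure
attenuates it by roughly `1/(1 + E[R])` (with E[R] ≈ 4.5 after the shift,
the −0.2 effect collapses to about −0.04); selection with opposite-signed
coefficients on exposure and outcome induces a small positive collider
association, biasing the negative effect toward the null.

## Synthetic cohorts and genotypes

The generator emulates: a middle-aged volunteer cohort (ages uniform on
40–69; sex ratio 0.54 female; follow-up times N(8, 2²) years clipped at
0.5 — a baseline-to-recontact gap of several years), phenotypes of known
reliability with homo- or heteroskedastic error (error s.d. affine in
standardized covariates, floored at 0.01, then rescaled so the mean error
variance still hits the reliability target), equiprobable-threshold
discretization for few-level variables, MCAR missingness, logistic
selection on any standardized covariate or latent phenotype, and
biallelic dosages (Binomial(2, MAF), optional AR(1)-copula adjacent LD)
with additive effects rescaled so the in-sample genetic variance equals
h²_true exactly.

It does **not** emulate: informative missingness, systematic (directional)
misreporting, temporal drift in genuinely time-varying phenotypes,
realistic LD beyond adjacent correlation, relatedness, population
structure, or imputation artefacts. Passing tests therefore demonstrate
the behaviour of the estimators under the stated error model, not
robustness to every failure mode of real cohort data.

One numerical consequence of the exact in-sample h² rescaling: the
variance of h² estimates *across generator seeds* excludes the
effect-dispersion component, while a variant-block jackknife correctly
includes it. Calibration checks of the jackknife therefore draw effects
without rescaling.

## Heritability machinery

Haseman–Elston regression estimates h² as
`Σ_{i<j} A_ij y_i y_j / Σ_{i<j} A_ij²` with `A = ZZ'/M` the GRM of
column-standardized genotypes and y standardized; missing dosages are
mean-imputed and zero-variance columns dropped. The implementation
accumulates everything through M × M cross-products (`Z'Z`, `Z'y`, row
sums of `Z²`), so the n × n GRM is never formed and leave-one-block-out
estimates are exact at negligible cost. Standard errors use the
delete-one-block jackknife over contiguous, near-equal variant blocks
(default 200; the remainder goes to leading blocks),
`se² = (B−1)/B · Σ_b (θ_b − θ̄)²`.

The heritability-difference test between the repeated-measure phenotype
(within-person mean of the two occasions, which halves independent error
variance and lifts reliability from ρ to 2ρ/(1+ρ)) and the single-measure
phenotype takes `r(h²_R, h²_S)` as the Pearson correlation of the paired
leave-one-block-out estimates — the simplest estimator-agnostic reading of
a jackknife correlation — and computes
`se(h²_diff) = √(se_R² + se_S² − 2 r se_R se_S)`, `Z = h²_diff/se`. A
degenerate `se_diff = 0` with zero difference returns Z = 0. Contrasts
where both heritabilities fall below 2% are flagged as suppressed rather
than hidden. Haseman–Elston with a block jackknife stands in for
summary-statistic heritability estimators that need genome-scale LD
reference data; the contrast formulas are estimator-agnostic by design.

Variant QC uses an exact Hardy–Weinberg test by full enumeration of
heterozygote counts conditional on allele counts (with log-factorial
arithmetic and a 1 + 10⁻¹² tolerance on the "no more probable" comparison
to absorb rounding); thresholds are HWE P > 10⁻¹⁵, MAF > 1%, MAC > 100,
call rate > 90%, and a variant passes iff all four hold. Clumping is the
greedy rule: most significant unassigned variant below the p threshold
becomes an index; same-chromosome variants within ± window and with sample
dosage-correlation² above the r² threshold are assigned to it. The IVW MR
estimator is the fixed-effect inverse-variance-weighted mean of Wald
ratios with weights `(β_exp/se_out)²`, refusing to report with fewer than
five instruments; instrument selection uses the strict clumping
configuration (10,000 kb, r² 0.001, P < 5 × 10⁻⁸).

Association scans are per-variant OLS with optional covariates (age and
sex suffice on unstructured synthetic data; principal-component covariates
are out of scope), two-sided t-tests, `β_std = Z/√N` and
`r2_snp = β_std²`; constant-dosage variants are flagged and skipped.
Benjamini–Hochberg FDR at 5% is available for downstream tables.

## Numerical and testing choices

* Test problem sizes (e.g. n = 90,000 / k = 200 for the simulation grid,
  n = 5,000 / M = 500 / 200 blocks for heritability recovery, n = 100,000
  for reliability calibration) were chosen as the smallest sizes at which
  the Monte-Carlo error is comfortably below the effect being asserted.
* Tests that check a 95% interval against a point null use a 3.5-s.e.
  band instead: a literal 95% check fails one run in twenty by design.
* Stochastic tests fix their generator seeds; hypothesis-based property
  tests bound their example counts and disable deadlines.
* Degenerate inputs fail loudly with typed exceptions
  (`ConfigurationError`, `DataError`, `DegenerateVariableError`,
  `InsufficientDataError`, `EligibilityError`, `AlignmentError`) naming
  the offending field where applicable.

## Known limitations

* The error-score PCA assumes a single dominant error dimension; multi-
  factor error structures are not modelled.
* Heteroskedastic error s.d. is affine in covariates with a hard floor;
  more flexible variance functions are not supported.
* The Haseman–Elston estimator targets unrelated, unstructured samples;
  with strong structure or relatedness its estimates and jackknife s.e.s
  are not trustworthy.
* The simulation's selection model is logistic by construction; other
  selection mechanisms (truncation, frailty) are out of scope, as is
  IPW-corrected re-estimation inside the simulation.
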