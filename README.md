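# reperr

**Reporting error and selective participation in repeated self-report
phenotypes.**

Biobank-scale studies lean heavily on short self-report questionnaires.
When a *time-invariant* phenotype (birth year, years of education, age
first wore glasses, childhood height...) is asked twice and the answers
disagree, the disagreement is reporting error — and that error attenuates
regression slopes, shrinks SNP-heritability estimates and costs discovery
power. Participation in a volunteer cohort is itself selective, and the two
behaviours are entangled: the people who report most consistently are also
the people most likely to take part. `reperr` is a toolkit for quantifying
both behaviours and their consequences, built for epidemiologists and
statistical geneticists who want to stress-test analyses against
phenotype-resolution problems without access to restricted cohort data.

## What it computes

* **Repeatability.** For paired reports of a phenotype, OLS of the
  follow-up report on the baseline report controlling for follow-up time,
  `P_T2 ~ P_T1 + time_T2-T1`; the model R² is the repeatability index and
  `1 − R²` the reporting-error index. Continuous variables are screened
  with a ≥ 10 s.d. baseline-deviation outlier rule first.
* **Individual error scores and RE_sum.** Stage 1: absolute stage-regression
  residuals scaled by the pooled T1/T2 standard deviation, one unit-free
  score per person per phenotype. Stage 2: row-mean imputation, PCA on the
  correlation matrix of eligible scores (≥ 50,000 non-missing repeated
  observations by default), PC₁ projection residualized for follow-up time.
* **Weights.** Participation weights `w_P = 1/p`, reporting-error weights
  `w_RE = 1/(1 + σ²_RE)` with `σ²_RE` the mean squared standardized-stage
  residual, and their product; all normalized to mean 1, with the Kish
  effective sample size `ESS = n / (Var(w) + 1)`, weighted repeatability
  (`R²_w`) and standardized mean shifts `(m_w − m)/s.d.`
* **Bias simulation.** The 2 × 4 Monte-Carlo design crossing causal
  direction (error-free BMI ↔ error-prone education, true effect
  v = −0.2) with heteroskedastic reporting error
  (`R_sim = −0.48E + 0.03B + ε`, shifted/scaled to min 0 and s.d. 1) and
  logistic selection
  (`P_sim = logistic(−2.84 + 0.42E − 0.12B)`, intercept derived from a
  5.5% response rate), reporting per-scenario bias and RMSE.
* **Genetics at toy scale.** Variant QC (exact Hardy–Weinberg test,
  MAF > 1%, MAC > 100, call rate > 90%), per-variant association scans with
  `β_std = Z/√N`, greedy LD clumping (250 kb / r² 0.1), the within-person
  mean as an error-corrected phenotype, Haseman–Elston SNP heritability
  with a delete-one-variant-block jackknife, the paired heritability
  difference test `Z = h²_diff / se(h²_diff)` with
  `se(h²_diff) = √(se_R² + se_S² − 2 r se_R se_S)`, and the
  inverse-variance-weighted MR estimator (≥ 5 instruments, clumped at
  10,000 kb / r² 0.001, P < 5 × 10⁻⁸).

A synthetic-cohort generator with known ground truth (target reliability,
covariate-driven heteroskedastic error, logistic selection, genotypes of
known h²) makes every stage testable end to end.

## Worked example

```python
import pandas as pd
import reperr as rp

cfg = rp.CohortConfig(
    n_individuals=50_000,
    seed=7,
    phenotypes=(
        rp.PhenotypeSpec("education_years", reliability=0.75,
                         error_model="heteroskedastic",
                         het_coefs={"intercept": 1.0, "age": 0.6}),
        rp.PhenotypeSpec("age_first_glasses", reliability=0.6,
                         error_model="heteroskedastic",
                         het_coefs={"intercept": 1.0, "age": 0.6}),
    ),
    selection_coefficients={"intercept": -1.2, "education_years": 0.6},
)
cohort = rp.generate_cohort(cfg)

print(rp.fit_repeatability(cohort.phenotype_pair("education_years")).summary())

scores = {name: rp.residual_error_scores(cohort.phenotype_pair(name))
          for name in ("education_years", "age_first_glasses")}
fu = pd.Series(cohort.data["followup_time"].to_numpy(), index=cohort.data["id"])
matrix = rp.assemble_matrix(scores, followup_time=fu, min_n=10_000)
print(rp.compute_resum(matrix).summary())

sel = cohort.data[cohort.data.selected]
print(rp.participation_weights(sel.set_index("id")["participation_probability"]).summary())
```

prints

```
Repeatability of 'education_years'
  n used               50000
  outliers removed     0
  R^2                  0.5617
  reporting error      0.4383
  high repeatability   False (threshold R^2 > 0.81)
  coefficients:
    const            -0.00160
    P_T1              0.74453
    followup_time    -0.00015

RE_sum over 2 indicators, n = 50000
  PC1 variance explained  0.611
  PC1 loadings:
    education_years               0.782
    age_first_glasses             0.782

WeightSet(kind=participation, n=12279, Var(w)=0.2347, ESS=9945.1)
```

Reading it: a phenotype generated at reliability 0.75 (the T1–T2
correlation) shows repeatability R² ≈ 0.75² ≈ 0.56, i.e. a reporting-error
index of 0.44 — well below the R² > 0.81 "high repeatability" bar. The two
error scores share an age-driven error factor, so both load positively on
PC₁. Selection on education makes participation probabilities unequal, and
inverse-probability weighting the ~12,000 selected individuals costs about
19% of the effective sample size.

The simulation study is one call away:

```python
res = rp.run_scenario(rp.SimScenario(direction="edu_to_bmi",
                                     reporting_error=True,
                                     n=90_000, k=200, seed=7))
print(res.summary())
# edu_to_bmi/scenario2: mean -0.0373 [-0.0376, -0.0370], bias +0.1627, RMSE 0.1627
```

— heteroskedastic error in the *exposure* collapses the true −0.2 effect
toward the null (classical regression dilution), whereas the same error in
the *outcome* (`direction="bmi_to_edu"`) leaves the estimate unbiased and
only widens its spread. `rp.run_grid(...)` runs all eight scenarios.

A `reperr` console script exposes the same pipeline from the shell
(`reperr simulate-cohort`, `repeatability`, `rescore`, `weights`,
`simulate-bias`, `gwas-contrast`, `ivw`); see `reperr --help`.

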