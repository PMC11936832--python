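"""Individual reporting-error scores and the PCA summary score (RE_sum).

Two-stage protocol.  Stage 1: for each phenotype, regress the follow-up
report on the baseline report and take absolute residuals, scaled by the
pooled standard deviation of the concatenated T1 and T2 observations — a
unit-free per-individual error score.  Stage 2: assemble the scores of
phenotypes with enough non-missing repeated observations into a matrix,
row-mean-impute missing entries, run PCA on the correlation matrix, and use
the first principal component as the weighted summary score RE_sum,
residualized for (mean) follow-up time.

Loadings are reported on the correlation scale (eigenvector times the
square root of the eigenvalue) with the sign fixed so the mean loading is
positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    DataError,
    DegenerateVariableError,
    EligibilityError,
)
from .repeatability import PhenotypePair

__all__ = [
    "ErrorScoreMatrix",
    "ResumResult",
    "DecompositionResult",
    "residual_error_scores",
    "assemble_matrix",
    "compute_resum",
    "correlation_matrix",
    "decompose_error",
    "univariate_associations",
]


def residual_error_scores(pair: PhenotypePair) -> pd.Series:
    """Stage-1 reporting-error score: |residual| / pooled s.d. of T1 and T2.

    The stage-1 model is the bivariate regression P_T2 ~ P_T1.  Scores are
    indexed by individual id and missing wherever either observation is
    missing.  Scale-invariant by construction: multiplying the phenotype by
    a constant multiplies residuals and pooled s.d. alike.
    """
    mask = pair.complete
    if mask.sum() < 3:
        raise DataError(f"pair {pair.name!r}: fewer than 3 complete rows")
    t1, t2 = pair.values_t1[mask], pair.values_t2[mask]
    pooled = np.concatenate(
        [pair.values_t1[~np.isnan(pair.values_t1)], pair.values_t2[~np.isnan(pair.values_t2)]]
    )
    pooled_sd = pooled.std(ddof=1)
    if not pooled_sd > 0:
        raise DegenerateVariableError(
            f"pair {pair.name!r}: pooled s.d. of T1/T2 observations is zero"
        )
    X = sm.add_constant(t1)
    res = sm.OLS(t2, X).fit()
    scores = np.full(len(pair), np.nan)
    scores[mask] = np.abs(res.resid) / pooled_sd
    return pd.Series(scores, index=pd.Index(pair.ids, name="id"), name=pair.name)


@dataclass
class ErrorScoreMatrix:
    """Individuals x phenotypes matrix of scaled absolute residual scores."""

    scores: pd.DataFrame
    followup_time: pd.Series
    excluded: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_nonmissing(self) -> pd.Series:
        return self.scores.notna().sum()

    @property
    def phenotypes(self) -> list[str]:
        return list(self.scores.columns)


def assemble_matrix(
    scores: Mapping[str, pd.Series],
    followup_time: pd.Series | Mapping[str, pd.Series] | None = None,
    min_n: int = 50_000,
) -> ErrorScoreMatrix:
    """Assemble per-phenotype score vectors, keeping those with >= min_n scores.

    ``followup_time`` may be a single per-individual series or a mapping of
    per-phenotype series, in which case the per-individual mean over the
    retained phenotypes is used.
    """
    frame = pd.DataFrame({name: s for name, s in scores.items()})
    counts = frame.notna().sum()
    eligible = [c for c in frame.columns if counts[c] >= min_n]
    excluded = {c: int(counts[c]) for c in frame.columns if c not in eligible}
    if not eligible:
        raise EligibilityError(
            "no phenotype has enough non-missing repeated observations; "
            f"counts: {dict(counts)} (min_n={min_n})"
        )
    frame = frame[eligible]
    if followup_time is None:
        fu = pd.Series(np.nan, index=frame.index)
    elif isinstance(followup_time, pd.Series):
        fu = followup_time.reindex(frame.index)
    else:
        fu = pd.DataFrame(
            {k: v for k, v in followup_time.items() if k in eligible}
        ).reindex(frame.index).mean(axis=1)
    return ErrorScoreMatrix(scores=frame, followup_time=fu, excluded=excluded)


@dataclass
class ResumResult:
    """PCA summary of the error-score matrix.

    ``resum`` is the first-principal-component projection, residualized for
    mean follow-up time; ``loadings`` are correlation-scale PC1 loadings
    (eigenvector x sqrt(eigenvalue)), sign-fixed to a positive mean.
    """

    eligible_phenotypes: list[str]
    loadings: pd.Series
    pc1_variance_explained: float
    resum: pd.Series
    n_scored: int

    def summary(self) -> str:
        lines = [
            f"RE_sum over {len(self.eligible_phenotypes)} indicators, "
            f"n = {self.n_scored}",
            f"  PC1 variance explained  {self.pc1_variance_explained:.3f}",
            "  PC1 loadings:",
        ]
        for k, v in self.loadings.items():
            lines.append(f"    {k:<28} {v: .3f}")
        return "\n".join(lines)


def _row_mean_impute(frame: pd.DataFrame) -> pd.DataFrame:
    """Replace missing entries by the individual's own mean over available scores."""
    row_means = frame.mean(axis=1)
    out = frame.copy()
    for c in out.columns:
        out[c] = out[c].fillna(row_means)
    return out


def compute_resum(matrix: ErrorScoreMatrix) -> ResumResult:
    """PCA-based summary reporting-error score.

    Individuals with no available score are excluded; remaining missing
    entries are row-mean-imputed (complete rows are untouched).  PCA runs on
    the correlation matrix of the imputed scores so no single indicator
    dominates by scale.
    """
    frame = matrix.scores.dropna(how="all")
    if len(frame) < 2:
        raise DataError("fewer than 2 individuals with at least one score")
    imputed = _row_mean_impute(frame)
    sds = imputed.std(ddof=1)
    constant = sds[~(sds > 0)].index.tolist()
    if constant:
        raise DegenerateVariableError(
            f"constant indicator column(s) after imputation: {constant}"
        )
    z = (imputed - imputed.mean()) / sds
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    corr = np.atleast_2d(corr)
    eigval, eigvec = np.linalg.eigh(corr)
    lead = np.argmax(eigval)
    v1, lam1 = eigvec[:, lead], eigval[lead]
    if v1.mean() < 0:  # all-positive loading convention
        v1 = -v1
    loadings = pd.Series(v1 * np.sqrt(lam1), index=frame.columns, name="pc1_loading")
    pc1 = z.to_numpy() @ v1

    fu = matrix.followup_time.reindex(frame.index)
    if fu.notna().all() and fu.std(ddof=0) > 0:
        X = sm.add_constant(fu.to_numpy(float))
        pc1 = np.asarray(sm.OLS(pc1, X).fit().resid)
    resum = pd.Series(pc1, index=frame.index, name="resum")
    return ResumResult(
        eligible_phenotypes=list(frame.columns),
        loadings=loadings,
        pc1_variance_explained=float(lam1 / len(frame.columns)),
        resum=resum,
        n_scored=len(frame),
    )


def correlation_matrix(
    matrix: ErrorScoreMatrix, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Returns (r, p, significant) DataFrames; cells with fewer than 3
    overlapping observations are NaN.
    """
    cols = matrix.phenotypes
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = matrix.scores[cols[i]], matrix.scores[cols[j]]
            overlap = a.notna() & b.notna()
            if overlap.sum() < 3:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rr, pp = stats.pearsonr(a[overlap], b[overlap])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    return r_df, p_df, p_df < alpha


@dataclass
class DecompositionResult:
    """Standardized coefficients (with 95% CIs) of error-score predictors."""

    outcome: str
    table: pd.DataFrame  # index: predictor; columns: beta_std, se, ci_low, ci_high, p

    def summary(self) -> str:
        lines = [f"Decomposition of {self.outcome!r} (standardized OLS)"]
        for name, row in self.table.iterrows():
            lines.append(
                f"  {name:<22} {row.beta_std: .4f} "
                f"[{row.ci_low: .4f}, {row.ci_high: .4f}]  p={row.p:.3g}"
            )
        return "\n".join(lines)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x, ddof=1)
    if not sd > 0:
        raise DegenerateVariableError("cannot standardize a constant variable")
    return (x - np.nanmean(x)) / sd


def decompose_error(
    score: np.ndarray,
    age: np.ndarray,
    followup_time: np.ndarray,
    sex: np.ndarray,
    outcome_name: str = "error_score",
) -> DecompositionResult:
    """Regress an error score on age, follow-up time, their interaction and sex.

    The outcome and continuous predictors (including the interaction term)
    are z-standardized; sex enters as 0/1.
    """
    score = np.asarray(score, float)
    mask = ~np.isnan(score)
    y = _standardize(score[mask])
    a = _standardize(np.asarray(age, float)[mask])
    t = _standardize(np.asarray(followup_time, float)[mask])
    inter = _standardize(a * t)
    s = np.asarray(sex, float)[mask]
    X = sm.add_constant(np.column_stack([a, t, inter, s]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("rank-deficient decomposition design")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    names = ["baseline_age", "followup_time", "age_x_followup_time", "sex"]
    table = pd.DataFrame(
        {
            "beta_std": res.params[1:],
            "se": res.bse[1:],
            "ci_low": ci[1:, 0],
            "ci_high": ci[1:, 1],
            "p": res.pvalues[1:],
        },
        index=names,
    )
    return DecompositionResult(outcome=outcome_name, table=table)


def univariate_associations(
    outcome: np.ndarray, predictors: pd.DataFrame
) -> pd.DataFrame:
    """One standardized bivariate OLS per predictor column.

    Returns a table of standardized betas with two-sided 95% CIs and
    p-values.  Constant predictors are skipped with a warning.
    """
    outcome = np.asarray(outcome, float)
    rows = {}
    for name in predictors.columns:
        x = predictors[name].to_numpy(float)
        mask = ~(np.isnan(outcome) | np.isnan(x))
        if np.nanstd(x[mask], ddof=1) == 0:
            warnings.warn(f"predictor {name!r} is constant; skipped", stacklevel=2)
            continue
        y = _standardize(outcome[mask])
        xs = _standardize(x[mask])
        res = sm.OLS(y, sm.add_constant(xs)).fit()
        lo, hi = res.conf_int(alpha=0.05)[1]
        rows[name] = {
            "beta_std": res.params[1],
            "se": res.bse[1],
            "ci_low": lo,
            "ci_high": hi,
            "p": res.pvalues[1],
            "n": int(mask.sum()),
        }
    return pd.DataFrame(rows).T
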