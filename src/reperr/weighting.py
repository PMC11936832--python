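"""Participation, reporting-error and combined weights.

Three weight families, all normalized to mean 1:

* participation weights  w_P  = 1 / participation probability
  (inverse-probability weighting; upweights under-represented individuals);
* reporting-error weights  w_RE = 1 / (1 + sigma2_RE), where sigma2_RE is
  the individual's mean squared stage-regression residual across the
  PCA-selected phenotypes (inverse-variance weighting; downweights
  error-prone reporters);
* combined weights: the elementwise product, renormalized.

Effective sample size uses the Kish formula for mean-1 weights,
ESS = n / (Var(w) + 1) with the population variance, so equal weights give
ESS = n exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import AlignmentError, DataError, DegenerateVariableError
from .repeatability import PhenotypePair, RepeatabilityModel

__all__ = [
    "WeightSet",
    "error_variance_weights",
    "reporting_error_weights",
    "participation_weights",
    "combine_weights",
    "effective_sample_size",
    "WeightedRepeatability",
    "weighted_repeatability",
    "MeanShift",
    "weighted_mean_shift",
]


@dataclass
class WeightSet:
    """Per-individual weights normalized to mean 1, with their ESS."""

    weights: pd.Series
    kind: str  # participation | reporting_error | combined

    @classmethod
    def from_raw(cls, raw: pd.Series, kind: str) -> "WeightSet":
        raw = raw.astype(float)
        if (raw <= 0).any():
            raise DataError(f"{kind} weights must be positive")
        return cls(weights=raw / raw.mean(), kind=kind)

    @property
    def n(self) -> int:
        return len(self.weights)

    @property
    def variance_of_weights(self) -> float:
        return float(self.weights.var(ddof=0))

    @property
    def effective_sample_size(self) -> float:
        return self.n / (self.variance_of_weights + 1.0)

    def summary(self) -> str:
        return (
            f"WeightSet(kind={self.kind}, n={self.n}, "
            f"Var(w)={self.variance_of_weights:.4f}, "
            f"ESS={self.effective_sample_size:.1f})"
        )


def effective_sample_size(w: WeightSet) -> float:
    """ESS = n x 1/(Var(w) + 1) for mean-1 weights."""
    return w.effective_sample_size


def error_variance_weights(var_p: pd.DataFrame) -> WeightSet:
    """Weights 1/(1 + sigma2_RE) from a per-individual x phenotype table of
    squared stage-regression residuals; sigma2_RE is the row mean over
    available phenotypes.  Individuals with no available phenotype are
    excluded (recorded in ``excluded_ids``)."""
    sigma2 = var_p.mean(axis=1, skipna=True)
    excluded = sigma2[sigma2.isna()].index
    sigma2 = sigma2.dropna()
    ws = WeightSet.from_raw(1.0 / (1.0 + sigma2), kind="reporting_error")
    ws.excluded_ids = list(excluded)  # log of dropped individuals
    return ws


def reporting_error_weights(
    pairs: Mapping[str, PhenotypePair], include_followup: bool = False
) -> WeightSet:
    """Inverse-error-variance weights from the PCA-selected phenotype pairs.

    Per phenotype, both occasions are z-standardized and the follow-up
    report regressed on the baseline report (plus follow-up time when
    ``include_followup``); the squared residual is the individual's error
    variance for that phenotype.  sigma2_RE averages these across available
    phenotypes; w_RE = 1/(1 + sigma2_RE), normalized to mean 1.
    """
    var_cols = {}
    for name, pair in pairs.items():
        mask = pair.complete
        t1 = pair.values_t1.copy()
        t2 = pair.values_t2.copy()
        t1 = (t1 - np.nanmean(t1)) / np.nanstd(t1, ddof=1)
        t2 = (t2 - np.nanmean(t2)) / np.nanstd(t2, ddof=1)
        X = t1[mask][:, None]
        if include_followup:
            X = np.column_stack([X, pair.followup_time[mask]])
        res = sm.OLS(t2[mask], sm.add_constant(X)).fit()
        v = np.full(len(pair), np.nan)
        v[mask] = res.resid**2
        var_cols[name] = pd.Series(v, index=pd.Index(pair.ids, name="id"))
    return error_variance_weights(pd.DataFrame(var_cols))


def participation_weights(probabilities: pd.Series) -> WeightSet:
    """Inverse-probability weights w_P = 1/p, normalized to mean 1."""
    p = pd.Series(probabilities).astype(float)
    if (p <= 0).any() or (p > 1).any():
        raise DataError("participation probabilities must be in (0, 1]")
    return WeightSet.from_raw(1.0 / p, kind="participation")


def combine_weights(w_p: WeightSet, w_re: WeightSet) -> WeightSet:
    """Reporting-error-adjusted participation weights: w_P x w_RE, renormalized."""
    if not w_p.weights.index.equals(w_re.weights.index):
        common = w_p.weights.index.intersection(w_re.weights.index)
        if len(common) == 0:
            raise AlignmentError("weight sets share no individuals")
        if len(common) < len(w_p.weights) or len(common) < len(w_re.weights):
            raise AlignmentError(
                "weight sets cover different individuals; align them first"
            )
    return WeightSet.from_raw(w_p.weights * w_re.weights, kind="combined")


@dataclass
class WeightedRepeatability:
    """Unweighted vs weighted repeatability of one phenotype."""

    name: str
    r2: float
    r2_w: float
    kind: str

    @property
    def r2_diff(self) -> float:
        """R^2 - R^2_w; positive values index repeatability lost to weighting."""
        return self.r2 - self.r2_w


def weighted_repeatability(
    pair: PhenotypePair,
    weights: WeightSet,
    covariates: Sequence[str] = ("followup_time",),
) -> WeightedRepeatability:
    """Fit the repeatability model by OLS and by WLS with the given weights.

    The weighted R^2 is 1 - (weighted SS_res)/(weighted SS_tot about the
    weighted mean), the standard WLS analogue.
    """
    model = RepeatabilityModel(pair, covariates=covariates)
    r2 = model.fit().r2
    w = weights.weights.reindex(pd.Index(pair.ids)).to_numpy(float)
    if np.isnan(w[model._mask]).any():
        raise AlignmentError("weights missing for some individuals in the pair")
    r2_w = model.fit(weights=w).r2
    return WeightedRepeatability(name=pair.name, r2=r2, r2_w=r2_w, kind=weights.kind)


@dataclass
class MeanShift:
    """Weighted-vs-unweighted mean of one variable, as a standardized difference."""

    name: str
    mean: float
    weighted_mean: float
    sd: float

    @property
    def smd(self) -> float:
        """(m_w - m) / unweighted s.d."""
        return (self.weighted_mean - self.mean) / self.sd


def weighted_mean_shift(
    values: np.ndarray | pd.Series, weights: WeightSet, name: str = "value"
) -> MeanShift:
    """Standardized mean difference induced by weighting."""
    if isinstance(values, pd.Series):
        v = values.reindex(weights.weights.index).to_numpy(float)
    else:
        v = np.asarray(values, float)
        if len(v) != weights.n:
            raise AlignmentError("values and weights have different lengths")
    w = weights.weights.to_numpy(float)
    mask = ~np.isnan(v)
    v, w = v[mask], w[mask]
    sd = v.std(ddof=1)
    if not sd > 0:
        raise DegenerateVariableError(f"{name!r} has zero variance")
    return MeanShift(
        name=name,
        mean=float(v.mean()),
        weighted_mean=float(np.sum(w * v) / np.sum(w)),
        sd=float(sd),
    )
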