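"""Test-retest repeatability of paired phenotype reports.

The repeatability of a time-invariant phenotype is quantified as the
coefficient of determination (R²) of an OLS regression of the follow-up
report on the baseline report, controlling for follow-up time:

    P_T2 ~ P_T1 + time_T2-T1   (+ optional extra covariates, e.g. age)

1 - R² is the reporting-error index.  For continuous variables (> 10
levels), observations deviating >= 10 s.d. from the baseline mean at either
occasion are removed first; the moments are computed from the baseline
vector before any exclusion, in a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .exceptions import (
    DataError,
    DegenerateVariableError,
    InsufficientDataError,
)

__all__ = [
    "PhenotypePair",
    "RepeatabilityResults",
    "RepeatabilityModel",
    "remove_outliers",
    "fit_repeatability",
    "concordance",
    "HIGH_REPEATABILITY_R2",
]

#: R² above 0.9² counts as high repeatability
HIGH_REPEATABILITY_R2 = 0.9**2


@dataclass
class PhenotypePair:
    """Baseline/follow-up observations of one phenotype.

    ``n_levels=None`` marks a continuous variable (treated as > 10 levels
    for the outlier rule).  ``measure_class`` is descriptive metadata only.
    """

    name: str
    values_t1: np.ndarray
    values_t2: np.ndarray
    followup_time: np.ndarray
    n_levels: int | None = None
    measure_class: str = "self_report_time_invariant"
    baseline_age: np.ndarray | None = None
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.values_t1 = np.asarray(self.values_t1, dtype=float)
        self.values_t2 = np.asarray(self.values_t2, dtype=float)
        self.followup_time = np.asarray(self.followup_time, dtype=float)
        if not (
            len(self.values_t1) == len(self.values_t2) == len(self.followup_time)
        ):
            raise DataError(
                f"pair {self.name!r}: values_t1, values_t2 and followup_time "
                "must have equal length"
            )
        if self.baseline_age is not None:
            self.baseline_age = np.asarray(self.baseline_age, dtype=float)
        if self.ids is None:
            self.ids = np.arange(len(self.values_t1))
        present_t2 = ~np.isnan(self.values_t2)
        if np.any(self.followup_time[present_t2] <= 0):
            raise DataError(
                f"pair {self.name!r}: followup_time must be > 0 where T2 present"
            )
        if self.n_levels is not None and self.n_levels < 2:
            raise DataError(f"pair {self.name!r}: n_levels must be >= 2")

    def __len__(self) -> int:
        return len(self.values_t1)

    @property
    def complete(self) -> np.ndarray:
        """Boolean mask of rows with both observations present."""
        return ~(np.isnan(self.values_t1) | np.isnan(self.values_t2))

    def subset(self, mask: np.ndarray) -> "PhenotypePair":
        return replace(
            self,
            values_t1=self.values_t1[mask],
            values_t2=self.values_t2[mask],
            followup_time=self.followup_time[mask],
            baseline_age=None if self.baseline_age is None else self.baseline_age[mask],
            ids=self.ids[mask],
        )

    @classmethod
    def from_dataframe(cls, df, name, t1="value_t1", t2="value_t2",
                       followup="followup_time", age=None, id_col="id",
                       n_levels=None) -> "PhenotypePair":
        return cls(
            name=name,
            values_t1=df[t1].to_numpy(float),
            values_t2=df[t2].to_numpy(float),
            followup_time=df[followup].to_numpy(float),
            baseline_age=None if age is None else df[age].to_numpy(float),
            ids=df[id_col].to_numpy() if id_col in df else None,
            n_levels=n_levels,
        )


def remove_outliers(
    pair: PhenotypePair, sd_threshold: float = 10.0
) -> tuple[PhenotypePair, int]:
    """Drop rows deviating >= sd_threshold baseline s.d. from the baseline mean.

    Applies only to variables with more than 10 levels (continuous ones);
    categorical pairs are returned unchanged.  Both occasions are screened
    against the *baseline* (T1) moments, computed before any exclusion.
    """
    if pair.n_levels is not None and pair.n_levels <= 10:
        return pair, 0
    t1 = pair.values_t1
    mean = np.nanmean(t1)
    sd = np.nanstd(t1, ddof=1)
    if not sd > 0:
        raise DegenerateVariableError(
            f"pair {pair.name!r}: baseline s.d. is zero; outlier rule undefined"
        )
    lim = sd_threshold * sd
    with np.errstate(invalid="ignore"):
        out = (np.abs(pair.values_t1 - mean) >= lim) | (
            np.abs(pair.values_t2 - mean) >= lim
        )
    out = np.where(np.isnan(out), False, out).astype(bool)
    if not out.any():
        return pair, 0
    return pair.subset(~out), int(out.sum())


class RepeatabilityModel:
    """OLS (or WLS) model of the follow-up report on the baseline report.

    Parameters
    ----------
    pair : PhenotypePair
    covariates : sequence of str
        Any of "followup_time", "age"; default ("followup_time",).
    outlier_sd : float or None
        Threshold for the baseline-s.d. outlier rule; None disables it.

    ``fit()`` returns :class:`RepeatabilityResults`; ``fit(weights=...)``
    runs weighted least squares with the same design.
    """

    def __init__(
        self,
        pair: PhenotypePair,
        covariates: Sequence[str] = ("followup_time",),
        outlier_sd: float | None = 10.0,
    ):
        if outlier_sd is not None:
            pair, n_removed = remove_outliers(pair, outlier_sd)
        else:
            n_removed = 0
        self.pair = pair
        self.covariates = tuple(covariates)
        self.n_outliers_removed = n_removed

        mask = pair.complete
        cols = {"P_T1": pair.values_t1}
        for cov in self.covariates:
            if cov == "followup_time":
                cols["followup_time"] = pair.followup_time
            elif cov == "age":
                if pair.baseline_age is None:
                    raise DataError(
                        f"pair {pair.name!r}: covariate 'age' requested but "
                        "baseline_age is missing"
                    )
                cols["age"] = pair.baseline_age
            else:
                raise DataError(f"unknown covariate {cov!r}")
        for v in cols.values():
            mask &= ~np.isnan(v)
        self._mask = mask
        self.endog = pair.values_t2[mask]
        X = np.column_stack([cols[c][mask] for c in cols])
        self.exog_names = ["const", *cols]
        self.exog = sm.add_constant(X, has_constant="add")

    def fit(self, weights: np.ndarray | None = None) -> "RepeatabilityResults":
        n_used = len(self.endog)
        if n_used < 3:
            raise InsufficientDataError(
                f"pair {self.pair.name!r}: {n_used} complete rows (< 3)"
            )
        if not (self.endog.std() > 0) or not (self.exog[:, 1].std() > 0):
            raise DegenerateVariableError(
                f"pair {self.pair.name!r}: zero variance in P_T1 or P_T2"
            )
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise DataError(
                f"pair {self.pair.name!r}: rank-deficient design (collinear covariates)"
            )
        if weights is None:
            res = sm.OLS(self.endog, self.exog).fit()
            r2 = float(res.rsquared)
        else:
            w = np.asarray(weights, dtype=float)
            if len(w) == len(self.pair):
                w = w[self._mask]
            if len(w) != n_used:
                raise DataError("weights length does not match pair")
            res = sm.WLS(self.endog, self.exog, weights=w).fit()
            fitted = self.exog @ res.params
            wmean = np.sum(w * self.endog) / np.sum(w)
            ss_res = np.sum(w * (self.endog - fitted) ** 2)
            ss_tot = np.sum(w * (self.endog - wmean) ** 2)
            r2 = float(1.0 - ss_res / ss_tot)
        params = dict(zip(self.exog_names, res.params))
        return RepeatabilityResults(
            name=self.pair.name,
            r2=r2,
            n_used=n_used,
            n_outliers_removed=self.n_outliers_removed,
            slope=params["P_T1"],
            intercept=params["const"],
            params=params,
            resid=np.asarray(self.endog - self.exog @ res.params),
            mask=self._mask,
            ids=self.pair.ids,
            weighted=weights is not None,
        )


@dataclass
class RepeatabilityResults:
    """Repeatability fit: R², reporting-error index and the fitted line."""

    name: str
    r2: float
    n_used: int
    n_outliers_removed: int
    slope: float
    intercept: float
    params: dict
    resid: np.ndarray
    mask: np.ndarray
    ids: np.ndarray
    weighted: bool = False

    @property
    def error_index(self) -> float:
        return 1.0 - self.r2

    @property
    def high_repeatability(self) -> bool:
        return self.r2 > HIGH_REPEATABILITY_R2

    def summary(self) -> str:
        lines = [
            f"Repeatability of {self.name!r}"
            + (" (weighted)" if self.weighted else ""),
            f"  n used               {self.n_used}",
            f"  outliers removed     {self.n_outliers_removed}",
            f"  R^2                  {self.r2:.4f}",
            f"  reporting error      {self.error_index:.4f}",
            f"  high repeatability   {self.high_repeatability}"
            f" (threshold R^2 > {HIGH_REPEATABILITY_R2:.2f})",
            "  coefficients:",
        ]
        for k, v in self.params.items():
            lines.append(f"    {k:<16} {v: .5f}")
        return "\n".join(lines)


def fit_repeatability(
    pair: PhenotypePair,
    covariates: Sequence[str] = ("followup_time",),
    outlier_sd: float | None = 10.0,
) -> RepeatabilityResults:
    """Convenience wrapper: build a :class:`RepeatabilityModel` and fit it."""
    return RepeatabilityModel(pair, covariates=covariates, outlier_sd=outlier_sd).fit()


def concordance(
    objective: np.ndarray,
    subjective: np.ndarray,
    covariates: Sequence[str] = (),
    followup_time: np.ndarray | None = None,
    name: str = "concordance",
) -> RepeatabilityResults:
    """R² agreement between an objective and a subjective measure.

    Same machinery as :func:`fit_repeatability` with the objective measure in
    the baseline role; no outlier rule is applied by default.
    """
    objective = np.asarray(objective, dtype=float)
    if followup_time is None:
        followup_time = np.ones_like(objective)
    pair = PhenotypePair(
        name=name,
        values_t1=objective,
        values_t2=np.asarray(subjective, dtype=float),
        followup_time=followup_time,
        measure_class="objective",
    )
    return fit_repeatability(pair, covariates=covariates, outlier_sd=None)
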