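"""Synthetic cohort generation with known measurement-error ground truth.

A cohort mimics a volunteer biobank: each individual has an age at baseline,
a sex, a follow-up time, and one or more *time-invariant* phenotypes observed
at two occasions (T1, T2).  The observed values are the latent true score
plus independent occasion-specific error whose variance is calibrated to a
target reliability

    reliability = Var(true) / Var(observed) = corr(P_T1, P_T2).

Error may be homoskedastic or heteroskedastic (error s.d. an affine-positive
function of covariates).  Selection into the cohort follows a logistic model
on the covariates, so downstream inverse-probability weighting has a known
target.  Genotypes are simulated as biallelic dosages with additive effects
producing a phenotype of known SNP heritability.

Everything is a pure function of (config, seed): identical inputs give
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import norm

from .exceptions import ConfigurationError, DataError

__all__ = [
    "PhenotypeSpec",
    "CohortConfig",
    "Cohort",
    "GenotypeSet",
    "generate_cohort",
    "generate_selection",
    "generate_genotypes",
]

#: floor for heteroskedastic error s.d. so it stays positive
SD_FLOOR = 0.01


@dataclass(frozen=True)
class PhenotypeSpec:
    """Specification of one simulated time-invariant phenotype.

    Parameters
    ----------
    name : str
        Column stem; the cohort table gets ``{name}_t1``, ``{name}_t2`` and
        ``{name}_true``.
    reliability : float
        Target Var(true)/Var(observed), in (0, 1].  1.0 means error-free.
    mean, sd : float
        Moments of the latent true-score normal distribution.
    error_model : {"homoskedastic", "heteroskedastic"}
    het_coefs : mapping, optional
        Affine model of the per-individual error s.d. on covariates, e.g.
        ``{"intercept": 1.0, "age": 0.5, "sex": -0.2}``.  The resulting
        s.d.s are floored at ``SD_FLOOR`` and rescaled so the mean error
        variance still matches the target reliability.
    n_levels : int, optional
        If given (>= 2), observed values are discretized by binning the
        latent observation at equiprobable normal thresholds, which
        preserves a well-defined latent reliability.
    missing_rate : float
        Probability that an observation (independently at T1 and T2) is
        missing completely at random.
    """

    name: str
    reliability: float
    mean: float = 0.0
    sd: float = 1.0
    error_model: str = "homoskedastic"
    het_coefs: Mapping[str, float] | None = None
    n_levels: int | None = None
    missing_rate: float = 0.0

    def validate(self) -> None:
        if not (0.0 < self.reliability <= 1.0):
            raise ConfigurationError(
                f"phenotype {self.name!r}: reliability must be in (0, 1], "
                f"got {self.reliability}"
            )
        if self.sd <= 0:
            raise ConfigurationError(
                f"phenotype {self.name!r}: sd must be > 0, got {self.sd}"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError(
                f"phenotype {self.name!r}: missing_rate must be in [0, 1), "
                f"got {self.missing_rate}"
            )
        if self.error_model not in ("homoskedastic", "heteroskedastic"):
            raise ConfigurationError(
                f"phenotype {self.name!r}: unknown error_model "
                f"{self.error_model!r}"
            )
        if self.error_model == "heteroskedastic" and not self.het_coefs:
            raise ConfigurationError(
                f"phenotype {self.name!r}: het_coefs required for "
                "heteroskedastic error_model"
            )
        if self.n_levels is not None and self.n_levels < 2:
            raise ConfigurationError(
                f"phenotype {self.name!r}: n_levels must be >= 2, "
                f"got {self.n_levels}"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of a synthetic cohort.

    Ages are uniform on [age_min, age_max] (default 40-69, a middle-aged
    volunteer recruitment window); follow-up times are normal
    (followup_mean, followup_sd) years clipped below at 0.5 so every T2
    observation has positive follow-up.  ``sex_ratio`` is the probability
    of sex == 1 (female).  ``selection_coefficients``, when given, are
    log-odds {intercept + slopes on covariates}; see
    :func:`generate_selection` for the covariate vocabulary.
    """

    n_individuals: int
    seed: int
    phenotypes: Sequence[PhenotypeSpec] = field(default_factory=tuple)
    followup_mean: float = 8.0
    followup_sd: float = 2.0
    age_min: float = 40.0
    age_max: float = 69.0
    sex_ratio: float = 0.54
    selection_coefficients: Mapping[str, float] | None = None

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ConfigurationError(
                f"n_individuals must be >= 2, got {self.n_individuals}"
            )
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ConfigurationError(
                f"sex_ratio must be in [0, 1], got {self.sex_ratio}"
            )
        if self.followup_sd < 0:
            raise ConfigurationError(
                f"followup_sd must be >= 0, got {self.followup_sd}"
            )
        if self.age_max <= self.age_min:
            raise ConfigurationError(
                f"age_max must exceed age_min, got [{self.age_min}, {self.age_max}]"
            )
        for spec in self.phenotypes:
            spec.validate()

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phenotypes"] = [dataclasses.asdict(p) for p in self.phenotypes]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        d["phenotypes"] = tuple(
            PhenotypeSpec(**p) if not isinstance(p, PhenotypeSpec) else p
            for p in d.get("phenotypes", ())
        )
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Cohort:
    """A generated cohort: one row per individual plus its generating config.

    ``data`` columns: id, sex, age_t1, followup_time, participation_probability,
    selected, and per phenotype ``{name}_t1``, ``{name}_t2``, ``{name}_true``.
    ``covariates`` holds the standardized covariates (and standardized latent
    true scores) that error and selection models refer to.
    """

    data: pd.DataFrame
    covariates: pd.DataFrame
    config: CohortConfig
    selection_fraction: float | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    def phenotype_pair(self, name: str):
        """Return the (T1, T2) observations of one phenotype as a PhenotypePair."""
        from .repeatability import PhenotypePair  # local import; avoids cycle

        spec = next((p for p in self.config.phenotypes if p.name == name), None)
        if spec is None:
            raise KeyError(f"no phenotype named {name!r} in cohort")
        return PhenotypePair(
            name=name,
            values_t1=self.data[f"{name}_t1"].to_numpy(float),
            values_t2=self.data[f"{name}_t2"].to_numpy(float),
            followup_time=self.data["followup_time"].to_numpy(float),
            n_levels=spec.n_levels,
            baseline_age=self.data["age_t1"].to_numpy(float),
            ids=self.data["id"].to_numpy(),
        )

    def to_tsv(self, path, layout: str = "wide") -> None:
        """Write the cohort as TSV; ``layout`` is 'wide' (default) or 'long'."""
        if layout == "wide":
            self.data.to_csv(path, sep="\t", index=False)
            return
        if layout != "long":
            raise ConfigurationError(f"layout must be 'wide' or 'long', got {layout!r}")
        base = ["id", "sex", "age_t1", "followup_time"]
        rows = []
        for spec in self.config.phenotypes:
            sub = self.data[base + [f"{spec.name}_t1", f"{spec.name}_t2"]].copy()
            sub.columns = base + ["value_t1", "value_t2"]
            sub.insert(1, "phenotype", spec.name)
            rows.append(sub)
        pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=0)
    return (x - x.mean()) / s if s > 0 else x - x.mean()


def _error_variances(
    spec: PhenotypeSpec, covariates: pd.DataFrame, target_error_var: float
) -> np.ndarray:
    """Per-individual error variances averaging to ``target_error_var``."""
    n = len(covariates)
    if spec.error_model == "homoskedastic" or target_error_var == 0.0:
        return np.full(n, target_error_var)
    coefs = dict(spec.het_coefs)
    sd = np.full(n, float(coefs.pop("intercept", 0.0)))
    for name, a in coefs.items():
        if name not in covariates.columns:
            raise ConfigurationError(
                f"phenotype {spec.name!r}: het_coefs references unknown "
                f"covariate {name!r}"
            )
        sd = sd + a * covariates[name].to_numpy(float)
    sd = np.maximum(SD_FLOOR, sd)
    var = sd**2
    return var * (target_error_var / var.mean())


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort per ``config``; deterministic in ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    age = rng.uniform(config.age_min, config.age_max, n)
    sex = (rng.random(n) < config.sex_ratio).astype(int)
    followup = np.clip(rng.normal(config.followup_mean, config.followup_sd, n), 0.5, None)

    data = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": sex,
            "age_t1": age,
            "followup_time": followup,
        }
    )
    covariates = pd.DataFrame(
        {
            "age": _zscore(age),
            "sex": sex.astype(float),
            "followup_time": _zscore(followup),
        }
    )

    for spec in config.phenotypes:
        true = rng.normal(spec.mean, spec.sd, n)
        var_true = spec.sd**2
        target_error_var = var_true * (1.0 - spec.reliability) / spec.reliability
        var_i = _error_variances(spec, covariates, target_error_var)
        sd_i = np.sqrt(var_i)
        t1 = true + rng.standard_normal(n) * sd_i
        t2 = true + rng.standard_normal(n) * sd_i

        if spec.n_levels is not None:
            # equiprobable thresholds of the latent observed distribution
            obs_sd = np.sqrt(var_true + target_error_var)
            qs = norm.ppf(
                np.linspace(0, 1, spec.n_levels + 1)[1:-1], loc=spec.mean, scale=obs_sd
            )
            t1 = np.digitize(t1, qs).astype(float)
            t2 = np.digitize(t2, qs).astype(float)

        if spec.missing_rate > 0:
            t1[rng.random(n) < spec.missing_rate] = np.nan
            t2[rng.random(n) < spec.missing_rate] = np.nan

        data[f"{spec.name}_t1"] = t1
        data[f"{spec.name}_t2"] = t2
        data[f"{spec.name}_true"] = true
        covariates[spec.name] = _zscore(true)

    data["participation_probability"] = 1.0
    data["selected"] = True
    cohort = Cohort(data=data, covariates=covariates, config=config)

    if config.selection_coefficients is not None:
        cohort = generate_selection(cohort, config.selection_coefficients, rng=rng)
    return cohort


def generate_selection(
    cohort: Cohort,
    coefficients: Mapping[str, float],
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Cohort:
    """Fill participation probabilities and selection flags in place.

    ``coefficients`` maps {"intercept": b0, covariate: slope, ...} on the
    log-odds scale; covariate names refer to columns of ``cohort.covariates``
    (standardized age / follow-up time, sex 0/1, standardized latent
    phenotype scores).  Selection is a uniform draw U < probability.
    """
    if rng is None:
        rng = np.random.default_rng(
            cohort.config.seed + 1 if seed is None else seed
        )
    coefs = dict(coefficients)
    lin = np.full(cohort.n, float(coefs.pop("intercept", 0.0)))
    for name, b in coefs.items():
        if name not in cohort.covariates.columns:
            raise ConfigurationError(
                f"selection coefficient references unknown covariate {name!r}"
            )
        lin = lin + b * cohort.covariates[name].to_numpy(float)
    if not np.all(np.isfinite(lin)):
        raise DataError("non-finite linear predictor in selection model")
    prob = expit(lin)
    u = rng.random(cohort.n)
    selected = u < prob
    cohort.data["participation_probability"] = prob
    cohort.data["selected"] = selected
    cohort.selection_fraction = float(selected.mean())
    return cohort


@dataclass
class GenotypeSet:
    """Biallelic dosages with known causal architecture.

    ``dosages`` is an (n_individuals, n_variants) float array with values in
    [0, 2] (NaN = missing call).  ``effects`` are per-variant effects on the
    *standardized* genotype scale; ``h2_true`` is the variance-standardized
    genetic variance of the phenotype simulated alongside.
    """

    dosages: np.ndarray
    maf: np.ndarray
    position: np.ndarray
    chromosome: np.ndarray
    effects: np.ndarray
    h2_true: float

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def to_tsv(self, path) -> None:
        """Write as TSV: one header row of variant ids, one row per individual."""
        cols = [f"chr{c}_pos{p}" for c, p in zip(self.chromosome, self.position)]
        pd.DataFrame(self.dosages, columns=cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeSet":
        df = pd.read_csv(path, sep="\t")
        chrom, pos = [], []
        for c in df.columns:
            chrom_s, pos_s = c.split("_pos")
            chrom.append(int(chrom_s.replace("chr", "")))
            pos.append(int(pos_s))
        dos = df.to_numpy(float)
        maf = np.nanmean(dos, axis=0) / 2.0
        maf = np.minimum(maf, 1 - maf)
        return cls(
            dosages=dos,
            maf=maf,
            position=np.array(pos),
            chromosome=np.array(chrom),
            effects=np.zeros(dos.shape[1]),
            h2_true=float("nan"),
        )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeSet":
        """Read GT-derived dosages from a (plain-text or bgzipped) VCF."""
        from cyvcf2 import VCF  # optional dependency

        rows, chrom, pos = [], [], []
        for var in VCF(str(path)):
            gts = np.array([g[0] + g[1] if g[0] >= 0 else np.nan for g in var.genotypes])
            rows.append(gts)
            chrom.append(int(str(var.CHROM).replace("chr", "")))
            pos.append(var.POS)
        dos = np.array(rows, dtype=float).T
        maf = np.nanmean(dos, axis=0) / 2.0
        maf = np.minimum(maf, 1 - maf)
        return cls(
            dosages=dos,
            maf=maf,
            position=np.array(pos),
            chromosome=np.array(chrom),
            effects=np.zeros(dos.shape[1]),
            h2_true=float("nan"),
        )


def generate_genotypes(
    n: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    h2_true: float = 0.3,
    n_causal: int | None = None,
    seed: int = 0,
    ld_rho: float = 0.0,
    spacing_bp: int = 5_000,
) -> tuple[GenotypeSet, np.ndarray]:
    """Simulate dosages and a quantitative phenotype of known heritability.

    Dosages are Binomial(2, MAF); with ``ld_rho`` > 0 the two latent allele
    draws follow an AR(1) Gaussian copula along the variant axis, inducing
    simple adjacent-variant LD.  Causal effects act on sample-standardized
    genotypes and are rescaled so the genetic variance equals ``h2_true``;
    the phenotype adds N(0, 1 - h2_true) environmental noise.
    """
    if not (0.0 <= h2_true < 1.0):
        raise ConfigurationError(f"h2_true must be in [0, 1), got {h2_true}")
    if n_causal is None:
        n_causal = n_variants
    if n_causal > n_variants:
        raise ConfigurationError(
            f"n_causal ({n_causal}) must be <= n_variants ({n_variants})"
        )
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, n_variants)

    if ld_rho == 0.0:
        dosages = rng.binomial(2, maf, size=(n, n_variants)).astype(float)
    else:
        thresh = norm.ppf(1.0 - maf)  # allele present when latent > threshold
        dosages = np.zeros((n, n_variants))
        for _hap in range(2):
            z = rng.standard_normal((n, n_variants))
            for j in range(1, n_variants):
                z[:, j] = ld_rho * z[:, j - 1] + np.sqrt(1 - ld_rho**2) * z[:, j]
            dosages += (z > thresh).astype(float)

    position = (np.arange(n_variants) + 1) * spacing_bp
    chromosome = np.ones(n_variants, dtype=int)

    effects = np.zeros(n_variants)
    genetic = np.zeros(n)
    if h2_true > 0 and n_causal > 0:
        causal = rng.choice(n_variants, size=n_causal, replace=False)
        beta = rng.standard_normal(n_causal)
        sd = dosages.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        z = (dosages - dosages.mean(axis=0)) / sd
        g = z[:, causal] @ beta
        g_var = g.var(ddof=0)
        if g_var == 0:
            raise DataError("degenerate genetic component (zero variance)")
        beta *= np.sqrt(h2_true / g_var)
        effects[causal] = beta
        genetic = g * np.sqrt(h2_true / g_var)

    phenotype = genetic + rng.normal(0.0, np.sqrt(1.0 - h2_true), n)
    gset = GenotypeSet(
        dosages=dosages,
        maf=np.minimum(maf, 1 - maf),
        position=position,
        chromosome=chromosome,
        effects=effects,
        h2_true=h2_true,
    )
    return gset, phenotype
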