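"""Reporting error in association scans and SNP-heritability, at toy scale.

Contains the genetics half of the pipeline: variant QC (exact
Hardy-Weinberg test, MAF/MAC/call-rate filters), per-variant association
scans with standardized effects (beta_std = Z/sqrt(N), r2_snp =
beta_std^2), greedy LD clumping, construction of the repeated-measure
phenotype (within-person mean across occasions), Haseman-Elston regression
with a delete-one-variant-block jackknife as the desk-scale heritability
estimator, the paired heritability-difference Z test, and the
inverse-variance-weighted MR estimator.

The heritability-difference machinery is estimator-agnostic: it needs only
matched leave-one-block-out estimates for the single- and repeated-measure
phenotypes, from which it takes the jackknife correlation

    se(h2_diff) = sqrt(se_R^2 + se_S^2 - 2 r se_R se_S),  Z = h2_diff / se.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .cohort import GenotypeSet
from .exceptions import ConfigurationError, DataError, InsufficientDataError

__all__ = [
    "hwe_exact_test",
    "variant_qc",
    "association_scan",
    "clump",
    "make_repeated_phenotype",
    "HasemanElstonModel",
    "HEResults",
    "H2Contrast",
    "h2_contrast",
    "MRResult",
    "ivw_estimate",
    "select_instruments",
    "fdr_correct",
    "QC_THRESHOLDS",
]

#: default variant-QC thresholds
QC_THRESHOLDS = {
    "hwe_p_min": 1e-15,
    "maf_min": 0.01,
    "mac_min": 100,
    "call_rate_min": 0.90,
}


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value by heterozygote enumeration.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het | n, n_rare) up to a constant, via log-factorials
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.searchsorted(hets, n_het)
    p_obs = probs[obs]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def variant_qc(
    genotypes: GenotypeSet | np.ndarray,
    hwe_p_min: float = QC_THRESHOLDS["hwe_p_min"],
    maf_min: float = QC_THRESHOLDS["maf_min"],
    mac_min: int = QC_THRESHOLDS["mac_min"],
    call_rate_min: float = QC_THRESHOLDS["call_rate_min"],
) -> pd.DataFrame:
    """Per-variant QC report: MAF, MAC, call rate, exact HWE p, pass flag.

    A variant passes iff HWE p > hwe_p_min, MAF > maf_min, MAC > mac_min and
    call rate > call_rate_min.  Dosages are rounded to hard calls for the
    HWE counts; monomorphic variants get MAF 0 and simply fail the MAF
    filter.
    """
    dos = genotypes.dosages if isinstance(genotypes, GenotypeSet) else np.asarray(genotypes, float)
    n, m = dos.shape
    called = ~np.isnan(dos)
    call_rate = called.mean(axis=0)
    freq = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    alt_count = np.nansum(dos, axis=0)
    total = 2.0 * called.sum(axis=0)
    mac = np.minimum(alt_count, total - alt_count)

    hwe_p = np.ones(m)
    hard = np.rint(dos)
    for j in range(m):
        g = hard[called[:, j], j]
        hwe_p[j] = hwe_exact_test(
            int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
        )
    report = pd.DataFrame(
        {
            "maf": maf,
            "mac": mac,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
        }
    )
    report["pass"] = (
        (report.hwe_p > hwe_p_min)
        & (report.maf > maf_min)
        & (report.mac > mac_min)
        & (report.call_rate > call_rate_min)
    )
    return report


def association_scan(
    genotypes: GenotypeSet | np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant OLS of the phenotype on dosage (+ covariates).

    Returns one row per variant with beta, se, z, p, n, beta_std = z/sqrt(n)
    and r2_snp = beta_std^2.  Constant-dosage variants are skipped
    (flagged, all statistics NaN).  Missing dosages are dropped per variant.
    """
    if isinstance(genotypes, GenotypeSet):
        dos, pos, chrom = genotypes.dosages, genotypes.position, genotypes.chromosome
    else:
        dos = np.asarray(genotypes, float)
        pos = np.arange(dos.shape[1])
        chrom = np.ones(dos.shape[1], dtype=int)
    y_all = np.asarray(phenotype, float)
    if len(y_all) != dos.shape[0]:
        raise DataError("phenotype length does not match genotype rows")
    if covariates is not None:
        covariates = np.asarray(covariates, float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]

    rows = []
    for j in range(dos.shape[1]):
        g = dos[:, j]
        ok = ~(np.isnan(g) | np.isnan(y_all))
        if covariates is not None:
            ok &= ~np.isnan(covariates).any(axis=1)
        gj, yj = g[ok], y_all[ok]
        nj = int(ok.sum())
        if nj < 3 or gj.std(ddof=0) == 0:
            rows.append(
                dict(chrom=chrom[j], pos=pos[j], beta=np.nan, se=np.nan, z=np.nan,
                     p=np.nan, n=nj, beta_std=np.nan, r2_snp=np.nan, skipped=True)
            )
            continue
        X = np.column_stack([np.ones(nj), gj])
        if covariates is not None:
            X = np.column_stack([X, covariates[ok]])
        XtX = X.T @ X
        coef = np.linalg.solve(XtX, X.T @ yj)
        resid = yj - X @ coef
        dof = nj - X.shape[1]
        sigma2 = resid @ resid / dof
        se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
        beta = coef[1]
        z = beta / se
        p = 2.0 * stats.t.sf(abs(z), dof)
        beta_std = z / np.sqrt(nj)
        rows.append(
            dict(chrom=chrom[j], pos=pos[j], beta=beta, se=se, z=z, p=p, n=nj,
                 beta_std=beta_std, r2_snp=beta_std**2, skipped=False)
        )
    out = pd.DataFrame(rows)
    out.index.name = "variant"
    return out


def _ld_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared sample correlation between dosage columns (mean-imputed)."""
    d = np.array(dosages, float)
    col_means = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = np.take(col_means, idx[1])
    sd = d.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (d - d.mean(axis=0)) / sd
    r = (z.T @ z) / len(d)
    return r**2


def clump(
    assoc: pd.DataFrame,
    dosages: np.ndarray | None = None,
    ld_r2: np.ndarray | None = None,
    p_threshold: float = 5e-8,
    window_kb: float = 250.0,
    r2_threshold: float = 0.1,
) -> list[int]:
    """Greedy LD clumping; returns positional indices of index variants.

    Repeatedly take the most significant unassigned variant with
    p < p_threshold as an index variant and assign to it every variant on
    the same chromosome within +/- window_kb that has LD r^2 >=
    r2_threshold with it.
    """
    if ld_r2 is None:
        if dosages is None:
            raise DataError("clump needs either dosages or a precomputed ld_r2 matrix")
        ld_r2 = _ld_r2(dosages)
    p = assoc["p"].to_numpy(float)
    pos = assoc["pos"].to_numpy(float)
    chrom = assoc["chrom"].to_numpy()
    window = window_kb * 1_000.0

    available = (p < p_threshold) & ~np.isnan(p)
    assigned = np.zeros(len(assoc), dtype=bool)
    index_variants: list[int] = []
    while True:
        cand = available & ~assigned
        if not cand.any():
            break
        i = int(np.nanargmin(np.where(cand, p, np.inf)))
        index_variants.append(i)
        near = (
            (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
            & (ld_r2[i] >= r2_threshold)
        )
        assigned |= near
        assigned[i] = True
    return index_variants


def make_repeated_phenotype(p_t1: np.ndarray, p_t2: np.ndarray) -> np.ndarray:
    """Within-person mean across the two occasions (NaN unless both present).

    Averaging halves the variance of independent occasion errors, raising
    reliability from rho to 2*rho/(1+rho).
    """
    p_t1 = np.asarray(p_t1, float)
    p_t2 = np.asarray(p_t2, float)
    out = (p_t1 + p_t2) / 2.0
    out[np.isnan(p_t1) | np.isnan(p_t2)] = np.nan
    return out


def _contiguous_blocks(m: int, n_blocks: int) -> list[np.ndarray]:
    """Near-equal contiguous index blocks; remainder goes to leading blocks."""
    sizes = np.full(n_blocks, m // n_blocks)
    sizes[: m % n_blocks] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [np.arange(edges[b], edges[b + 1]) for b in range(n_blocks)]


class HasemanElstonModel:
    """Haseman-Elston regression of phenotype cross-products on kinship.

    The estimator regresses y_i * y_j (i < j) on the off-diagonal entries
    of the genetic relatedness matrix A = Z Z' / M built from
    column-standardized genotypes Z, without intercept (y standardized):

        h2 = sum_{i<j} A_ij y_i y_j / sum_{i<j} A_ij^2

    Standard errors come from a delete-one-block jackknife over ``n_blocks``
    contiguous variant blocks, mirroring genome-block resampling.  All
    quantities are accumulated through M x M cross-products, so the n x n
    relatedness matrix is never materialized.
    """

    def __init__(
        self,
        genotypes: GenotypeSet | np.ndarray,
        phenotype: np.ndarray,
        n_blocks: int = 200,
    ):
        dos = genotypes.dosages if isinstance(genotypes, GenotypeSet) else np.asarray(genotypes, float)
        y = np.asarray(phenotype, float)
        ok = ~np.isnan(y)
        dos, y = dos[ok], y[ok]
        if dos.shape[1] < n_blocks:
            raise ConfigurationError(
                f"n_blocks ({n_blocks}) exceeds number of variants ({dos.shape[1]})"
            )
        d = np.array(dos, float)  # mean-impute missing calls
        col_means = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d[idx] = np.take(col_means, idx[1])
        sd = d.std(axis=0, ddof=0)
        keep = sd > 0
        d, sd = d[:, keep], sd[keep]
        self.Z = (d - d.mean(axis=0)) / sd
        sy = y.std(ddof=0)
        if not sy > 0:
            raise DataError("phenotype has zero variance")
        self.y = (y - y.mean()) / sy
        self.n, self.m = self.Z.shape
        self.n_blocks = n_blocks
        self.blocks = _contiguous_blocks(self.m, n_blocks)

    @staticmethod
    def _h2(uu: float, cc: float, r: np.ndarray, y2: np.ndarray, m: int) -> float:
        # off-diagonal HE ratio from aggregate cross-products:
        #   y'Ay = uu/m ; diag_i = r_i/m ; ||A||_F^2 = cc/m^2
        num = (uu / m - np.dot(r, y2) / m) / 2.0
        den = (cc / m**2 - np.dot(r / m, r / m)) / 2.0
        return num / den

    def fit(self) -> "HEResults":
        Z, y = self.Z, self.y
        u = Z.T @ y                      # (m,)
        C = Z.T @ Z                      # (m, m)
        r = (Z**2).sum(axis=1)           # (n,) diagonal row sums
        y2 = y**2
        uu_full = float(u @ u)
        colsq = (C**2).sum(axis=0)       # squared column norms of C
        cc_full = float(colsq.sum())
        h2 = self._h2(uu_full, cc_full, r, y2, self.m)

        loo = np.empty(self.n_blocks)
        for b, idx in enumerate(self.blocks):
            mb = len(idx)
            uu = uu_full - float(u[idx] @ u[idx])
            # ||C'||_F^2 after deleting block rows+cols
            sub = C[np.ix_(idx, idx)]
            cc = cc_full - 2.0 * float(colsq[idx].sum()) + float((sub**2).sum())
            rb = (Z[:, idx] ** 2).sum(axis=1)
            loo[b] = self._h2(uu, cc, r - rb, y2, self.m - mb)
        B = self.n_blocks
        se = float(np.sqrt((B - 1) / B * ((loo - loo.mean()) ** 2).sum()))
        return HEResults(h2=float(h2), se=se, block_estimates=loo, n=self.n, m=self.m)


@dataclass
class HEResults:
    """Haseman-Elston heritability estimate with jackknife uncertainty."""

    h2: float
    se: float
    block_estimates: np.ndarray  # leave-one-block-out estimates
    n: int
    m: int

    @property
    def ci(self) -> tuple[float, float]:
        return (self.h2 - 1.96 * self.se, self.h2 + 1.96 * self.se)

    def summary(self) -> str:
        lo, hi = self.ci
        return (
            f"HE h2 = {self.h2:.4f} (se {self.se:.4f}, 95% CI [{lo:.4f}, {hi:.4f}]); "
            f"n = {self.n}, M = {self.m}, {len(self.block_estimates)} jackknife blocks"
        )


def he_h2(
    genotypes: GenotypeSet | np.ndarray,
    phenotype: np.ndarray,
    n_blocks: int = 200,
) -> HEResults:
    """Fit :class:`HasemanElstonModel` and return its results."""
    return HasemanElstonModel(genotypes, phenotype, n_blocks=n_blocks).fit()


@dataclass
class H2Contrast:
    """Paired heritability contrast between repeated- and single-measure scans."""

    h2_repeated: float
    h2_single: float
    se_repeated: float
    se_single: float
    jackknife_r: float
    suppressed: bool  # both h2 below the reporting floor

    @property
    def h2_diff(self) -> float:
        return self.h2_repeated - self.h2_single

    @property
    def se_diff(self) -> float:
        var = (
            self.se_repeated**2
            + self.se_single**2
            - 2.0 * self.jackknife_r * self.se_repeated * self.se_single
        )
        return float(np.sqrt(max(var, 0.0)))

    @property
    def z(self) -> float:
        if self.se_diff == 0.0:
            return 0.0 if self.h2_diff == 0.0 else float("inf")
        return self.h2_diff / self.se_diff

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))

    def summary(self) -> str:
        flag = " [suppressed: both h2 < 2%]" if self.suppressed else ""
        return (
            f"h2 repeated {self.h2_repeated:.4f} vs single {self.h2_single:.4f}: "
            f"diff {self.h2_diff:+.4f} (se {self.se_diff:.4f}, r {self.jackknife_r:.3f}), "
            f"Z = {self.z:.3f}, p = {self.p:.3g}{flag}"
        )


def h2_contrast(
    repeated: HEResults, single: HEResults, min_h2: float = 0.02
) -> H2Contrast:
    """Heritability-difference Z test from paired block-jackknife estimates.

    The correlation r(h2_R, h2_S) is the Pearson correlation of the paired
    leave-one-block-out estimates; the contrast is flagged as suppressed
    when both heritabilities fall below ``min_h2``.
    """
    if len(repeated.block_estimates) != len(single.block_estimates):
        raise DataError(
            "mismatched jackknife block counts: "
            f"{len(repeated.block_estimates)} vs {len(single.block_estimates)}"
        )
    r = float(np.corrcoef(repeated.block_estimates, single.block_estimates)[0, 1])
    return H2Contrast(
        h2_repeated=repeated.h2,
        h2_single=single.h2,
        se_repeated=repeated.se,
        se_single=single.se,
        jackknife_r=r,
        suppressed=(repeated.h2 < min_h2 and single.h2 < min_h2),
    )


@dataclass
class MRResult:
    """Inverse-variance-weighted Mendelian-randomization estimate."""

    estimate: float
    se: float
    n_instruments: int
    p_threshold: float = 5e-8
    clump_window_kb: float = 10_000.0
    clump_r2: float = 0.001

    @property
    def ci(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.estimate / self.se)))

    def summary(self) -> str:
        lo, hi = self.ci
        return (
            f"IVW estimate {self.estimate:.4f} (se {self.se:.4f}, "
            f"95% CI [{lo:.4f}, {hi:.4f}]) from {self.n_instruments} instruments"
        )


MIN_INSTRUMENTS = 5


def ivw_estimate(
    beta_exposure: np.ndarray,
    beta_outcome: np.ndarray,
    se_outcome: np.ndarray,
) -> MRResult:
    """Fixed-effect IVW estimate over per-instrument Wald ratios.

    estimate = sum(w_j * beta_out_j / beta_exp_j) / sum(w_j) with
    w_j = (beta_exp_j / se_out_j)^2; with standardized inputs the estimate
    is on the standardized (alpha_std) scale.  Requires >= 5 instruments.
    """
    be = np.asarray(beta_exposure, float)
    bo = np.asarray(beta_outcome, float)
    so = np.asarray(se_outcome, float)
    if not (len(be) == len(bo) == len(so)):
        raise DataError("instrument vectors must have equal length")
    if len(be) < MIN_INSTRUMENTS:
        raise InsufficientDataError(
            f"need at least {MIN_INSTRUMENTS} genetic instruments, got {len(be)}"
        )
    w = (be / so) ** 2
    est = float(np.sum(w * (bo / be)) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return MRResult(estimate=est, se=se, n_instruments=len(be))


def select_instruments(
    assoc: pd.DataFrame,
    dosages: np.ndarray,
    p_threshold: float = 5e-8,
    window_kb: float = 10_000.0,
    r2_threshold: float = 0.001,
) -> list[int]:
    """Instrument selection for MR: genome-wide-significant, strictly clumped."""
    return clump(
        assoc,
        dosages=dosages,
        p_threshold=p_threshold,
        window_kb=window_kb,
        r2_threshold=r2_threshold,
    )


def fdr_correct(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg FDR at ``alpha``: (reject mask, adjusted p-values)."""
    reject, p_adj, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return reject, p_adj
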