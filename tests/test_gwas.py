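"""Variant QC, association scans, clumping, HE heritability and IVW MR."""

from math import factorial

import numpy as np
import pandas as pd
import pytest

import reperr as rp
from reperr.exceptions import ConfigurationError, DataError, InsufficientDataError
from reperr.gwas import QC_THRESHOLDS, _ld_r2


def hwe_oracle(n_aa, n_ab, n_bb):
    """Independent exact-test oracle via integer enumeration of het counts."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def weight(nab):
        naa2 = n_a - nab
        if naa2 < 0 or naa2 % 2:
            return 0
        naa = naa2 // 2
        nbb = n - nab - naa
        if nbb < 0:
            return 0
        return (
            factorial(n) // (factorial(naa) * factorial(nab) * factorial(nbb))
        ) * 2**nab

    ws = {h: weight(h) for h in range(n + 1) if weight(h) > 0}
    tot = sum(ws.values())
    p_obs = ws[n_ab]
    return sum(w for w in ws.values() if w <= p_obs) / tot


class TestHWEExactTest:
    def test_equilibrium_proportions_not_rejected(self):
        assert rp.hwe_exact_test(2500, 5000, 2500) > 0.9

    @pytest.mark.parametrize(
        "counts",
        [(5, 10, 5), (20, 5, 20), (0, 10, 0), (7, 1, 2), (50, 21, 29), (3, 0, 3)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert rp.hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-9)

    def test_gross_heterozygote_excess_rejected(self):
        assert rp.hwe_exact_test(0, 200, 0) < 1e-15


class TestVariantQC:
    def test_pass_iff_all_criteria(self, toy_genotypes):
        gset, _ = toy_genotypes
        report = rp.variant_qc(gset)
        manual = (
            (report.hwe_p > QC_THRESHOLDS["hwe_p_min"])
            & (report.maf > QC_THRESHOLDS["maf_min"])
            & (report.mac > QC_THRESHOLDS["mac_min"])
            & (report.call_rate > QC_THRESHOLDS["call_rate_min"])
        )
        assert (report["pass"] == manual).all()

    def test_rare_variant_fails_maf_filter(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.005, size=(20_000, 1)).astype(float)
        report = rp.variant_qc(dos)
        assert report.maf[0] < 0.01 and not report["pass"][0]

    def test_monomorphic_variant_fails_quietly(self):
        report = rp.variant_qc(np.zeros((500, 1)))
        assert report.maf[0] == 0.0 and not report["pass"][0]

    def test_low_call_rate_fails(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, 0.3, size=(5_000, 1)).astype(float)
        dos[: 1_000, 0] = np.nan  # 80% call rate
        report = rp.variant_qc(dos)
        assert report.call_rate[0] == pytest.approx(0.8)
        assert not report["pass"][0]


class TestAssociationScan:
    def test_beta_std_identity(self, toy_genotypes):
        gset, pheno = toy_genotypes
        scan = rp.association_scan(gset, pheno)
        ok = ~scan.skipped
        np.testing.assert_allclose(
            scan.beta_std[ok] * np.sqrt(scan.n[ok]), scan.z[ok], atol=1e-10
        )
        assert (scan.r2_snp[ok] >= 0).all()

    def test_causal_variant_recovered(self):
        rng = np.random.default_rng(2)
        n = 10_000
        g = rng.binomial(2, 0.4, n).astype(float)
        z = (g - g.mean()) / g.std()
        beta_std_true = 0.05
        y = beta_std_true * z + np.sqrt(1 - beta_std_true**2) * rng.standard_normal(n)
        scan = rp.association_scan(g[:, None], y)
        assert abs(scan.beta_std[0] - beta_std_true) < 3 / np.sqrt(n)

    def test_constant_dosage_skipped(self):
        y = np.random.default_rng(3).normal(size=100)
        scan = rp.association_scan(np.ones((100, 1)), y)
        assert scan.skipped[0] and np.isnan(scan.beta[0])

    def test_covariate_adjustment_removes_confounding(self):
        rng = np.random.default_rng(4)
        n = 5_000
        confounder = rng.standard_normal(n)
        g = rng.binomial(2, 0.3, n) + 0.8 * confounder  # dosage-like, confounded
        y = 0.5 * confounder + rng.standard_normal(n)
        raw = rp.association_scan(g[:, None], y)
        adj = rp.association_scan(g[:, None], y, covariates=confounder)
        assert raw.p[0] < 1e-6  # spurious hit
        assert adj.p[0] > 0.01  # gone after adjustment


class TestClump:
    def test_single_significant_variant(self):
        assoc = pd.DataFrame(
            {"p": [1e-10, 0.5], "pos": [100_000, 200_000], "chrom": [1, 1]}
        )
        idx = rp.clump(assoc, ld_r2=np.eye(2))
        assert idx == [0]

    def test_perfect_ld_pair_collapses_to_smaller_p(self):
        assoc = pd.DataFrame(
            {"p": [1e-10, 1e-12], "pos": [100_000, 150_000], "chrom": [1, 1]}
        )
        ld = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert rp.clump(assoc, ld_r2=ld) == [1]

    def test_five_variant_manual_trace(self):
        # greedy trace: v3 (p=1e-20) indexes and absorbs v2 (20 kb, r2=0.9);
        # v0 (p=1e-12) indexes and absorbs v1 (100 kb, r2=0.8); v4 not significant
        assoc = pd.DataFrame(
            {
                "p": [1e-12, 1e-10, 1e-9, 1e-20, 0.5],
                "pos": [100_000, 200_000, 600_000, 620_000, 900_000],
                "chrom": [1, 1, 1, 1, 1],
            }
        )
        ld = np.eye(5)
        ld[0, 1] = ld[1, 0] = 0.8
        ld[2, 3] = ld[3, 2] = 0.9
        assert rp.clump(assoc, ld_r2=ld) == [3, 0]

    def test_window_limits_assignment(self):
        # high LD but outside the window: both stay index variants
        assoc = pd.DataFrame(
            {"p": [1e-12, 1e-10], "pos": [100_000, 900_000], "chrom": [1, 1]}
        )
        ld = np.array([[1.0, 0.95], [0.95, 1.0]])
        assert rp.clump(assoc, ld_r2=ld, window_kb=250) == [0, 1]

    def test_ld_from_dosages(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.5, size=(2_000, 2)).astype(float)
        g[:, 1] = g[:, 0]  # perfect LD
        r2 = _ld_r2(g)
        assert r2[0, 1] == pytest.approx(1.0)


class TestRepeatedPhenotype:
    def test_identical_occasions(self):
        x = np.array([1.0, 2.0, np.nan])
        out = rp.make_repeated_phenotype(x, x)
        np.testing.assert_array_equal(out[:2], x[:2])
        assert np.isnan(out[2])

    def test_error_variance_halves(self):
        rng = np.random.default_rng(6)
        n = 500_000
        true = rng.standard_normal(n)
        sigma = 0.8
        m = rp.make_repeated_phenotype(
            true + rng.normal(0, sigma, n), true + rng.normal(0, sigma, n)
        )
        assert (m - true).var() == pytest.approx(sigma**2 / 2, rel=0.02)

    def test_spearman_brown_reliability(self):
        # reliability of the two-occasion mean is 2*rho/(1+rho)
        rho = 0.5
        cfg = rp.CohortConfig(
            n_individuals=200_000,
            seed=31,
            phenotypes=(rp.PhenotypeSpec("x", reliability=rho),),
        )
        d = rp.generate_cohort(cfg).data
        m = rp.make_repeated_phenotype(d["x_t1"].to_numpy(), d["x_t2"].to_numpy())
        rel = d["x_true"].var() / m.var()
        assert rel == pytest.approx(2 * rho / (1 + rho), abs=0.01)


class TestHasemanElston:
    def test_null_phenotype_estimate_near_zero(self):
        gset, _ = rp.generate_genotypes(1_500, 150, h2_true=0.0, seed=41)
        y = np.random.default_rng(42).standard_normal(1_500)
        res = rp.he_h2(gset, y, n_blocks=25)
        # 3.5-s.e. band (a plain 95% CI check fails 1 in 20 runs)
        assert abs(res.h2) < 3.5 * res.se

    def test_recovers_generative_h2(self, toy_genotypes):
        gset, pheno = toy_genotypes
        res = rp.he_h2(gset, pheno, n_blocks=25)
        assert abs(res.h2 - 0.3) < 3 * res.se

    def test_doubled_noise_attenuates_by_variance_ratio(self, toy_genotypes):
        # adding an extra unit of noise: genetic variance h2 out of total
        # 2 - h2 + h2 = 2, so the estimate drops to h2_true / 2
        gset, pheno = toy_genotypes
        rng = np.random.default_rng(43)
        noisy = pheno + rng.standard_normal(len(pheno))
        res = rp.he_h2(gset, noisy, n_blocks=25)
        assert abs(res.h2 - 0.3 / 2) < 3 * res.se

    def test_leave_one_out_consistency(self, toy_genotypes):
        # leave-one-block-out estimates computed via aggregate cross-products
        # must match a direct refit without that block
        gset, pheno = toy_genotypes
        model = rp.HasemanElstonModel(gset, pheno, n_blocks=10)
        res = model.fit()
        drop = model.blocks[3]
        keep = np.setdiff1d(np.arange(gset.n_variants), drop)
        direct = rp.he_h2(gset.dosages[:, keep], pheno, n_blocks=9)
        assert res.block_estimates[3] == pytest.approx(direct.h2, abs=1e-10)

    def test_too_many_blocks_raises(self, toy_genotypes):
        gset, pheno = toy_genotypes
        with pytest.raises(ConfigurationError):
            rp.he_h2(gset, pheno, n_blocks=gset.n_variants + 1)

    def test_jackknife_se_calibrated_across_seeds(self):
        # jackknife s.e. should approximate the across-seed spread; effects
        # are drawn fresh per seed (no in-sample rescaling) so the spread
        # includes the effect-dispersion component the jackknife reports
        def draw(seed, n=3_000, m=200, h2=0.3):
            rng = np.random.default_rng(seed)
            d = rng.binomial(2, rng.uniform(0.05, 0.5, m), size=(n, m)).astype(float)
            z = (d - d.mean(0)) / d.std(0)
            beta = rng.normal(0, np.sqrt(h2 / m), m)
            return d, z @ beta + rng.normal(0, np.sqrt(1 - h2), n)

        ests, ses = [], []
        for seed in range(50):
            d, y = draw(1_000 + seed)
            res = rp.he_h2(d, y, n_blocks=40)
            ests.append(res.h2)
            ses.append(res.se)
        empirical_sd = np.std(ests, ddof=1)
        assert abs(np.mean(ses) - empirical_sd) < 0.3 * empirical_sd


class TestH2Contrast:
    def test_identical_blocks_give_zero_diff(self):
        blocks = np.random.default_rng(50).uniform(0.2, 0.4, 30)
        a = rp.HEResults(h2=0.3, se=0.02, block_estimates=blocks, n=100, m=60)
        b = rp.HEResults(h2=0.3, se=0.02, block_estimates=blocks.copy(), n=100, m=60)
        c = rp.h2_contrast(a, b)
        assert c.h2_diff == 0.0 and c.z == 0.0
        assert c.jackknife_r == pytest.approx(1.0)

    def test_hand_evaluated_formula(self):
        # se (0.02, 0.03), r = 0.5, diff = 0.05:
        # se(diff) = sqrt(0.0004 + 0.0009 - 0.0006), Z = 0.05 / that
        c = rp.H2Contrast(
            h2_repeated=0.30, h2_single=0.25,
            se_repeated=0.02, se_single=0.03,
            jackknife_r=0.5, suppressed=False,
        )
        assert c.se_diff == pytest.approx(np.sqrt(0.0007), abs=1e-12)
        assert c.z == pytest.approx(0.05 / np.sqrt(0.0007), abs=1e-10)

    def test_mismatched_block_counts_raise(self):
        a = rp.HEResults(0.3, 0.02, np.zeros(10), 100, 60)
        b = rp.HEResults(0.3, 0.02, np.zeros(12), 100, 60)
        with pytest.raises(DataError):
            rp.h2_contrast(a, b)

    def test_suppression_flag(self):
        blocks = np.full(10, 0.01) + np.linspace(0, 1e-3, 10)
        a = rp.HEResults(0.01, 0.005, blocks, 100, 60)
        b = rp.HEResults(0.005, 0.005, blocks * 0.5, 100, 60)
        assert rp.h2_contrast(a, b).suppressed


def _noisy_phenotypes(latent, reliability, rng):
    """Two error-laden observations of a latent trait at a given reliability."""
    err_var = latent.var() * (1 - reliability) / reliability
    t1 = latent + rng.normal(0, np.sqrt(err_var), len(latent))
    t2 = latent + rng.normal(0, np.sqrt(err_var), len(latent))
    return t1, t2


class TestSingleVsRepeatedMeasureScans:
    def test_repeated_measure_raises_h2_at_low_reliability(self):
        # childhood-recall-like phenotype: reliability 0.55, h2_true 0.3
        gset, latent = rp.generate_genotypes(5_000, 200, h2_true=0.3,
                                             n_causal=50, seed=61)
        t1, t2 = _noisy_phenotypes(latent, 0.55, np.random.default_rng(62))
        single = rp.he_h2(gset, t1, n_blocks=40)
        repeated = rp.he_h2(gset, rp.make_repeated_phenotype(t1, t2), n_blocks=40)
        c = rp.h2_contrast(repeated, single)
        assert c.h2_diff > 0
        # attenuation follows the reliability: h2_single ~ 0.55 * 0.3
        assert abs(single.h2 - 0.55 * 0.3) < 3 * single.se

    def test_betas_match_but_ses_shrink(self):
        gset, latent = rp.generate_genotypes(3_000, 150, h2_true=0.3,
                                             n_causal=40, seed=63)
        # raw (unstandardized) phenotypes: per-variant slopes estimate the
        # same latent-trait effect either way, but the repeated measure has
        # less residual noise, so its standard errors shrink
        t1, t2 = _noisy_phenotypes(latent, 0.6, np.random.default_rng(64))
        scan_s = rp.association_scan(gset, t1)
        scan_r = rp.association_scan(gset, rp.make_repeated_phenotype(t1, t2))
        diffs = scan_r.beta - scan_s.beta
        # paired differences centred at zero
        assert abs(diffs.mean()) < 3 * diffs.std() / np.sqrt(len(diffs))
        # repeated-measure standard errors strictly smaller in median
        assert scan_r.se.median() < scan_s.se.median()

    def test_discovery_gain_with_repeated_measure(self):
        gset, latent = rp.generate_genotypes(4_000, 150, h2_true=0.5,
                                             n_causal=10, seed=65)
        t1, t2 = _noisy_phenotypes(latent, 0.5, np.random.default_rng(66))
        scan_s = rp.association_scan(gset, t1)
        scan_r = rp.association_scan(gset, rp.make_repeated_phenotype(t1, t2))
        thresh = 1e-4
        n_s = len(rp.clump(scan_s, dosages=gset.dosages, p_threshold=thresh))
        n_r = len(rp.clump(scan_r, dosages=gset.dosages, p_threshold=thresh))
        assert n_r >= n_s

    def test_h2_attenuation_tracks_reliability_grid(self):
        from scipy.stats import spearmanr

        gset, latent = rp.generate_genotypes(4_000, 200, h2_true=0.4,
                                             n_causal=50, seed=67)
        grid = [0.3, 0.5, 0.7, 0.9]
        h2_single, h2_diff, repeat_r2 = [], [], []
        for i, rel in enumerate(grid):
            rng = np.random.default_rng(70 + i)
            t1, t2 = _noisy_phenotypes(latent, rel, rng)
            s = rp.he_h2(gset, t1, n_blocks=40)
            r = rp.he_h2(gset, rp.make_repeated_phenotype(t1, t2), n_blocks=40)
            h2_single.append(s.h2)
            h2_diff.append(r.h2 - s.h2)
            pair = rp.PhenotypePair("x", t1, t2, rng.uniform(2, 10, len(t1)))
            repeat_r2.append(rp.fit_repeatability(pair).r2)
        assert spearmanr(grid, h2_single).statistic == 1.0
        # the heritability gap narrows as repeatability improves
        assert spearmanr(repeat_r2, h2_diff).statistic < 0


class TestIVW:
    def test_constant_ratio_recovered_exactly(self):
        be = np.array([0.1, 0.2, 0.15, 0.3, 0.25])
        res = rp.ivw_estimate(be, 0.4 * be, np.full(5, 0.01))
        assert res.estimate == pytest.approx(0.4, abs=1e-12)

    def test_four_instruments_refused(self):
        with pytest.raises(InsufficientDataError, match="got 4"):
            rp.ivw_estimate(np.ones(4), np.ones(4), np.ones(4))

    def test_generative_effect_recovered(self):
        rng = np.random.default_rng(80)
        n_inst, alpha = 20, 0.3
        be = rng.uniform(0.05, 0.3, n_inst)
        se = np.full(n_inst, 0.01)
        bo = alpha * be + rng.normal(0, se)
        res = rp.ivw_estimate(be, bo, se)
        assert abs(res.estimate - alpha) < 3 * res.se

    def test_instrument_selection_uses_strict_clumping(self):
        gset, latent = rp.generate_genotypes(4_000, 100, h2_true=0.5,
                                             n_causal=5, seed=81)
        scan = rp.association_scan(gset, latent)
        loose = rp.clump(scan, dosages=gset.dosages, p_threshold=1e-3,
                         window_kb=250, r2_threshold=0.1)
        strict = rp.select_instruments(scan, gset.dosages, p_threshold=1e-3)
        assert len(strict) <= len(loose)


class TestFDR:
    def test_null_pvalues_rarely_rejected(self):
        rng = np.random.default_rng(90)
        reject, p_adj = rp.fdr_correct(rng.uniform(size=500))
        assert reject.mean() < 0.02
        assert (p_adj >= np.sort(p_adj)[0]).all()
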