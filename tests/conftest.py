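import numpy as np
import pytest

import reperr as rp


@pytest.fixture(scope="session")
def het_pair():
    """Paired observations with covariate-driven (heteroskedastic) error.

    true ~ N(0,1); per-individual error s.d. 0.3 + 1.5*U(0,1); both
    occasions share the individual's error s.d.  Returns the pair plus the
    per-individual error variances (generative ground truth).
    """
    rng = np.random.default_rng(42)
    n = 20_000
    true = rng.standard_normal(n)
    sd_i = 0.3 + 1.5 * rng.random(n)
    t1 = true + sd_i * rng.standard_normal(n)
    t2 = true + sd_i * rng.standard_normal(n)
    pair = rp.PhenotypePair(
        name="het",
        values_t1=t1,
        values_t2=t2,
        followup_time=rng.uniform(2.0, 10.0, n),
    )
    return pair, sd_i**2


@pytest.fixture(scope="session")
def toy_genotypes():
    """Small genotype panel with a heritable phenotype (h2 = 0.3)."""
    gset, pheno = rp.generate_genotypes(
        n=2_000, n_variants=150, h2_true=0.3, n_causal=40, seed=7
    )
    return gset, pheno
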