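"""Shared fixtures: small simulated cohorts built once per session."""

import numpy as np
import pandas as pd
import pytest

from mtgrs import (
    SimConfig,
    GenotypeMatrix,
    marginal_gwas,
    simulate_genotypes,
    simulate_phenotypes,
)


def make_genotypes(counts: np.ndarray, chrom: str | list = "1") -> GenotypeMatrix:
    """Wrap a raw count matrix (NaN = missing) in a GenotypeMatrix."""
    counts = np.asarray(counts, dtype=np.float32)
    n, m = counts.shape
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    markers = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.arange(1, m + 1) * 100,
            "id": [f"m{j + 1}" for j in range(m)],
            "effect_allele": "A",
            "other_allele": "G",
            "af": np.nanmean(counts, axis=0) / 2.0,
            "missingness": np.isnan(counts).mean(axis=0),
        }
    )
    samples = np.array([f"s{i + 1}" for i in range(n)])
    return GenotypeMatrix(counts=counts, markers=markers, samples=samples)


@pytest.fixture(scope="session")
def two_trait_cohort():
    """n=500, m=200 cohort with one quantitative and one binary trait."""
    cfg = SimConfig(
        n_individuals=500,
        n_markers=200,
        block_size=20,
        within_block_rho=0.8,
        n_causal=80,
        h2=[0.5, 0.5],
        rg=np.array([[1.0, 0.6], [0.6, 1.0]]),
        trait_types=["quantitative", "binary"],
        prevalence=[np.nan, 0.2],
        seed=11,
    )
    G = simulate_genotypes(cfg)
    phenos = simulate_phenotypes(G, cfg)
    return cfg, G, phenos


@pytest.fixture(scope="session")
def linear_sumstats(two_trait_cohort):
    cfg, G, phenos = two_trait_cohort
    cov = phenos.covariates()
    return marginal_gwas(
        G, phenos.table["trait_1"].to_numpy(), cov, model="linear", trait="trait_1"
    )


@pytest.fixture(scope="session")
def random_genotypes():
    """60 samples x 30 independent markers, no missingness."""
    rng = np.random.default_rng(5)
    p = rng.uniform(0.1, 0.5, 30)
    counts = rng.binomial(2, p, size=(60, 30)).astype(np.float32)
    return make_genotypes(counts)
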