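"""Synthetic multi-trait GWAS cohorts.

Generates genotypes in blocks of linkage disequilibrium (LD) and k correlated
phenotypes under a standard additive polygenic model, so that every downstream
stage (association, LD-score regression, index weighting, scoring, evaluation)
can be exercised and validated without access-restricted cohort data.

Genotypes
---------
Each marker belongs to a block of ``block_size`` consecutive markers.  Two
independent latent Gaussian "haplotype" streams follow an AR(1) process with
parameter ``within_block_rho`` inside a block (the process restarts at block
boundaries, so across-block correlation is zero in expectation).  Each latent
value is thresholded at the standard-normal quantile of its marker's minor
allele frequency, and the two resulting alleles are summed to an allele count
in {0, 1, 2}.  This yields exact Hardy-Weinberg marginals at the drawn MAF and
a tunable, monotonically decaying within-block genotype correlation.

Phenotypes
----------
True per-marker effects for the k traits are drawn jointly at ``n_causal``
uniformly chosen markers with covariance (r_g)_kl * h_k * h_l / n_causal on
standardized genotypes, so the genetic values have variance h2_k per trait and
genetic correlation r_g between traits.  Independent Gaussian residuals bring
the genetic-plus-residual variance to 1.  Covariate effects (sex, age) shift
the liability before binary traits are produced by thresholding at the
quantile corresponding to the case prevalence K.

All randomness flows from a single integer seed through named child streams
(see :data:`_STREAMS`), so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "PhenotypeTable",
    "simulate_genotypes",
    "simulate_phenotypes",
    "split_folds",
]

# fixed order of child RNG streams spawned from the master seed
_STREAMS = ("genotypes", "missingness", "effects", "residuals", "covariates", "causal")


def _stream(seed: int, name: str) -> np.random.Generator:
    """Child generator for one named stage, derived from the master seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(name)])


@dataclass
class SimConfig:
    """Parameters of a simulated cohort.

    ``h2``, ``rg``, ``trait_types`` and ``prevalence`` are aligned k-vectors /
    k x k matrices; ``prevalence`` entries are ignored for quantitative traits.
    ``covariate_effects`` are liability-scale effects of (standardized) sex and
    age per trait, broadcastable to shape (k, 2).
    """

    n_individuals: int
    n_markers: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    block_size: int = 20
    within_block_rho: float | tuple[float, float] = (0.2, 0.95)
    n_causal: int = 100
    h2: Sequence[float] = (0.5,)
    rg: np.ndarray | None = None
    trait_types: Sequence[str] = ("quantitative",)
    prevalence: Sequence[float] | None = None
    covariate_effects: np.ndarray | float = 0.1
    missing_rate: float = 0.005
    seed: int = 0
    trait_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.h2 = np.asarray(self.h2, dtype=float)
        k = self.h2.size
        if self.rg is None:
            self.rg = np.eye(k)
        self.rg = np.asarray(self.rg, dtype=float)
        if self.trait_names is None:
            self.trait_names = [f"trait_{i + 1}" for i in range(k)]
        if self.prevalence is None:
            self.prevalence = [np.nan] * k
        self.covariate_effects = np.broadcast_to(
            np.asarray(self.covariate_effects, dtype=float), (k, 2)
        ).copy()
        self._validate()

    @property
    def k(self) -> int:
        return int(self.h2.size)

    def _validate(self) -> None:
        if self.n_markers <= 0:
            raise ValueError("n_markers must be positive")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        rho = np.atleast_1d(np.asarray(self.within_block_rho, dtype=float))
        if np.any((rho < 0) | (rho >= 1)) or rho.size > 2:
            raise ValueError("within_block_rho must be in [0, 1) (scalar or (lo, hi) range)")
        if not 1 <= self.n_causal <= self.n_markers:
            raise ValueError("n_causal must be in [1, n_markers]")
        if np.any((self.h2 < 0) | (self.h2 > 1)):
            raise ValueError("h2 entries must be in [0, 1]")
        rg = self.rg
        if rg.shape != (self.k, self.k):
            raise ValueError("rg must be k x k")
        if not np.allclose(rg, rg.T) or not np.allclose(np.diag(rg), 1.0):
            raise ValueError("rg must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(rg).min() < -1e-8:
            raise ValueError("rg must be positive semi-definite")
        if len(self.trait_types) != self.k:
            raise ValueError("trait_types length must equal k")
        for t, K in zip(self.trait_types, self.prevalence):
            if t == "binary" and not (0 < K < 1):
                raise ValueError("binary traits need prevalence K in (0, 1)")
            if t not in ("quantitative", "binary"):
                raise ValueError(f"unknown trait type {t!r}")


@dataclass
class GenotypeMatrix:
    """n x m allele-count matrix with per-marker metadata.

    ``counts`` holds effect-allele counts in {0, 1, 2} as float with NaN for
    missing entries.  ``markers`` carries chrom, pos, id, effect_allele,
    other_allele, af (effect-allele frequency on non-missing entries) and
    missingness.  ``samples`` is the ordered sample-id vector.
    """

    counts: np.ndarray
    markers: pd.DataFrame
    samples: np.ndarray

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Effect-allele frequency recomputed from non-missing counts."""
        return np.nanmean(self.counts, axis=0) / 2.0

    def missingness(self) -> np.ndarray:
        return np.isnan(self.counts).mean(axis=0)

    def standardized(self) -> np.ndarray:
        """Mean-imputed, column-standardized copy (float64).

        Monomorphic columns come back as all-zero rather than dividing by a
        zero standard deviation.
        """
        x = np.array(self.counts, dtype=float)
        mu = np.nanmean(x, axis=0)
        inds = np.where(np.isnan(x))
        x[inds] = np.take(mu, inds[1])
        x -= mu
        sd = x.std(axis=0)
        sd[sd == 0] = np.inf
        return x / sd

    def subset_markers(self, index) -> "GenotypeMatrix":
        """New matrix restricted to a marker index (bool mask or positions)."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            counts=self.counts[:, idx],
            markers=self.markers.iloc[idx].reset_index(drop=True),
            samples=self.samples,
        )

    def subset_samples(self, index) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        cnt = self.counts[idx]
        mk = self.markers.copy()
        mk["af"] = np.nanmean(cnt, axis=0) / 2.0
        mk["missingness"] = np.isnan(cnt).mean(axis=0)
        return GenotypeMatrix(counts=cnt, markers=mk, samples=self.samples[idx])


@dataclass
class PhenotypeTable:
    """Phenotypes and covariates aligned to a GenotypeMatrix.

    ``table`` has one row per sample: trait columns, sex (0/1), age, pc1..pc10
    placeholders (constant zero) and, once assigned, a fold column.  The true
    generative quantities (genetic values, causal effects) are carried for
    validation and are not part of the on-disk format.
    """

    table: pd.DataFrame
    traits: list[str]
    trait_types: list[str]
    genetic_values: np.ndarray = field(repr=False, default=None)
    true_effects: np.ndarray = field(repr=False, default=None)
    causal_index: np.ndarray = field(repr=False, default=None)

    @property
    def samples(self) -> np.ndarray:
        return self.table["sample_id"].to_numpy()

    def covariates(self, names: Sequence[str] = ("sex", "age")) -> pd.DataFrame:
        return self.table[list(names)]


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw an LD-blocked genotype matrix. Deterministic under ``cfg.seed``."""
    rng = _stream(cfg.seed, "genotypes")
    n, m, bs = cfg.n_individuals, cfg.n_markers, cfg.block_size
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)

    # per-block AR(1) parameter: scalar, or drawn from a (lo, hi) range so
    # that LD strength -- and hence the LD-score spread -- varies along the
    # genome the way real linkage maps do
    n_blocks = (m + bs - 1) // bs
    rho_spec = np.atleast_1d(np.asarray(cfg.within_block_rho, dtype=float))
    if rho_spec.size == 1:
        block_rho = np.full(n_blocks, rho_spec[0])
    else:
        block_rho = rng.uniform(rho_spec[0], rho_spec[1], size=n_blocks)

    # two latent AR(1) haplotype streams, restarted at every block boundary
    eps = rng.standard_normal((2, n, m))
    lat = np.empty_like(eps)
    for j in range(m):
        if j % bs == 0:
            lat[:, :, j] = eps[:, :, j]
        else:
            rho = block_rho[j // bs]
            lat[:, :, j] = rho * lat[:, :, j - 1] + np.sqrt(1.0 - rho**2) * eps[:, :, j]

    thresh = stats.norm.isf(maf)  # allele carried iff latent exceeds this
    counts = ((lat[0] > thresh).astype(np.float32) + (lat[1] > thresh)).astype(np.float32)

    if cfg.missing_rate > 0:
        miss_rng = _stream(cfg.seed, "missingness")
        mask = miss_rng.random((n, m)) < cfg.missing_rate
        counts[mask] = np.nan

    markers = pd.DataFrame(
        {
            "chrom": np.repeat("1", m),
            "pos": np.arange(1, m + 1) * 1000,
            "id": [f"snp_{j + 1:06d}" for j in range(m)],
            "effect_allele": "A",
            "other_allele": "G",
            "maf": maf,
            "af": np.nanmean(counts, axis=0) / 2.0,
            "missingness": np.isnan(counts).mean(axis=0),
        }
    )
    samples = np.array([f"id_{i + 1:06d}" for i in range(n)])
    return GenotypeMatrix(counts=counts, markers=markers, samples=samples)


def _psd_normal(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """Multivariate normal draws tolerating a singular covariance."""
    return rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=size, method="eigh")


def simulate_phenotypes(G: GenotypeMatrix, cfg: SimConfig) -> PhenotypeTable:
    """Draw k correlated traits on top of a genotype matrix.

    Liability for trait t is  g_t + c_sex*sex' + c_age*age' + e_t  with
    var(g_t)=h2_t, var(e_t)=1-h2_t and primed covariates standardized.  Binary
    traits threshold the liability at the (1-K) quantile of its theoretical
    normal distribution, so the realized case fraction is binomial around K.
    """
    if G.m != cfg.n_markers or G.n != cfg.n_individuals:
        raise ValueError("genotype matrix dimensions do not match cfg")
    k = cfg.k
    n = G.n
    h = np.sqrt(cfg.h2)
    sigma = cfg.rg * np.outer(h, h)

    causal_rng = _stream(cfg.seed, "causal")
    causal = np.sort(causal_rng.choice(G.m, size=cfg.n_causal, replace=False))

    eff_rng = _stream(cfg.seed, "effects")
    beta = _psd_normal(eff_rng, sigma / cfg.n_causal, size=cfg.n_causal)  # (n_causal, k)

    W = G.standardized()[:, causal]
    gvals = W @ beta  # (n, k)

    cov_rng = _stream(cfg.seed, "covariates")
    sex = cov_rng.integers(0, 2, size=n).astype(float)
    age = cov_rng.normal(56.4, 8.0, size=n)
    sex_s = (sex - sex.mean()) / max(sex.std(), 1e-12)
    age_s = (age - age.mean()) / age.std()

    res_rng = _stream(cfg.seed, "residuals")
    resid = res_rng.standard_normal((n, k)) * np.sqrt(np.clip(1.0 - cfg.h2, 0.0, None))

    ce = cfg.covariate_effects
    liability = gvals + resid + sex_s[:, None] * ce[:, 0] + age_s[:, None] * ce[:, 1]

    data = {"sample_id": G.samples, "sex": sex, "age": age}
    for t in range(k):
        name = cfg.trait_names[t]
        if cfg.trait_types[t] == "binary":
            K = cfg.prevalence[t]
            sd_tot = np.sqrt(1.0 + ce[t, 0] ** 2 + ce[t, 1] ** 2)
            cut = stats.norm.isf(K) * sd_tot
            data[name] = (liability[:, t] > cut).astype(float)
        else:
            data[name] = liability[:, t]
    table = pd.DataFrame(data)
    for j in range(1, 11):  # principal-component placeholders, constant zero
        table[f"pc{j}"] = 0.0

    return PhenotypeTable(
        table=table,
        traits=list(cfg.trait_names),
        trait_types=list(cfg.trait_types),
        genetic_values=gvals,
        true_effects=beta,
        causal_index=causal,
    )


def split_folds(samples: Sequence, k_folds: int, seed: int) -> np.ndarray:
    """Partition samples into k_folds disjoint near-equal folds.

    Returns an integer fold id (0..k_folds-1) per sample, in sample order.
    Fold sizes differ by at most one; deterministic under ``seed``.
    """
    n = len(samples)
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    if k_folds > n:
        raise ValueError("k_folds cannot exceed the number of samples")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k_folds)):
        fold[chunk] = f
    return fold
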