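"""Bias-adjusted LD, windowed LD scores, and summary-statistic estimation of
heritability and genetic correlation.

The squared Pearson correlation between two genotype columns is upward-biased
in finite samples; the adjusted estimator

    r~2 = r2 - (1 - r2) / (N - 2)

is used throughout.  The LD score of marker i is the sum of r~2 over a window
of markers centred on i (``window`` markers in total, i.e. +/- window//2,
truncated at chromosome boundaries, never spanning chromosomes), including the
self term r~2(i,i) = 1.

Heritability is the no-intercept least-squares regression of squared z-scores
y = (beta/se)^2 on Z = n_eff * l / m; the genetic correlation between two
traits regresses the z-score product on sqrt(n1*n2) * l / m and rescales by
sqrt(h2_1 * h2_2).  Both estimators are implemented in this literal
no-intercept form by default.  Because E[chi^2] carries a unit baseline under
the null, two refinements are provided: ``baseline`` subtracts a known null
level from y before the no-intercept solve (1.0 for chi-squared statistics;
the sample-overlap offset for z-products) — the pipeline default — and
``intercept=True`` frees the intercept, the form canonical LD-score
regression uses to absorb confounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import SummaryStats
from .simulate import GenotypeMatrix

__all__ = [
    "LDScoreTrack",
    "GeneticParams",
    "adjusted_r2",
    "ld_scores",
    "estimate_n_eff",
    "estimate_h2",
    "estimate_rg",
    "observed_to_liability",
    "estimate_genetic_params",
]

#: heritability floor applied when an estimate feeds weight construction
H2_FLOOR = 1e-6


@dataclass
class LDScoreTrack:
    """Per-marker LD scores with the window parameters that produced them."""

    table: pd.DataFrame  # columns: id, chrom, pos, l
    window: int
    n_ref: int

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not np.isfinite(self.table["l"]).all():
            raise ValueError("LD scores must be finite")

    @property
    def l(self) -> np.ndarray:
        return self.table["l"].to_numpy()


@dataclass
class GeneticParams:
    """Per-trait h2 and n_eff plus the k x k genetic-correlation matrix.

    ``rg`` is clamped to [-1, 1]; the raw regression estimates are kept in
    ``rg_raw``.  ``scale`` records whether binary-trait h2 is on the observed
    or liability scale.
    """

    traits: list[str]
    h2: np.ndarray
    n_eff: np.ndarray
    rg: np.ndarray
    rg_raw: np.ndarray = None
    scale: str = "observed"

    def __post_init__(self) -> None:
        if self.rg_raw is None:
            self.rg_raw = self.rg.copy()
        self.rg = np.clip(self.rg_raw, -1.0, 1.0)
        np.fill_diagonal(self.rg, 1.0)
        if not np.allclose(self.rg, self.rg.T):
            raise ValueError("rg must be symmetric")


def adjusted_r2(x, z, n: int | None = None) -> float:
    """Bias-adjusted squared Pearson correlation of two genotype columns.

    Computed on pairwise-complete samples; ``n`` defaults to the number of
    complete pairs and must exceed 2.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(z))
    xs, zs = x[mask], z[mask]
    if n is None:
        n = xs.size
    if n <= 2:
        raise ValueError("need more than 2 samples for the bias adjustment")
    if np.ptp(xs) == 0 or np.ptp(zs) == 0:
        raise ValueError("constant column: correlation undefined")
    r = np.corrcoef(xs, zs)[0, 1]
    r2 = r * r
    return float(r2 - (1.0 - r2) / (n - 2))


def _band_adjusted_r2(Zn: np.ndarray, n: int, a: int, b: int, lo: int, hi: int) -> np.ndarray:
    """Adjusted r2 of markers [a,b) against markers [lo,hi) from unit-norm columns."""
    R = Zn[:, a:b].T @ Zn[:, lo:hi]
    r2 = R * R
    return r2 - (1.0 - r2) / (n - 2)


def ld_scores(G: GenotypeMatrix, window: int = 5000, chunk_size: int = 512) -> LDScoreTrack:
    """Windowed LD scores l_i = sum over the window of adjusted r2 with i.

    The window holds ``window`` markers centred on i (+/- window//2), truncated
    at chromosome ends; the self term contributes exactly 1.  Genotypes are
    mean-imputed before standardization; monomorphic markers get l = 1.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = G.n
    if n <= 2:
        raise ValueError("need more than 2 samples")
    half = window // 2

    X = G.standardized()
    norms = np.sqrt((X * X).sum(0))
    norms[norms == 0] = np.inf
    Zn = X / norms  # unit-norm columns: dot products are Pearson r

    l = np.ones(G.m)
    chroms = G.markers["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        first, last = idx[0], idx[-1]
        if not np.array_equal(idx, np.arange(first, last + 1)):
            raise ValueError("markers of one chromosome must be contiguous")
        mc = idx.size
        Zc = Zn[:, first:last + 1]
        mono = np.isinf(norms[first:last + 1])
        for a in range(0, mc, chunk_size):
            b = min(a + chunk_size, mc)
            lo = max(0, a - half)
            hi = min(mc, b + half)
            band = _band_adjusted_r2(Zc, n, a, b, lo, hi)
            # prefix sums let each marker read off its own window slice
            cs = np.concatenate([np.zeros((b - a, 1)), np.cumsum(band, axis=1)], axis=1)
            for row, i in enumerate(range(a, b)):
                w0 = max(0, i - half) - lo
                w1 = min(mc, i + half + 1) - lo
                l[first + i] = cs[row, w1] - cs[row, w0] - band[row, i - lo] + 1.0
        l[first:last + 1][mono] = 1.0

    table = G.markers[["id", "chrom", "pos"]].copy()
    table["l"] = l
    return LDScoreTrack(table=table, window=window, n_ref=n)


def estimate_n_eff(ss: SummaryStats) -> float:
    """Effective sample size: median over markers of 1 / (2 af (1-af) se^2)."""
    t = ss.valid_table()
    af = t["af"].to_numpy()
    se = t["se"].to_numpy()
    ok = (af > 0) & (af < 1) & (se > 0) & np.isfinite(se)
    if not ok.any():
        raise ValueError("no markers with valid allele frequency and SE")
    return float(np.median(1.0 / (2.0 * af[ok] * (1.0 - af[ok]) * se[ok] ** 2)))


def _align(ss: SummaryStats, ld: LDScoreTrack) -> pd.DataFrame:
    merged = ss.table.merge(ld.table[["id", "l"]], on="id", how="inner")
    merged = merged[merged["valid"] & np.isfinite(merged["se"]) & (merged["se"] > 0)]
    if merged.empty:
        raise ValueError("no valid markers shared between summary stats and LD scores")
    return merged


def _slope(Z: np.ndarray, y: np.ndarray, intercept: bool, baseline: float) -> float:
    if intercept:
        X = np.column_stack([np.ones_like(Z), Z])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(coef[1])
    denom = float(Z @ Z)
    if denom == 0:
        raise ValueError("regressor is identically zero")
    return float(Z @ (y - baseline) / denom)


def estimate_h2(
    ss: SummaryStats,
    ld: LDScoreTrack,
    m: int,
    n_eff: float | None = None,
    intercept: bool = False,
    baseline: float = 0.0,
) -> float:
    """Heritability from the regression of squared z-scores on n_eff * l / m.

    ``baseline`` is a known null level subtracted from y before the
    no-intercept solve (chi-squared statistics have mean 1 under the null, so
    ``baseline=1.0`` gives the constrained-intercept estimator; the default 0
    is the literal form).  ``intercept=True`` frees the intercept instead.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    t = _align(ss, ld)
    if n_eff is None:
        n_eff = estimate_n_eff(ss)
    y = (t["beta"].to_numpy() / t["se"].to_numpy()) ** 2
    Z = n_eff * t["l"].to_numpy() / m
    return _slope(Z, y, intercept, baseline)


def estimate_rg(
    ss1: SummaryStats,
    ss2: SummaryStats,
    ld: LDScoreTrack,
    h2_1: float,
    h2_2: float,
    m: int,
    n1: float | None = None,
    n2: float | None = None,
    intercept: bool = False,
    baseline: float = 0.0,
) -> float:
    """Genetic correlation from the regression of the z-score product on
    sqrt(n1*n2) * l / m, rescaled by sqrt(h2_1*h2_2).  Returns the raw value
    (not clamped; see GeneticParams).

    With overlapping samples the z-score product has a non-genetic offset of
    n_overlap * r_pheno / sqrt(n1 n2); pass it as ``baseline`` (or free the
    intercept) so it is not attributed to the genetic term.
    """
    if h2_1 <= 0 or h2_2 <= 0:
        raise ValueError("heritabilities must be positive to estimate rg")
    t1 = _align(ss1, ld).set_index("id")
    t2 = _align(ss2, ld).set_index("id")
    common = t1.index.intersection(t2.index)
    if common.empty:
        raise ValueError("no shared valid markers between the two traits")
    t1, t2 = t1.loc[common], t2.loc[common]
    if n1 is None:
        n1 = estimate_n_eff(ss1)
    if n2 is None:
        n2 = estimate_n_eff(ss2)
    y = (t1["beta"] / t1["se"]).to_numpy() * (t2["beta"] / t2["se"]).to_numpy()
    Z = np.sqrt(n1 * n2) * t1["l"].to_numpy() / m
    return _slope(Z, y, intercept, baseline) / np.sqrt(h2_1 * h2_2)


def observed_to_liability(h2_obs: float, K: float) -> float:
    """Transform observed-scale heritability of a 0/1 trait to the liability
    scale for a population sample: h2_liab = h2_obs * K(1-K) / phi(z_K)^2."""
    if not 0 < K < 1:
        raise ValueError("prevalence K must be in (0, 1)")
    if h2_obs < 0:
        raise ValueError("h2_obs must be non-negative")
    z = stats.norm.isf(K)
    return float(h2_obs * K * (1.0 - K) / stats.norm.pdf(z) ** 2)


def estimate_genetic_params(
    stats_list: list[SummaryStats],
    ld: LDScoreTrack,
    m: int,
    intercept: bool = False,
    chi2_baseline: float = 0.0,
    overlap_corr: np.ndarray | None = None,
) -> GeneticParams:
    """h2, n_eff and the full pairwise rg matrix for a list of traits.

    ``chi2_baseline`` is passed to every h2 regression (1.0 constrains the
    null level of the chi-squared statistics); ``overlap_corr`` is a k x k
    matrix of non-genetic z-product offsets — for traits measured on the same
    samples, the phenotypic correlations.  Non-positive h2 estimates are
    retained in ``h2`` for reporting but floored at H2_FLOOR inside the rg
    rescaling (with a warning), mirroring what the weight construction does.
    """
    k = len(stats_list)
    h2 = np.empty(k)
    n_eff = np.empty(k)
    for i, ss in enumerate(stats_list):
        n_eff[i] = estimate_n_eff(ss)
        h2[i] = estimate_h2(
            ss, ld, m, n_eff=n_eff[i], intercept=intercept, baseline=chi2_baseline
        )
    h2_used = h2.copy()
    if (h2_used <= 0).any():
        warnings.warn("non-positive h2 estimate floored for rg computation", stacklevel=2)
        h2_used = np.maximum(h2_used, H2_FLOOR)

    rg_raw = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            off = 0.0 if overlap_corr is None else float(overlap_corr[i, j])
            rg_raw[i, j] = rg_raw[j, i] = estimate_rg(
                stats_list[i], stats_list[j], ld,
                h2_used[i], h2_used[j], m,
                n1=n_eff[i], n2=n_eff[j], intercept=intercept, baseline=off,
            )
    return GeneticParams(
        traits=[ss.trait for ss in stats_list],
        h2=h2, n_eff=n_eff, rg=rg_raw.copy(), rg_raw=rg_raw,
    )
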