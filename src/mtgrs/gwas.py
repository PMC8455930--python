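"""Marker QC, phenotype adjustment, and marginal per-marker association.

Per-marker regressions are fit internally and vectorized across markers: for
every marker j the design is [intercept | covariates | allele count_j], and the
normal equations of all markers in a chunk are assembled with einsum and solved
batched.  Logistic models use iteratively reweighted least squares (IRLS) with
a deviance tolerance of 1e-8 and at most 50 iterations; markers that fail to
converge, or are monomorphic after per-marker missing-sample exclusion, are
emitted with ``valid=False`` and an invalid SE so downstream stages can drop
them.  Wald tests are reported: a t tail for linear models, a normal tail for
logistic models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .simulate import GenotypeMatrix

__all__ = [
    "SummaryStats",
    "QCReport",
    "HarmonizeReport",
    "qc_filter_markers",
    "inverse_rank_normalize",
    "adjust_phenotype",
    "marginal_gwas",
    "or_to_beta",
    "harmonize",
]

#: canonical summary-statistics columns
SUMSTAT_COLUMNS = [
    "id", "chrom", "pos", "effect_allele", "other_allele",
    "af", "beta", "se", "p", "n", "valid",
]


@dataclass
class SummaryStats:
    """Per-marker marginal estimates for one trait.

    ``table`` has the canonical columns (id, chrom, pos, effect_allele,
    other_allele, af, beta, se, p, n, valid); ``model`` is ``linear``,
    ``logistic`` or ``index`` (for selection-index adjusted effects).
    """

    table: pd.DataFrame
    trait: str = "trait"
    model: str = "linear"

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns {missing}")
        if self.table["id"].duplicated().any():
            raise ValueError("marker ids must be unique")

    @property
    def m(self) -> int:
        return len(self.table)

    def valid_table(self) -> pd.DataFrame:
        return self.table[self.table["valid"]].reset_index(drop=True)

    def zscores(self) -> np.ndarray:
        t = self.table
        return (t["beta"] / t["se"]).to_numpy()


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    n_maf: int
    n_missingness: int
    n_region: int


@dataclass
class HarmonizeReport:
    n_external: int
    n_overlap: int
    n_flipped: int
    n_incompatible: int
    n_position_mismatch: int = 0


def qc_filter_markers(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    miss_max: float = 0.05,
    exclude_regions: list[tuple[str, int, int]] = (),
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop markers by MAF, missingness and exclusion regions.

    Thresholds default to the conventional genotyping-array QC of minor allele
    frequency >= 1% and missingness <= 5%.  Regions are (chrom, start, end),
    1-based inclusive.  Returns the filtered matrix (marker order preserved)
    and per-criterion removal counts; a marker can fail several criteria.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 <= miss_max <= 1):
        raise ValueError("miss_max must be in [0, 1]")
    af = G.allele_frequencies()
    maf = np.minimum(af, 1.0 - af)
    miss = G.missingness()

    fail_maf = (maf < maf_min) | np.isnan(maf)
    fail_miss = miss > miss_max
    fail_region = np.zeros(G.m, dtype=bool)
    chroms = G.markers["chrom"].to_numpy()
    pos = G.markers["pos"].to_numpy()
    for chrom, start, end in exclude_regions:
        fail_region |= (chroms == str(chrom)) & (pos >= start) & (pos <= end)

    keep = ~(fail_maf | fail_miss | fail_region)
    if not keep.any():
        warnings.warn("QC removed every marker", stacklevel=2)
    report = QCReport(
        n_input=G.m,
        n_retained=int(keep.sum()),
        n_maf=int(fail_maf.sum()),
        n_missingness=int(fail_miss.sum()),
        n_region=int(fail_region.sum()),
    )
    return G.subset_markers(keep), report


def inverse_rank_normalize(v) -> np.ndarray:
    """Rank-based map to standard-normal quantiles (Blom offset).

    Uses Phi^-1((rank - 3/8) / (n + 1/4)) with average ranks for ties.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-d array")
    if np.unique(v).size < 2:
        raise ValueError("inverse rank normalization undefined for constant input")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.375) / (v.size + 0.25))


def adjust_phenotype(y, covariates: pd.DataFrame) -> np.ndarray:
    """Residualize a quantitative trait on covariates, then rank-normalize."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(y.size), np.asarray(covariates, dtype=float)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    if resid.std() < 1e-10 * max(y.std(), 1.0):
        raise ValueError("residuals are numerically constant; nothing left to normalize")
    return inverse_rank_normalize(resid)


def _covariate_design(n: int, covariates: pd.DataFrame | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows do not match sample count")
    return np.column_stack([np.ones(n), C])


def _assemble(Acc, Acg, Agg, rc, rg_):
    """Stack the blocks of per-marker normal equations into batched arrays."""
    mchunk, p = Acg.shape
    A = np.empty((mchunk, p + 1, p + 1))
    A[:, :p, :p] = Acc
    A[:, :p, p] = Acg
    A[:, p, :p] = Acg
    A[:, p, p] = Agg
    r = np.concatenate([rc, rg_[:, None]], axis=1)
    return A, r


def _chunk_linear(y, C, g, se_floor=1e-300):
    n, p = C.shape
    mask = ~np.isnan(g)
    g0 = np.where(mask, g, 0.0)
    maskf = mask.astype(float)
    nuse = maskf.sum(0)

    mono = np.array([np.ptp(col[msk]) == 0 if msk.any() else True
                     for col, msk in zip(g0.T, mask.T)])

    Acc = np.einsum("np,nm,nq->mpq", C, maskf, C)
    Acg = np.einsum("np,nm->mp", C, g0)
    Agg = (g0 * g0).sum(0)
    rc = np.einsum("np,nm->mp", C, maskf * y[:, None])
    rg_ = (g0 * y[:, None]).sum(0)
    A, r = _assemble(Acc, Acg, Agg, rc, rg_)

    bad = mono | (nuse <= p + 1)
    A[bad] = np.eye(p + 1)
    b = np.linalg.solve(A, r[:, :, None])[:, :, 0]

    yhat = C @ b[:, :p].T + g0 * b[:, p]
    rss = (maskf * (y[:, None] - yhat) ** 2).sum(0)
    dof = np.maximum(nuse - (p + 1), 1)
    sigma2 = rss / dof
    Ainv = np.linalg.inv(A)
    se = np.sqrt(np.maximum(sigma2 * Ainv[:, p, p], se_floor))
    tval = b[:, p] / se
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    valid = ~bad & np.isfinite(se)
    se[~valid] = np.nan
    pval[~valid] = np.nan
    beta = b[:, p]
    beta[bad] = np.nan
    return beta, se, pval, nuse.astype(int), valid


def _chunk_logistic(y, C, g, max_iter=50, tol=1e-8):
    n, p = C.shape
    mask = ~np.isnan(g)
    g0 = np.where(mask, g, 0.0)
    maskf = mask.astype(float)
    nuse = maskf.sum(0)
    mchunk = g.shape[1]

    mono = np.array([np.ptp(col[msk]) == 0 if msk.any() else True
                     for col, msk in zip(g0.T, mask.T)])

    b = np.zeros((mchunk, p + 1))
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    b[:, 0] = np.log(ybar / (1 - ybar))
    dev_old = np.full(mchunk, np.inf)
    converged = np.zeros(mchunk, dtype=bool)
    A = np.tile(np.eye(p + 1), (mchunk, 1, 1))

    for _ in range(max_iter):
        eta = C @ b[:, :p].T + g0 * b[:, p]
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        wt = maskf * mu * (1.0 - mu)
        z = eta + (y[:, None] - mu) / (mu * (1.0 - mu))

        Acc = np.einsum("np,nm,nq->mpq", C, wt, C)
        Acg = np.einsum("np,nm->mp", C, wt * g0)
        Agg = (wt * g0 * g0).sum(0)
        rc = np.einsum("np,nm->mp", C, wt * z)
        rg_ = (wt * g0 * z).sum(0)
        A, r = _assemble(Acc, Acg, Agg, rc, rg_)
        bad = mono | (nuse <= p + 1)
        A[bad] = np.eye(p + 1)
        try:
            b = np.linalg.solve(A, r[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            sing = np.abs(np.linalg.det(A)) < 1e-300
            A[sing] = np.eye(p + 1)
            mono = mono | sing
            b = np.linalg.solve(A, r[:, :, None])[:, :, 0]

        dev = -2.0 * (maskf * (y[:, None] * np.log(mu) +
                               (1 - y[:, None]) * np.log(1 - mu))).sum(0)
        converged = np.abs(dev - dev_old) < tol
        dev_old = dev
        if converged.all():
            break

    Ainv = np.linalg.inv(A)
    se = np.sqrt(np.maximum(Ainv[:, p, p], 0.0))
    valid = converged & ~mono & np.isfinite(se) & (se > 0)
    zval = np.where(valid, b[:, p] / np.where(se > 0, se, np.nan), np.nan)
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    beta = b[:, p].copy()
    beta[mono] = np.nan
    se[~valid] = np.nan
    pval[~valid] = np.nan
    return beta, se, pval, nuse.astype(int), valid


def marginal_gwas(
    G: GenotypeMatrix,
    y,
    covariates: pd.DataFrame | None = None,
    model: str = "linear",
    trait: str = "trait",
    chunk_size: int = 512,
) -> SummaryStats:
    """Per-marker marginal regression of y on allele count plus covariates.

    Missing genotypes are handled by per-marker sample exclusion.  Returns
    betas on the observed scale (log-odds for ``model='logistic'``), Wald
    standard errors and P-values, and the per-marker non-missing N.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != G.n:
        raise ValueError("phenotype length does not match genotype rows")
    if model == "logistic":
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])) or uniq.size < 2:
            raise ValueError("logistic model requires a 0/1 outcome with both classes")
    elif model != "linear":
        raise ValueError("model must be 'linear' or 'logistic'")
    C = _covariate_design(G.n, covariates)

    fit = _chunk_logistic if model == "logistic" else _chunk_linear
    parts = []
    for j0 in range(0, G.m, chunk_size):
        g = np.asarray(G.counts[:, j0:j0 + chunk_size], dtype=float)
        parts.append(fit(y, C, g))
    beta, se, pval, nuse, valid = (np.concatenate(x) for x in zip(*parts))

    table = pd.DataFrame(
        {
            "id": G.markers["id"].to_numpy(),
            "chrom": G.markers["chrom"].to_numpy(),
            "pos": G.markers["pos"].to_numpy(),
            "effect_allele": G.markers["effect_allele"].to_numpy(),
            "other_allele": G.markers["other_allele"].to_numpy(),
            "af": np.nanmean(G.counts, axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "p": np.clip(pval, np.nextafter(0, 1), 1.0),
            "n": nuse,
            "valid": valid,
        }
    )
    return SummaryStats(table=table, trait=trait, model=model)


def or_to_beta(or_value, p):
    """Convert odds ratios and P-values to (beta, se).

    beta = ln(OR); se = |beta| / z with z the two-sided normal quantile
    Phi^-1(1 - p/2).  Degenerate inputs (OR = 1, p >= 1) yield NaN standard
    errors so the markers can be flagged invalid downstream.
    """
    or_value = np.asarray(or_value, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(or_value <= 0):
        raise ValueError("odds ratios must be positive")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P-values must be in (0, 1]")
    beta = np.log(or_value)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = stats.norm.isf(p / 2.0)
        se = np.where((beta != 0) & (z > 0), np.abs(beta) / z, np.nan)
    if beta.ndim == 0:
        return float(beta), float(se)
    return beta, se


def harmonize(
    external: SummaryStats, reference: pd.DataFrame
) -> tuple[SummaryStats, HarmonizeReport]:
    """Align external summary statistics to a reference allele orientation.

    ``reference`` needs columns id, effect_allele, other_allele (chrom/pos are
    cross-checked when present in both).  Markers present in both are kept;
    where the external alleles are swapped relative to the reference, beta is
    negated and af complemented.  Allele pairs matching neither orientation
    are dropped and counted.  Output order follows the reference.
    """
    ref = reference.reset_index(drop=True).copy()
    ref["_order"] = np.arange(len(ref))
    ext = external.table
    merged = ref.merge(ext, on="id", suffixes=("_ref", ""), how="inner")
    if merged.empty:
        raise ValueError("no overlapping markers between external and reference")

    n_posmm = 0
    if "chrom_ref" in merged.columns and "pos_ref" in merged.columns:
        mm = (merged["chrom_ref"].astype(str) != merged["chrom"].astype(str)) | (
            merged["pos_ref"].to_numpy() != merged["pos"].to_numpy()
        )
        n_posmm = int(mm.sum())
        merged = merged[~mm]

    ea_ref = merged["effect_allele_ref"].to_numpy()
    oa_ref = merged["other_allele_ref"].to_numpy()
    ea = merged["effect_allele"].to_numpy()
    oa = merged["other_allele"].to_numpy()
    same = (ea == ea_ref) & (oa == oa_ref)
    swapped = (ea == oa_ref) & (oa == ea_ref)
    keep = same | swapped

    out = merged[keep].copy()
    flip = swapped[keep]
    out.loc[flip, "beta"] = -out.loc[flip, "beta"].to_numpy()
    out.loc[flip, "af"] = 1.0 - out.loc[flip, "af"].to_numpy()
    out["effect_allele"] = out["effect_allele_ref"]
    out["other_allele"] = out["other_allele_ref"]
    out = out.sort_values("_order")

    report = HarmonizeReport(
        n_external=len(ext),
        n_overlap=len(merged),
        n_flipped=int(flip.sum()),
        n_incompatible=int((~keep).sum()),
        n_position_mismatch=n_posmm,
    )
    table = out[SUMSTAT_COLUMNS].reset_index(drop=True)
    return SummaryStats(table=table, trait=external.trait, model=external.model), report
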