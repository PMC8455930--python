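"""Marker selection and genomic risk scores, single- and multi-trait.

The single-trait score of a sample is the dot product of its allele counts
with the marginal effect estimates over a marker subset chosen by LD pruning
(greedy, P-value priority) and P-value thresholding.  The multi-trait score
re-weights the per-marker effects of k correlated traits with a selection
index w = V^-1 C, where V is the k x k variance-covariance matrix of the
estimated effects,

    var(b_k)   = h2_k / M + 1 / N_k
    cov(b_k,l) = r_g(k,l) h_k h_l / M,

C is the covariance of each trait's estimates with the true focal-trait
effects (the first column of the genetic part of V), and M is the effective
number of independent chromosomal segments (60,000 for a human cohort of
unrelated Europeans).  The adjusted effect of marker i is w' b_i and the
multi-trait score sums X_i * (w' b_i) exactly as the single-trait score does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import SUMSTAT_COLUMNS, SummaryStats
from .simulate import GenotypeMatrix

__all__ = [
    "IndexWeights",
    "RiskScoreSet",
    "DEFAULT_M",
    "ST_P_GRID",
    "MT_P_GRID",
    "R2_GRID",
    "ld_prune",
    "p_threshold",
    "st_grs",
    "index_weights",
    "mt_adjust_effects",
    "mt_grs",
    "build_scenario",
]

#: effective number of independent chromosomal segments (human, unrelated)
DEFAULT_M = 60_000

#: P-value thresholding grids for single- and multi-trait scoring
ST_P_GRID = (0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 0.9, 0.99)
MT_P_GRID = (0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 0.75, 0.99)

#: LD-pruning r2 ceilings
R2_GRID = (0.1, 0.5, 0.9)

#: rg magnitude ceiling applied before building V, guarding against
#: estimation noise pushing the matrix to singularity
RG_CLAMP = 0.999


@dataclass
class IndexWeights:
    """Selection-index weights for a focal trait (element 0) given k traits."""

    w: np.ndarray
    M: float
    N: np.ndarray
    h2: np.ndarray
    rg: np.ndarray
    traits: list[str] = None
    scenario: str = ""
    condition_number: float = np.nan
    V: np.ndarray = field(repr=False, default=None)
    C: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        k = self.w.size
        if not (self.N.size == k and self.h2.size == k and self.rg.shape == (k, k)):
            raise ValueError("w, N, h2, rg dimensions are inconsistent")
        if self.M <= 0:
            raise ValueError("M must be positive")

    def residual(self) -> float:
        """Max-norm of V w - C (should be ~0 for a well-posed solve)."""
        return float(np.abs(self.V @ self.w - self.C).max())


@dataclass
class RiskScoreSet:
    """Per-sample scores plus the settings that produced them."""

    samples: np.ndarray
    score: np.ndarray
    settings: dict

    @property
    def n(self) -> int:
        return self.score.size


def _priority_order(ss: pd.DataFrame) -> np.ndarray:
    """Marker visit order: ascending P, ties broken by genomic position."""
    return np.lexsort((ss["pos"].to_numpy(), ss["chrom"].to_numpy(), ss["p"].to_numpy()))


def ld_prune(
    G: GenotypeMatrix,
    ss: SummaryStats,
    r2_max: float,
    window: int = 5000,
) -> list[str]:
    """Greedy LD pruning with P-value priority.

    Markers are visited in ascending focal-trait P; a marker is kept iff its
    adjusted r~2 with every already-kept marker within the window (same
    chromosome, index distance <= window//2) is below ``r2_max``.  Returns
    kept marker ids in genomic order.
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    if ss.m == 0 or G.m == 0:
        raise ValueError("empty input")
    tab = ss.table.merge(
        G.markers[["id"]].assign(_gidx=np.arange(G.m)), on="id", how="inner"
    )
    if tab.empty:
        raise ValueError("no shared markers between genotypes and summary stats")
    tab = tab[tab["valid"] & np.isfinite(tab["p"])]
    n = G.n
    half = window // 2

    X = G.standardized()
    norms = np.sqrt((X * X).sum(0))
    norms[norms == 0] = np.inf
    Zn = X / norms

    order = _priority_order(tab)
    gidx = tab["_gidx"].to_numpy()
    ids_arr = tab["id"].to_numpy()
    chroms = G.markers["chrom"].to_numpy()
    kept_by_chrom: dict[str, list[int]] = {}
    kept_ids: list[tuple[int, str]] = []
    for row in order:
        j = int(gidx[row])
        chrom = chroms[j]
        kept = kept_by_chrom.setdefault(chrom, [])
        karr = np.asarray(kept, dtype=int)
        near = karr[np.abs(karr - j) <= half] if karr.size else karr
        if near.size:
            r = Zn[:, near].T @ Zn[:, j]
            r2 = r * r
            r2adj = r2 - (1.0 - r2) / (n - 2)
            if np.any(r2adj >= r2_max):
                continue
        kept.append(j)
        kept_ids.append((j, ids_arr[row]))
    kept_ids.sort(key=lambda t: t[0])
    return [mid for _, mid in kept_ids]


def p_threshold(ss: SummaryStats, p_max: float) -> list[str]:
    """Marker ids with P strictly below ``p_max``, order preserved."""
    if not 0 < p_max <= 1:
        raise ValueError("p_max must be in (0, 1]")
    t = ss.table
    keep = t["valid"] & (t["p"] < p_max)
    return t.loc[keep, "id"].tolist()


def _score(G: GenotypeMatrix, ss: SummaryStats, markers: list[str], settings: dict) -> RiskScoreSet:
    if len(markers) == 0:
        raise ValueError("empty marker subset")
    gpos = pd.Series(np.arange(G.m), index=G.markers["id"])
    spos = ss.table.set_index("id")
    missing_g = [m for m in markers if m not in gpos.index]
    missing_s = [m for m in markers if m not in spos.index]
    if missing_g or missing_s:
        raise ValueError("marker subset not contained in genotypes and summary stats")
    idx = gpos.loc[markers].to_numpy()
    beta = spos.loc[markers, "beta"].to_numpy(dtype=float)
    af = spos.loc[markers, "af"].to_numpy(dtype=float)

    X = np.asarray(G.counts[:, idx], dtype=float)
    nanmask = np.isnan(X)
    if nanmask.any():
        # missing genotypes imputed to twice the training allele frequency
        X[nanmask] = np.broadcast_to(2.0 * af, X.shape)[nanmask]
    score = X @ beta
    settings = dict(settings, marker_count=len(markers))
    return RiskScoreSet(samples=G.samples, score=score, settings=settings)


def st_grs(G: GenotypeMatrix, ss: SummaryStats, markers: list[str], **settings) -> RiskScoreSet:
    """Single-trait score: per-sample sum of allele counts times beta."""
    return _score(G, ss, markers, dict(settings, kind="ST", trait=ss.trait))


def index_weights(
    h2,
    rg,
    N,
    M: float = DEFAULT_M,
    traits: list[str] | None = None,
    scenario: str = "",
    cond_max: float = 1e12,
) -> IndexWeights:
    """Selection-index weights w = V^-1 C for the focal trait (element 0)."""
    h2 = np.asarray(h2, dtype=float)
    N = np.asarray(N, dtype=float)
    rg = np.atleast_2d(np.asarray(rg, dtype=float))
    k = h2.size
    if np.any(h2 < 0):
        raise ValueError("h2 must be non-negative")
    if np.any(N <= 0):
        raise ValueError("N must be positive")
    if M <= 0:
        raise ValueError("M must be positive")

    R = np.clip(rg, -RG_CLAMP, RG_CLAMP)
    np.fill_diagonal(R, 1.0)
    # estimation noise can leave R indefinite; clip eigenvalues so the
    # genetic part of V stays positive semi-definite
    evals, evecs = np.linalg.eigh(R)
    if evals.min() < 1e-3:
        A = evecs @ np.diag(np.clip(evals, 1e-3, None)) @ evecs.T
        d = np.sqrt(np.diag(A))
        R = A / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    h = np.sqrt(h2)
    V = R * np.outer(h, h) / M
    V[np.diag_indices(k)] = h2 / M + 1.0 / N
    C = R[0] * h[0] * h / M  # C_0 = h2_0 / M since R[0,0] = 1

    cond = float(np.linalg.cond(V))
    if not np.isfinite(cond) or cond > cond_max:
        off = np.abs(R - np.eye(k))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        names = traits or [f"trait_{t}" for t in range(k)]
        raise ValueError(
            f"variance matrix ill-conditioned (cond={cond:.3g}); "
            f"strongest-coupled pair: {names[i]} / {names[j]} (rg={R[i, j]:.3f})"
        )
    w = np.linalg.solve(V, C)
    return IndexWeights(
        w=w, M=float(M), N=N, h2=h2, rg=R, traits=traits,
        scenario=scenario, condition_number=cond, V=V, C=C,
    )


def mt_adjust_effects(stats_list: list[SummaryStats], weights: IndexWeights) -> SummaryStats:
    """Index-weighted marker effects: b_MT_i = sum_k w_k b_{k,i}.

    All k summary statistics must already be harmonized to an identical
    marker set, orientation and order (focal trait first).  Marker metadata
    and P-values come from the focal trait; markers invalid in any trait are
    marked invalid in the output.
    """
    if len(stats_list) != weights.w.size:
        raise ValueError("number of summary statistics does not match weights")
    focal = stats_list[0].table
    ids = focal["id"].to_numpy()
    for ss in stats_list[1:]:
        if not np.array_equal(ss.table["id"].to_numpy(), ids):
            raise ValueError("summary statistics are not aligned on an identical marker set")
    betas = np.column_stack([ss.table["beta"].to_numpy(dtype=float) for ss in stats_list])
    valid = np.logical_and.reduce(
        [ss.table["valid"].to_numpy() & np.isfinite(ss.table["beta"]) for ss in stats_list]
    )
    adjusted = betas @ weights.w

    table = focal[SUMSTAT_COLUMNS].copy()
    table["beta"] = adjusted
    table["valid"] = valid
    return SummaryStats(table=table, trait=f"{stats_list[0].trait}_MT", model="index")


def mt_grs(G: GenotypeMatrix, adjusted: SummaryStats, markers: list[str], **settings) -> RiskScoreSet:
    """Multi-trait score: allele counts times index-adjusted effects."""
    return _score(G, adjusted, markers, dict(settings, kind="MT", trait=adjusted.trait))


@dataclass
class ScenarioSet:
    """Ordered trait labels (focal first) and the stats feeding the index."""

    scenario: str
    labels: list[str]
    stats: list[SummaryStats]

    @property
    def k(self) -> int:
        return len(self.labels)


def build_scenario(
    scenario: str,
    focal: SummaryStats | None = None,
    info: list[SummaryStats] = (),
    external: list[SummaryStats] = (),
    which_external: int = 0,
) -> ScenarioSet:
    """Assemble the trait set for one of the four weighting scenarios.

    S1: internal focal stats + information traits.
    S2: one external focal-trait study + information traits.
    S3: one external focal study + information traits + internal focal stats.
    S4: internal focal stats + information traits + all external studies.
    """
    info = list(info)
    external = list(external)
    if scenario in ("S2", "S3"):
        if not external:
            raise ValueError(f"scenario {scenario} requires external focal-trait statistics")
        if which_external >= len(external):
            raise ValueError("which_external out of range")
        ext = external[which_external]
    if scenario in ("S1", "S4") and focal is None:
        raise ValueError(f"scenario {scenario} requires internal focal statistics")
    if not info:
        raise ValueError("information-trait statistics are required")

    if scenario == "S1":
        stats_list = [focal] + info
    elif scenario == "S2":
        stats_list = [ext] + info
    elif scenario == "S3":
        if focal is None:
            raise ValueError("scenario S3 requires internal focal statistics")
        stats_list = [ext] + info + [focal]
    elif scenario == "S4":
        if not external:
            raise ValueError("scenario S4 requires external focal-trait statistics")
        stats_list = [focal] + info + external
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return ScenarioSet(
        scenario=scenario,
        labels=[ss.trait for ss in stats_list],
        stats=stats_list,
    )
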