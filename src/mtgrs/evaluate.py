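"""Risk-score evaluation: incremental Nagelkerke R2, percentile risk
stratification with odds ratios, and cross-validated orchestration.

The incremental Nagelkerke pseudo-R2 compares two nested logistic models by
maximum likelihood — the full model contains the covariates plus the genomic
risk score, the reduced model the covariates only:

    R2 = (1 - exp(-LR/n)) / (1 - exp(2 L0 / n)),

with LR = 2 (l_full - l_reduced) and L0 the reduced-model log-likelihood.
The denominator is the standard Nagelkerke ceiling, so R2 lies in [0, 1] and
is 0 exactly when the score adds no likelihood.

Percentile stratification ranks samples by score into equal-occupancy bins,
reports the disease prevalence per bin, and an odds ratio per bin from a
covariate-adjusted logistic model of that bin against a reference bin (the
50th percentile by default); each bin is fit against the reference separately
so empty bins degrade gracefully.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gwas import SummaryStats, marginal_gwas
from .ldsc import estimate_genetic_params, ld_scores
from .scoring import (
    build_scenario,
    index_weights,
    ld_prune,
    mt_adjust_effects,
    mt_grs,
    p_threshold,
    st_grs,
)
from .simulate import GenotypeMatrix, PhenotypeTable, split_folds

__all__ = [
    "EvaluationResult",
    "CVConfig",
    "nagelkerke_r2",
    "percentile_stratify",
    "cross_validate",
    "summarize_cv",
]


@dataclass
class EvaluationResult:
    """Percentile table plus the settings that produced it."""

    percentiles: pd.DataFrame  # bin, n, n_cases, prevalence, odds_ratio, estimable
    reference: int
    top_decile_prevalence: float
    settings: dict = field(default_factory=dict)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    model = sm.Logit(y, X)
    with np.errstate(over="ignore", divide="ignore"):
        res = model.fit(disp=0, maxiter=200, method="lbfgs")
    if not np.all(np.isfinite(res.params)):
        raise ValueError("logistic fit did not converge (non-finite coefficients)")
    return res


def nagelkerke_r2(y, score, covariates: pd.DataFrame | None = None) -> float:
    """Incremental Nagelkerke R2 of a score over a covariate-only model."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(score.score if hasattr(score, "score") else score, dtype=float)
    if s.shape[0] != y.shape[0]:
        raise ValueError("score and outcome are not aligned")
    classes = np.unique(y)
    if classes.size < 2 or not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("outcome must be binary with both classes present")
    n = y.size
    Xr = np.ones((n, 1))
    if covariates is not None:
        Xr = np.column_stack([Xr, np.asarray(covariates, dtype=float)])
    Xf = np.column_stack([Xr, s])

    reduced = _fit_logit(y, Xr)
    if np.ptp(s) == 0:
        lr = 0.0  # constant score carries no information
    else:
        full = _fit_logit(y, Xf)
        lr = max(2.0 * (full.llf - reduced.llf), 0.0)
    l0 = reduced.llf
    denom = 1.0 - np.exp(2.0 * l0 / n)
    if denom <= 0:
        raise ValueError("degenerate null model: Nagelkerke ceiling is zero")
    return float((1.0 - np.exp(-lr / n)) / denom)


def _rank_bins(score: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-occupancy bin ids (1..n_bins); ties broken by stable sample order."""
    n = score.size
    order = np.argsort(score, kind="stable")
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    bins = np.empty(n, dtype=int)
    start = 0
    for b, sz in enumerate(sizes, start=1):
        bins[order[start:start + sz]] = b
        start += sz
    return bins


def percentile_stratify(
    score,
    y,
    covariates: pd.DataFrame | None = None,
    reference: int = 50,
    n_bins: int = 100,
) -> EvaluationResult:
    """Rank samples into percentile bins; prevalence and OR vs reference bin.

    ORs come from separate logistic fits of each bin against the reference
    bin with covariates; a bin with zero cases (or the reference having no
    variation) is flagged non-estimable.  The reference bin's OR is exactly 1.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(score.score if hasattr(score, "score") else score, dtype=float)
    if not 1 <= reference <= n_bins:
        raise ValueError("reference percentile out of range")
    if y.size < n_bins:
        raise ValueError("need at least one sample per percentile bin")
    bins = _rank_bins(s, n_bins)
    C = None if covariates is None else np.asarray(covariates, dtype=float)

    rows = []
    ref_mask = bins == reference
    for b in range(1, n_bins + 1):
        mask = bins == b
        nb = int(mask.sum())
        cases = int(y[mask].sum())
        prev = cases / nb if nb else np.nan
        if b == reference:
            oratio, ok = 1.0, True
        else:
            sub = mask | ref_mask
            ysub = y[sub]
            ind = mask[sub].astype(float)
            if ysub.sum() == 0 or ysub.sum() == ysub.size or cases == 0:
                oratio, ok = np.nan, False
            else:
                X = np.column_stack([np.ones(ind.size), ind])
                if C is not None:
                    X = np.column_stack([X, C[sub]])
                try:
                    res = _fit_logit(ysub, X)
                    oratio, ok = float(np.exp(res.params[1])), True
                except Exception:
                    oratio, ok = np.nan, False
        rows.append({"bin": b, "n": nb, "n_cases": cases, "prevalence": prev,
                     "odds_ratio": oratio, "estimable": ok})
    table = pd.DataFrame(rows)
    top = table[table["bin"] > n_bins - n_bins // 10]
    top_prev = float(top["n_cases"].sum() / top["n"].sum())
    return EvaluationResult(
        percentiles=table,
        reference=reference,
        top_decile_prevalence=top_prev,
        settings=getattr(score, "settings", {}),
    )


@dataclass
class CVConfig:
    """Grid and bookkeeping for a cross-validated scoring experiment.

    ``scenarios`` may contain "ST" plus any of S1-S4; external summary
    statistics (already harmonized to the cohort's marker orientation) are
    supplied per study label.  ``m_total`` is the marker count entering the
    LD-score regressions; ``M`` the effective-segment count of the index.
    """

    focal: str
    info_traits: list[str]
    scenarios: list[str] = field(default_factory=lambda: ["ST", "S1"])
    r2_grid: tuple = (0.9,)
    p_grid: tuple = (0.05,)
    k_folds: int = 10
    ld_window: int = 5000
    prune_window: int = 5000
    #: effective independent segments; None = marker count / mean LD score
    M: float | None = None
    seed: int = 0
    intercept: bool = False
    #: null level subtracted from chi-squared statistics in the h2 regression
    chi2_baseline: float = 1.0
    covariate_names: tuple = ("sex", "age")
    external_stats: dict = field(default_factory=dict)


def _fold_gwas(G, phenos, cfg, train_idx):
    """Marginal statistics for the focal and information traits on one fold."""
    Gt = G.subset_samples(train_idx)
    cov = phenos.covariates(cfg.covariate_names).iloc[train_idx]
    ttypes = dict(zip(phenos.traits, phenos.trait_types))
    stats = {}
    for trait in [cfg.focal] + list(cfg.info_traits):
        yv = phenos.table[trait].to_numpy()[train_idx]
        model = "logistic" if ttypes[trait] == "binary" else "linear"
        stats[trait] = marginal_gwas(Gt, yv, cov, model=model, trait=trait)
    return Gt, stats


def cross_validate(G: GenotypeMatrix, phenos: PhenotypeTable, config: CVConfig) -> pd.DataFrame:
    """Full pipeline under k-fold cross validation.

    For each fold: marginal effects on the training folds per trait, LD
    scores on the training genotypes, genetic parameters, index weights per
    scenario, pruning/thresholding on the focal statistics, scoring and
    incremental Nagelkerke R2 on the held-out fold.  Returns a tidy table
    (fold, scenario, r2_max, p_max, n_markers, r2_nagelkerke).
    """
    folds = split_folds(phenos.samples, config.k_folds, config.seed)
    cov_all = phenos.covariates(config.covariate_names)
    y_all = phenos.table[config.focal].to_numpy()
    externals = {k: v for k, v in config.external_stats.items()}

    rows = []
    for f in range(config.k_folds):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        Gt, stats = _fold_gwas(G, phenos, config, train_idx)
        Gv = G.subset_samples(test_idx)
        y_test = y_all[test_idx]
        cov_test = cov_all.iloc[test_idx]

        ld = ld_scores(Gt, window=config.ld_window)
        focal_ss = stats[config.focal]
        info_ss = [stats[t] for t in config.info_traits]
        ext_ss = list(externals.values())

        # index weights and adjusted effects are per fold/scenario, not per grid cell
        M_eff = config.M if config.M is not None else Gt.m / float(np.mean(ld.l))
        pheno_corr = np.corrcoef(
            phenos.table[phenos.traits].to_numpy(dtype=float)[train_idx].T
        )
        trait_pos = {t: i for i, t in enumerate(phenos.traits)}
        adjusted: dict[str, SummaryStats] = {}
        for scen in config.scenarios:
            if scen == "ST":
                continue
            try:
                sset = build_scenario(scen, focal=focal_ss, info=info_ss, external=ext_ss)
                # z-product offsets: phenotypic correlation for cohort traits
                # (full sample overlap), zero for external studies
                k = sset.k
                overlap = np.zeros((k, k))
                for i, a in enumerate(sset.labels):
                    for j, b in enumerate(sset.labels):
                        if i != j and a in trait_pos and b in trait_pos:
                            overlap[i, j] = pheno_corr[trait_pos[a], trait_pos[b]]
                params = estimate_genetic_params(
                    sset.stats, ld, m=Gt.m, intercept=config.intercept,
                    chi2_baseline=config.chi2_baseline, overlap_corr=overlap,
                )
                h2_used = np.maximum(params.h2, 1e-6)
                iw = index_weights(
                    h2_used, params.rg, params.n_eff, M=M_eff,
                    traits=sset.labels, scenario=scen,
                )
                adjusted[scen] = mt_adjust_effects(sset.stats, iw)
            except ValueError as exc:
                raise RuntimeError(f"fold {f}, scenario {scen}: {exc}") from exc

        for r2_max in config.r2_grid:
            pruned = set(ld_prune(Gt, focal_ss, r2_max, window=config.prune_window))
            for p_max in config.p_grid:
                chosen = [m for m in p_threshold(focal_ss, p_max) if m in pruned]
                for scen in config.scenarios:
                    try:
                        if scen == "ST":
                            sc = st_grs(Gv, focal_ss, chosen, r2_max=r2_max, p_max=p_max)
                        else:
                            sc = mt_grs(Gv, adjusted[scen], chosen, r2_max=r2_max, p_max=p_max)
                        r2n = nagelkerke_r2(y_test, sc, cov_test)
                        nm = sc.settings["marker_count"]
                    except ValueError as exc:
                        raise RuntimeError(
                            f"fold {f}, scenario {scen}, r2<{r2_max}, P<{p_max}: {exc}"
                        ) from exc
                    rows.append({
                        "fold": f, "scenario": scen, "r2_max": r2_max,
                        "p_max": p_max, "n_markers": nm, "r2_nagelkerke": r2n,
                    })
    return pd.DataFrame(rows)


def summarize_cv(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of the mean across folds per grid cell."""
    def sem(x):
        x = np.asarray(x, dtype=float)
        return x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else np.nan

    return (
        results.groupby(["scenario", "r2_max", "p_max"], as_index=False)
        .agg(mean_r2=("r2_nagelkerke", "mean"), sem_r2=("r2_nagelkerke", sem),
             n_folds=("fold", "nunique"))
    )
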