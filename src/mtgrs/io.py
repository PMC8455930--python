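"""Readers and writers: PLINK1 bed/bim/fam, phenotype and summary-statistic
TSVs, LD-score tracks, and the YAML pipeline configuration.

The PLINK1 binary genotype codec is implemented here directly (SNP-major,
2-bit codes: 00 = homozygous A1, 01 = missing, 10 = heterozygous, 11 =
homozygous A2; A1 is the counted/effect allele).  bim positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gwas import SUMSTAT_COLUMNS, SummaryStats, or_to_beta
from .ldsc import LDScoreTrack
from .simulate import GenotypeMatrix, PhenotypeTable

__all__ = [
    "read_plink",
    "write_plink",
    "read_sumstats",
    "write_sumstats",
    "read_phenotypes",
    "write_phenotypes",
    "read_ldscores",
    "write_ldscores",
    "PipelineConfig",
    "load_config",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK1 bed

# 2-bit code -> allele-1 count (NaN = missing)
_CODE_TO_COUNT = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed/bim/fam.  bim columns: chrom, id, cM(0), pos, A1, A2."""
    prefix = Path(prefix)
    n, m = G.n, G.m
    counts = G.counts

    codes = np.full((m, n), 1, dtype=np.uint8)  # default: missing
    cnt = counts.T
    codes[cnt == 2] = 0
    codes[cnt == 1] = 2
    codes[cnt == 0] = 3

    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (
        (padded.reshape(m, n_bytes, 4) << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    )
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": G.markers["chrom"],
            "id": G.markers["id"],
            "cm": 0,
            "pos": G.markers["pos"],
            "a1": G.markers["effect_allele"],
            "a2": G.markers["other_allele"],
        }
    )
    bim.to_csv(Path(str(prefix) + ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": G.samples, "iid": G.samples, "pat": 0, "mat": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(Path(str(prefix) + ".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read bed/bim/fam into a GenotypeMatrix (A1 = counted effect allele)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        Path(str(prefix) + ".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        Path(str(prefix) + ".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"iid": str},
    )
    if bim["id"].duplicated().any():
        raise ValueError("duplicate marker ids in bim")
    n, m = len(fam), len(bim)

    raw = Path(Path(str(prefix) + ".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError("bad bed magic bytes (expected SNP-major PLINK1)")
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * n_bytes:
        raise ValueError(
            f"bed size inconsistent with bim/fam: got {body.size} genotype bytes, "
            f"expected {m * n_bytes}"
        )
    mat = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (mat >> (2 * k)) & 0b11
    counts = _CODE_TO_COUNT[codes[:, :n]].T.astype(np.float32)

    markers = pd.DataFrame(
        {
            "chrom": bim["chrom"].astype(str),
            "pos": bim["pos"].astype(int),
            "id": bim["id"],
            "effect_allele": bim["a1"],
            "other_allele": bim["a2"],
            "af": np.nanmean(counts, axis=0) / 2.0,
            "missingness": np.isnan(counts).mean(axis=0),
        }
    )
    return GenotypeMatrix(counts=counts, markers=markers, samples=fam["iid"].to_numpy())


# --- summary statistics -----------------------------------------------------

#: accepted header aliases, lowercase
_ALIASES = {
    "id": ("id", "snp", "rsid", "marker", "markername", "variant_id"),
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "effect_allele": ("effect_allele", "ea", "a1", "alt", "allele1"),
    "other_allele": ("other_allele", "oa", "a2", "ref", "allele2", "allele0"),
    "af": ("af", "eaf", "frq", "freq", "maf", "effect_allele_frequency"),
    "beta": ("beta", "b", "effect", "effect_size"),
    "or": ("or", "odds_ratio", "oddsratio"),
    "se": ("se", "stderr", "standard_error"),
    "p": ("p", "pval", "p_value", "pvalue"),
    "n": ("n", "nobs", "n_total", "sample_size"),
}


def _resolve_columns(columns) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    out = {}
    for canon, aliases in _ALIASES.items():
        for a in aliases:
            if a in lower:
                out[canon] = lower[a]
                break
    return out


def read_sumstats(
    path: str | Path, dialect: str = "auto", trait: str | None = None
) -> SummaryStats:
    """Read a delimited summary-statistics file via the header alias map.

    ``dialect='or'`` (or 'auto' with an OR column and no beta column) converts
    odds ratios with :func:`or_to_beta`; rows whose conversion is degenerate
    are kept with ``valid=False``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = _resolve_columns(df.columns)
    required = ["id", "effect_allele", "other_allele", "af", "se", "p", "n"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")

    use_or = dialect == "or" or (dialect == "auto" and "beta" not in cols and "or" in cols)
    if not use_or and "beta" not in cols:
        raise ValueError(f"{path.name}: neither beta nor OR column found")

    out = pd.DataFrame({"id": df[cols["id"]].astype(str)})
    out["chrom"] = df[cols["chrom"]].astype(str) if "chrom" in cols else "0"
    out["pos"] = df[cols["pos"]].astype(int) if "pos" in cols else 0
    out["effect_allele"] = df[cols["effect_allele"]].astype(str)
    out["other_allele"] = df[cols["other_allele"]].astype(str)
    for c in ("af", "se", "p", "n"):
        out[c] = pd.to_numeric(df[cols[c]], errors="coerce")
    if use_or:
        orv = pd.to_numeric(df[cols["or"]], errors="coerce").to_numpy()
        beta, se = or_to_beta(np.where(orv > 0, orv, np.nan), out["p"].clip(1e-300, 1).to_numpy())
        out["beta"] = beta
        out["se"] = se
    else:
        out["beta"] = pd.to_numeric(df[cols["beta"]], errors="coerce")
    out["valid"] = (
        np.isfinite(out["beta"]) & np.isfinite(out["se"]) & (out["se"] > 0)
        & np.isfinite(out["p"]) & (out["p"] > 0) & (out["p"] <= 1)
    )
    model = "logistic" if use_or else "linear"
    return SummaryStats(
        table=out[SUMSTAT_COLUMNS], trait=trait or path.stem, model=model
    )


def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    """Write the canonical TSV: id, chr, pos, ea, oa, af, beta, se, p, n."""
    t = ss.table.rename(
        columns={"chrom": "chr", "effect_allele": "ea", "other_allele": "oa"}
    )
    t[["id", "chr", "pos", "ea", "oa", "af", "beta", "se", "p", "n"]].to_csv(
        path, sep="\t", index=False
    )


def write_phenotypes(phenos: PhenotypeTable, path: str | Path) -> None:
    phenos.table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path, traits: list[str] | None = None) -> PhenotypeTable:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if traits is None:
        reserved = {"sample_id", "sex", "age", "fold"} | {f"pc{j}" for j in range(1, 11)}
        traits = [c for c in table.columns if c not in reserved]
    ttypes = [
        "binary" if set(pd.unique(table[t].dropna())) <= {0.0, 1.0} else "quantitative"
        for t in traits
    ]
    return PhenotypeTable(table=table, traits=traits, trait_types=ttypes)


def write_ldscores(ld: LDScoreTrack, path: str | Path) -> None:
    t = ld.table.rename(columns={"chrom": "chr"})
    t[["id", "chr", "pos", "l"]].to_csv(path, sep="\t", index=False)


def read_ldscores(path: str | Path, window: int = 5000, n_ref: int = 0) -> LDScoreTrack:
    t = pd.read_csv(path, sep="\t", dtype={"chr": str})
    t = t.rename(columns={"chr": "chrom"})
    return LDScoreTrack(table=t[["id", "chrom", "pos", "l"]], window=window, n_ref=n_ref)


# --- pipeline configuration -------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything a full run needs; CLI flags override config keys."""

    out_dir: str = "results"
    seed: int = 1
    # inputs (optional when the simulate stage provides them)
    bfile: str | None = None
    phenotypes: str | None = None
    sumstats: list[dict] = field(default_factory=list)  # {path, trait, focal: bool}
    # simulation block (dict passed to SimConfig) or None to use files
    simulate: dict | None = None
    focal: str | None = None
    info_traits: list[str] = field(default_factory=list)
    # QC
    maf_min: float = 0.01
    miss_max: float = 0.05
    exclude_regions: list = field(default_factory=list)
    # genetic parameters
    ld_window: int = 5000
    intercept: bool = True
    #: effective independent segments; None = marker count / mean LD score
    #: (a genotyped human cohort corresponds to roughly 60,000)
    M: float | None = None
    # scoring grid
    scenarios: list[str] = field(default_factory=lambda: ["ST", "S1"])
    r2_grid: list[float] = field(default_factory=lambda: [0.9])
    p_grid: list[float] = field(default_factory=lambda: [0.05])
    k_folds: int = 10
    covariates: list[str] = field(default_factory=lambda: ["sex", "age"])

    def validate(self) -> None:
        if not self.r2_grid or not self.p_grid:
            raise ValueError("r2_grid and p_grid must be non-empty")
        if self.seed is None:
            raise ValueError("a seed is required")
        if self.simulate is None:
            for p in (self.bfile and self.bfile + ".bed", self.phenotypes):
                if p is None or not Path(p).exists():
                    raise ValueError(f"input path missing or not found: {p}")
            if self.focal is None:
                raise ValueError("a focal trait must be named")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
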