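"""Join risk variants to significant eQTL records and orient effect signs.

Each eQTL record associates one variant with one gene in one tissue, with an
expression effect size (beta, per alt allele as supplied) and the minor
allele frequency.  Effects are re-oriented to the minor allele so that signs
are comparable across variants, and each association carries the joined
variant's GWAS significance as -log10(p).  The signed prioritization signal
is the product of GWAS significance and oriented effect.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EQTL_COLUMNS = ["rsid", "gene_id", "gene_symbol", "tissue", "beta", "pvalue", "maf"]

ASSOC_COLUMNS = [
    "rsid", "gene_id", "gene_symbol", "tissue", "beta", "eqtl_pvalue", "maf",
    "alt_is_minor", "oriented_beta", "gwas_neglogp", "odds_ratio", "chrom", "pos",
]


class EqtlError(ValueError):
    """Raised on malformed or duplicated eQTL input records."""


@dataclass
class JoinReport:
    """Bookkeeping for one variant/eQTL join."""
    n_variants: int = 0
    n_with_eqtl: int = 0
    n_without_eqtl: int = 0
    no_eqtl_rsids: list[str] = field(default_factory=list)
    n_assumed_alt_minor: int = 0


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    """Read a significant-eQTL TSV; ``minor_is_alt`` (0/1) is optional."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"rsid": str, "gene_id": str})
    missing = [c for c in EQTL_COLUMNS if c not in df.columns]
    if missing:
        raise EqtlError(f"{path}: missing required columns {missing}")
    return df


def join_eqtls(variants: pd.DataFrame, eqtls: pd.DataFrame) -> tuple[pd.DataFrame, JoinReport]:
    """Inner-join a risk-variant catalog to an eQTL table by rsID.

    Returns one association per (rsid, gene_id, tissue) triple whose rsID is
    in the catalog, with GWAS fields copied from the variant, plus a
    :class:`JoinReport` counting catalog variants that had no eQTL.

    Raises
    ------
    EqtlError
        If the eQTL table contains a duplicated (rsid, gene_id, tissue)
        triple, or p-values/MAF are out of range.
    """
    dup = eqtls.duplicated(subset=["rsid", "gene_id", "tissue"])
    if dup.any():
        first = eqtls[dup].iloc[0]
        raise EqtlError(
            f"duplicate eQTL record for ({first['rsid']}, {first['gene_id']}, {first['tissue']})"
        )
    if ((eqtls["pvalue"] <= 0) | (eqtls["pvalue"] > 1)).any():
        raise EqtlError("eQTL p-values must lie in (0, 1]")
    if ((eqtls["maf"] <= 0) | (eqtls["maf"] > 0.5)).any():
        raise EqtlError("MAF must lie in (0, 0.5]")

    merged = eqtls.merge(
        variants[["rsid", "chrom", "pos", "gwas_pvalue", "odds_ratio"]],
        on="rsid", how="inner",
    )
    report = JoinReport(n_variants=len(variants))
    joined_rsids = set(merged["rsid"])
    report.n_with_eqtl = int(variants["rsid"].isin(joined_rsids).sum())
    missing_mask = ~variants["rsid"].isin(joined_rsids)
    report.n_without_eqtl = int(missing_mask.sum())
    report.no_eqtl_rsids = sorted(variants.loc[missing_mask, "rsid"])

    if "minor_is_alt" in merged.columns:
        alt_is_minor = merged["minor_is_alt"].astype(bool)
    else:
        log.warning("eQTL table has no minor_is_alt column; assuming alt allele is minor")
        alt_is_minor = pd.Series(True, index=merged.index)
        report.n_assumed_alt_minor = len(merged)

    assoc = pd.DataFrame({
        "rsid": merged["rsid"],
        "gene_id": merged["gene_id"],
        "gene_symbol": merged["gene_symbol"],
        "tissue": merged["tissue"],
        "beta": merged["beta"].astype(float),
        "eqtl_pvalue": merged["pvalue"].astype(float),
        "maf": merged["maf"].astype(float),
        "alt_is_minor": alt_is_minor.values,
        "gwas_neglogp": -np.log10(merged["gwas_pvalue"].astype(float)),
        "odds_ratio": merged["odds_ratio"].astype(float),
        "chrom": merged["chrom"],
        "pos": merged["pos"],
    })
    assoc["oriented_beta"] = np.where(assoc["alt_is_minor"], assoc["beta"], -assoc["beta"])
    assoc = assoc.sort_values(["rsid", "gene_id", "tissue"], kind="mergesort").reset_index(drop=True)
    return assoc[ASSOC_COLUMNS], report


def orient_by_minor_allele(beta: float, alt_is_minor: bool, maf: float) -> float:
    """Return the expression effect per *minor* allele.

    The supplied beta is per alt allele; when the alt allele is the major
    allele the sign flips.  Applying the operation twice with a flipped flag
    restores the original sign; the magnitude is always preserved.
    """
    if not 0 < maf <= 0.5:
        raise EqtlError(f"MAF must lie in (0, 0.5], got {maf}")
    return beta if alt_is_minor else -beta


def signed_signal(assoc: pd.DataFrame) -> pd.Series:
    """Signed prioritization signal: GWAS -log10(p) x minor-allele-oriented beta."""
    return assoc["gwas_neglogp"] * assoc["oriented_beta"]


@dataclass
class EgeneSummary:
    """Distinct-egene counts per (variant, tissue) with global order statistics."""
    table: pd.DataFrame          # columns rsid, tissue, n_egenes
    median_egenes: float
    max_egenes: int


def summarize_egenes(assoc: pd.DataFrame) -> EgeneSummary:
    """Count distinct egenes per variant per tissue, with global median/max."""
    if assoc.empty:
        return EgeneSummary(pd.DataFrame(columns=["rsid", "tissue", "n_egenes"]), float("nan"), 0)
    counts = (
        assoc.groupby(["rsid", "tissue"])["gene_id"].nunique()
        .rename("n_egenes").reset_index()
        .sort_values(["rsid", "tissue"], kind="mergesort").reset_index(drop=True)
    )
    return EgeneSummary(
        table=counts,
        median_egenes=float(counts["n_egenes"].median()),
        max_egenes=int(counts["n_egenes"].max()),
    )


def tissue_gene_set(assoc: pd.DataFrame, tissue_substring: str) -> set[str]:
    """Distinct gene_ids observed in tissues matching a case-insensitive
    substring (e.g. ``"brain"`` for the brain-restricted egene set)."""
    mask = assoc["tissue"].str.contains(tissue_substring, case=False, regex=False)
    return set(assoc.loc[mask, "gene_id"])


def manhattan_table(assoc: pd.DataFrame) -> pd.DataFrame:
    """Per-variant plotting table: position, significance, and the
    largest-magnitude signed signal across the variant's associations."""
    df = assoc.copy()
    df["signal"] = signed_signal(df)
    df["absig"] = df["signal"].abs()
    df = df.sort_values(["absig", "gene_id", "tissue"], ascending=[False, True, True], kind="mergesort")
    best = df.drop_duplicates("rsid", keep="first")
    out = best[["chrom", "pos", "rsid", "gwas_neglogp", "signal"]].rename(
        columns={"signal": "best_signed_signal"}
    )
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
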