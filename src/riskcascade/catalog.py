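"""Risk-variant catalog: multi-source aggregation and LD-proxy expansion.

Risk variants arrive as per-source summary-statistic tables (one row per
reported index SNP).  The catalog unions the sources by rsID, keeps the most
significant p-value for variants reported more than once, applies the
genome-wide significance threshold, and then expands the set with linkage
disequilibrium (LD) proxies.  A proxy inherits the most significant GWAS
p-value among its linked index ("parent") variants.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Canonical column order of the unified catalog.
CATALOG_COLUMNS = [
    "rsid", "chrom", "pos", "ref", "alt",
    "gwas_pvalue", "odds_ratio", "sources",
    "is_index", "parent_rsid", "r2_to_parent",
]

SOURCE_COLUMNS = ["rsid", "chrom", "pos", "pvalue", "or", "ref", "alt"]
PROXY_COLUMNS = ["index_rsid", "proxy_rsid", "r2"]


class CatalogError(ValueError):
    """Raised on malformed source rows or conflicting variant records."""


def read_source_table(path: str | Path, source: str | None = None) -> pd.DataFrame:
    """Read one per-source GWAS TSV (``rsid chrom pos pvalue or ref alt``).

    ``#``-prefixed lines are comments.  ``source`` defaults to the file stem
    and is attached as a column so tables can be concatenated downstream.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"rsid": str, "chrom": str})
    missing = [c for c in SOURCE_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: missing required columns {missing}")
    df["source"] = source if source is not None else path.stem
    return df


def read_proxy_table(path: str | Path) -> pd.DataFrame:
    """Read an LD-proxy TSV (``index_rsid proxy_rsid r2`` plus optional
    ``chrom pos ref alt`` coordinates for the proxy)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"index_rsid": str, "proxy_rsid": str, "chrom": str})
    missing = [c for c in PROXY_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: missing required columns {missing}")
    return df


def _validate_pvalues(df: pd.DataFrame, col: str = "pvalue") -> None:
    bad = df[(df[col] <= 0) | (df[col] > 1) | df[col].isna()]
    if len(bad):
        rows = ", ".join(
            f"{r.rsid} (source={getattr(r, 'source', '?')}, p={getattr(r, col)})"
            for r in bad.head(10).itertuples()
        )
        raise CatalogError(f"{len(bad)} row(s) with p-value outside (0, 1]: {rows}")


def merge_risk_sources(tables: list[pd.DataFrame], pvalue_max: float = 1e-4) -> pd.DataFrame:
    """Union risk variants from several source tables into one catalog.

    A variant present in multiple sources appears once, carrying the union of
    source labels and the minimum (most significant) p-value; coordinates and
    alleles are taken from the row attaining that minimum.  Only variants with
    ``gwas_pvalue < pvalue_max`` are retained, and all survivors are flagged
    as index variants.

    Raises
    ------
    CatalogError
        If any p-value lies outside (0, 1] or if one rsID is reported at
        conflicting genomic coordinates.
    """
    if not 0 < pvalue_max <= 1:
        raise CatalogError(f"pvalue_max must be in (0, 1], got {pvalue_max}")
    if not tables:
        raise CatalogError("no source tables supplied")
    frames = []
    for i, t in enumerate(tables):
        t = t.copy()
        if "source" not in t.columns:
            t["source"] = f"source{i + 1}"
        frames.append(t)
    allrows = pd.concat(frames, ignore_index=True)
    _validate_pvalues(allrows)

    coords = allrows.groupby("rsid")[["chrom", "pos"]].nunique()
    conflicts = coords[(coords["chrom"] > 1) | (coords["pos"] > 1)]
    if len(conflicts):
        raise CatalogError(
            "conflicting coordinates for rsid(s): " + ", ".join(conflicts.index[:10])
        )

    # row with min p per rsid wins the coordinate/allele fields
    allrows = allrows.sort_values(["pvalue", "source"], kind="mergesort")
    best = allrows.drop_duplicates("rsid", keep="first").set_index("rsid")
    src = allrows.groupby("rsid")["source"].agg(lambda s: ",".join(sorted(set(s))))

    cat = pd.DataFrame({
        "rsid": best.index,
        "chrom": best["chrom"].values,
        "pos": best["pos"].astype(np.int64).values,
        "ref": best["ref"].values,
        "alt": best["alt"].values,
        "gwas_pvalue": best["pvalue"].values,
        "odds_ratio": best["or"].values,
        "sources": src.reindex(best.index).values,
    })
    cat = cat[cat["gwas_pvalue"] < pvalue_max].copy()
    cat["is_index"] = True
    cat["parent_rsid"] = ""
    cat["r2_to_parent"] = 1.0
    return cat.sort_values("rsid", kind="mergesort").reset_index(drop=True)[CATALOG_COLUMNS]


def expand_ld(catalog: pd.DataFrame, proxies: pd.DataFrame, r2_min: float = 0.8) -> pd.DataFrame:
    """Add LD-proxy variants with ``r2 >= r2_min`` to an index catalog.

    Each admitted proxy is annotated with the most significant GWAS p-value
    among its linked parents, the parent attaining that minimum, and the r²
    of that link.  Proxy rsIDs already present in the catalog are not
    duplicated (the existing record wins), so the operation is idempotent.
    Links whose index rsID is absent from the catalog are dropped with a
    logged count; proxy coordinates default to the parent's when the proxy
    table carries none.
    """
    if ((proxies["r2"] < 0) | (proxies["r2"] > 1) | proxies["r2"].isna()).any():
        raise CatalogError("proxy r2 values must lie in [0, 1]")
    if (proxies["index_rsid"] == proxies["proxy_rsid"]).any():
        raise CatalogError("proxy link with index_rsid == proxy_rsid")

    known = set(catalog["rsid"])
    unknown = ~proxies["index_rsid"].isin(known)
    if unknown.any():
        log.warning("dropping %d proxy link(s) to unknown index variants", int(unknown.sum()))
    links = proxies[~unknown & (proxies["r2"] >= r2_min)]
    links = links[~links["proxy_rsid"].isin(known)]
    if links.empty:
        return catalog.reset_index(drop=True)

    parent = catalog.set_index("rsid")
    ann = links.merge(
        parent[["chrom", "pos", "ref", "alt", "gwas_pvalue", "odds_ratio"]],
        left_on="index_rsid", right_index=True, suffixes=("", "_parent"),
    )
    # most significant parent wins; ties broken by parent rsid for determinism
    ann = ann.sort_values(["gwas_pvalue", "index_rsid"], kind="mergesort")
    ann = ann.drop_duplicates("proxy_rsid", keep="first")

    has_coords = "pos" in proxies.columns and "chrom" in proxies.columns
    if has_coords:
        chrom = ann["chrom"].where(ann["chrom"].notna(), ann["chrom_parent"]) \
            if "chrom_parent" in ann.columns else ann["chrom"]
        pos = ann["pos"].where(ann["pos"].notna(), ann["pos_parent"]) \
            if "pos_parent" in ann.columns else ann["pos"]
        ref = ann["ref"] if "ref" in proxies.columns else ann["ref_parent"]
        alt = ann["alt"] if "alt" in proxies.columns else ann["alt_parent"]
    else:
        log.warning("proxy table has no coordinates; inheriting parent positions")
        chrom, pos, ref, alt = ann["chrom"], ann["pos"], ann["ref"], ann["alt"]

    prox = pd.DataFrame({
        "rsid": ann["proxy_rsid"].values,
        "chrom": np.asarray(chrom),
        "pos": np.asarray(pos, dtype=np.int64),
        "ref": np.asarray(ref),
        "alt": np.asarray(alt),
        "gwas_pvalue": ann["gwas_pvalue"].values,
        "odds_ratio": ann["odds_ratio"].values,
        "sources": "",
        "is_index": False,
        "parent_rsid": ann["index_rsid"].values,
        "r2_to_parent": ann["r2"].values,
    })
    out = pd.concat([catalog[CATALOG_COLUMNS], prox[CATALOG_COLUMNS]], ignore_index=True)
    return out.sort_values("rsid", kind="mergesort").reset_index(drop=True)


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"rsid": str, "chrom": str, "parent_rsid": str},
        keep_default_na=False,
        na_values=[],
    )
    df["pos"] = df["pos"].astype(np.int64)
    for col in ("gwas_pvalue", "odds_ratio", "r2_to_parent"):
        df[col] = df[col].astype(float)
    df["is_index"] = df["is_index"].astype(str).str.lower().isin({"true", "1"})
    return df[CATALOG_COLUMNS]
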