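"""Gene-set over-representation against an egene background.

Query gene sets emerging from each filter stage are tested for enrichment
of annotation categories with the upper-tail hypergeometric probability,
against a background of all egenes (genes with at least one significant
eQTL).  Benjamini-Hochberg adjustment is applied across the categories
tested at each stage.  ``collapse_locus`` replaces clustered paralogs that
share a locus with a single representative, so one physical signal is not
counted many times.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "set_id", "set_size", "overlap", "query_size", "background_size",
    "p_value", "adjusted_p", "fold",
]


class EnrichmentError(ValueError):
    """Raised on empty backgrounds or malformed gene-set files."""


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: ``set_id <tab> description <tab> gene...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EnrichmentError(f"{path}:{i + 1}: expected >= 3 GMT columns")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_locus_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return dict(zip(df["gene_id"], df["locus_label"]))


def hypergeometric_enrichment(
    query: set[str],
    categories: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """One-sided over-representation test of a query set in each category.

    ``p_value`` is the probability of drawing at least the observed overlap
    when ``query_size`` genes are sampled without replacement from the
    background; ``adjusted_p`` is Benjamini-Hochberg across categories.
    Query genes outside the background are logged and dropped; categories
    are intersected with the background before testing.  Results are sorted
    by p-value then set_id.
    """
    if not background:
        raise EnrichmentError("background gene set is empty")
    stray = query - background
    if stray:
        log.warning("%d query gene(s) outside the background were dropped", len(stray))
    query = query & background
    N = len(background)
    q = len(query)
    rows = []
    for set_id in sorted(categories):
        members = categories[set_id] & background
        K = len(members)
        k = len(query & members)
        # P(X >= k) for X ~ Hypergeom(N, K, q)
        p = float(hypergeom.sf(k - 1, N, K, q)) if K and q else 1.0
        p = min(p, 1.0)
        expected = q * K / N
        fold = k / expected if expected > 0 else float("nan")
        rows.append((set_id, K, k, q, N, p, fold))
    df = pd.DataFrame(rows, columns=["set_id", "set_size", "overlap", "query_size",
                                     "background_size", "p_value", "fold"])
    if len(df):
        df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["adjusted_p"] = pd.Series(dtype=float)
    df = df.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)
    return df[RESULT_COLUMNS]


def collapse_locus(genes: set[str], locus_map: dict[str, str]) -> set[str]:
    """Collapse genes sharing a locus label to one representative each.

    The lexicographically first gene of each locus present in ``genes``
    stands for the whole cluster; genes without a locus label pass through
    unchanged.  Apply the same map to query and background so sizes stay
    consistent.
    """
    by_locus: dict[str, list[str]] = {}
    out = set()
    for g in genes:
        locus = locus_map.get(g)
        if locus is None:
            out.add(g)
        else:
            by_locus.setdefault(locus, []).append(g)
    out.update(min(members) for members in by_locus.values())
    return out
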