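"""Gene prioritization by significance-effect correlation.

For each gene (per tissue) the Pearson correlation between GWAS significance
(-log10 p) and minor-allele-oriented eQTL effect is computed over the gene's
distinct SNPs; genes are kept when the tissue-averaged correlation clears a
cutoff.  A complementary pairwise statistic correlates the *differences* in
significance and effect over all unordered SNP pairs, with a seeded
permutation null providing empirical p-values and Q-Q tables.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

COMBINED_TISSUE = "combined"


class PrioritizationError(ValueError):
    """Raised on mixed gene/tissue groups or invalid parameters."""


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation via the covariance/sigma formula.

    Returns NaN for degenerate input (fewer than two points or a constant
    variable).  Kept explicit rather than delegated so the vectorized
    permutation path shares one definition; unit tests cross-check it
    against scipy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


@dataclass
class GeneScore:
    gene_id: str
    tissue: str
    n_snps: int
    pearson_r: float          # NaN when undefined (n < min_n or constant input)
    mean_r: float = float("nan")
    passes: bool = False


def gene_correlation(assoc: pd.DataFrame, min_n: int = 3) -> GeneScore:
    """Correlation between GWAS significance and oriented eQTL effect for
    one gene in one tissue, over the gene's distinct SNPs.

    Undefined (NaN) when fewer than ``min_n`` distinct SNPs are available or
    either variable is constant — low-n correlations are noise, not signal.
    """
    if min_n < 3:
        raise PrioritizationError("min_n must be >= 3")
    if assoc["gene_id"].nunique() > 1 or assoc["tissue"].nunique() > 1:
        raise PrioritizationError("gene_correlation expects a single (gene, tissue) group")
    snps = assoc.drop_duplicates("rsid")
    n = len(snps)
    r = float("nan")
    if n >= min_n:
        r = pearson(snps["gwas_neglogp"].values, snps["oriented_beta"].values)
    gene = assoc["gene_id"].iloc[0] if len(assoc) else ""
    tissue = assoc["tissue"].iloc[0] if len(assoc) else ""
    return GeneScore(gene_id=gene, tissue=tissue, n_snps=n, pearson_r=r)


def score_genes(assoc: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Per-(gene, tissue) correlation table over a full association frame."""
    rows = []
    for (gene, tissue), grp in assoc.groupby(["gene_id", "tissue"], sort=True):
        s = gene_correlation(grp, min_n=min_n)
        rows.append((gene, tissue, s.n_snps, s.pearson_r))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "n_snps", "pearson_r"])


def aggregate_gene_scores(scores: pd.DataFrame, mode: str = "mean_across_tissues") -> pd.DataFrame:
    """Collapse per-tissue gene scores to one selection statistic per gene.

    ``mean_across_tissues``: the statistic is the unweighted mean of defined
    per-tissue correlations.  ``per_tissue``: the statistic is the maximum
    defined per-tissue correlation.  Genes with no defined per-tissue value
    are marked undefined (NaN statistic) and never pass the filter.
    """
    if mode not in ("mean_across_tissues", "per_tissue"):
        raise PrioritizationError(f"unknown aggregation mode {mode!r}")
    rows = []
    for gene, grp in scores.groupby("gene_id", sort=True):
        defined = grp["pearson_r"].dropna()
        mean_r = float(defined.mean()) if len(defined) else float("nan")
        if mode == "mean_across_tissues":
            stat = mean_r
        else:
            stat = float(defined.max()) if len(defined) else float("nan")
        rows.append((gene, len(grp), len(defined), int(grp["n_snps"].sum()), mean_r, stat))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_tissues", "n_defined", "n_snps", "mean_r", "stat"]
    )


def filter_genes(aggregated: pd.DataFrame, cutoff: float = 0.4) -> list[str]:
    """Genes whose selection statistic is >= cutoff, sorted by gene_id."""
    if not -1 <= cutoff <= 1:
        raise PrioritizationError(f"cutoff must lie in [-1, 1], got {cutoff}")
    passing = aggregated[aggregated["stat"] >= cutoff]
    return sorted(passing["gene_id"])


def heatmap_matrix(scores: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Genes-by-tissues matrix of per-tissue correlations (heatmap-ready)."""
    mat = scores.pivot_table(index="gene_id", columns="tissue", values="pearson_r", aggfunc="first")
    if genes is not None:
        mat = mat.loc[[g for g in genes if g in mat.index]]
    return mat.sort_index()


# ---------------------------------------------------------------------------
# Pairwise SNP-SNP difference statistic
# ---------------------------------------------------------------------------

@dataclass
class PairwiseStat:
    gene_id: str
    tissue: str
    n_snps: int
    n_pairs: int
    r_pairwise: float                 # NaN when undefined
    empirical_p: float = float("nan")
    null_quantiles: np.ndarray | None = None


def _pair_diffs(sig: np.ndarray, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Differences over all unordered pairs, oriented so dsig >= 0."""
    n = sig.size
    iu, ju = np.triu_indices(n, k=1)
    dsig = sig[iu] - sig[ju]
    dbeta = beta[iu] - beta[ju]
    flip = dsig < 0
    dsig = np.where(flip, -dsig, dsig)
    dbeta = np.where(flip, -dbeta, dbeta)
    return dsig, dbeta


def pairwise_snp_statistic(assoc: pd.DataFrame, min_pairs: int = 100) -> PairwiseStat:
    """Correlation of pairwise differences (dsig, dbeta) over all unordered
    SNP pairs of one gene in one tissue, each pair oriented so dsig >= 0.

    Undefined when fewer than ``min_pairs`` pairs exist or a difference
    vector is constant.
    """
    if assoc["gene_id"].nunique() > 1 or assoc["tissue"].nunique() > 1:
        raise PrioritizationError("pairwise_snp_statistic expects a single (gene, tissue) group")
    snps = assoc.drop_duplicates("rsid")
    n = len(snps)
    n_pairs = n * (n - 1) // 2
    gene = assoc["gene_id"].iloc[0] if len(assoc) else ""
    tissue = assoc["tissue"].iloc[0] if len(assoc) else ""
    r = float("nan")
    if n_pairs >= min_pairs:
        dsig, dbeta = _pair_diffs(snps["gwas_neglogp"].values.astype(float),
                                  snps["oriented_beta"].values.astype(float))
        r = pearson(dsig, dbeta)
    return PairwiseStat(gene_id=gene, tissue=tissue, n_snps=n, n_pairs=n_pairs, r_pairwise=r)


def permutation_null(
    assoc: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    min_pairs: int = 100,
    quantile_grid: np.ndarray | None = None,
) -> PairwiseStat:
    """Pairwise statistic with a permutation null and empirical p-value.

    The null shuffles the effect vector against the significance vector
    ``n_perm`` times; the empirical p is the add-one upper-tail rank
    ``(1 + #{null >= observed}) / (n_perm + 1)``.  Null quantiles on a
    1%..99% grid are attached for Q-Q plotting.  Fully reproducible from
    the seed.
    """
    if n_perm < 100:
        raise PrioritizationError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stat = pairwise_snp_statistic(assoc, min_pairs=min_pairs)
    if not np.isfinite(stat.r_pairwise):
        return stat

    snps = assoc.drop_duplicates("rsid")
    sig = snps["gwas_neglogp"].values.astype(float)
    beta = snps["oriented_beta"].values.astype(float)
    n = sig.size
    iu, ju = np.triu_indices(n, k=1)
    dsig = sig[iu] - sig[ju]
    flip = dsig < 0
    dsig = np.where(flip, -dsig, dsig)

    # permute beta, form oriented pair differences, correlate against fixed dsig
    perms = np.tile(beta, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    dbeta = perms[:, iu] - perms[:, ju]
    dbeta = np.where(flip[None, :], -dbeta, dbeta)

    xc = dsig - dsig.mean()
    xnorm = np.sqrt((xc * xc).sum())
    yc = dbeta - dbeta.mean(axis=1, keepdims=True)
    ynorm = np.sqrt((yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        null = (yc @ xc) / (ynorm * xnorm)
    null = null[np.isfinite(null)]
    if null.size == 0:
        return stat

    stat.empirical_p = float((1 + np.sum(null >= stat.r_pairwise)) / (null.size + 1))
    grid = quantile_grid if quantile_grid is not None else np.arange(0.01, 1.00, 0.01)
    stat.null_quantiles = np.quantile(null, grid)
    stat._null = null  # retained for Q-Q pooling
    return stat


def qq_table(stats: list[PairwiseStat]) -> pd.DataFrame:
    """Observed pairwise correlations vs pooled-null quantiles.

    Observed values are sorted ascending and matched to quantiles of the
    pooled permutation null at plotting positions (k - 0.5)/n; emitted as a
    (expected, observed) table for Q-Q plotting.
    """
    observed = np.sort([s.r_pairwise for s in stats if np.isfinite(s.r_pairwise)])
    if observed.size < 2:
        raise PrioritizationError("qq_table requires >= 2 defined statistics")
    pools = [getattr(s, "_null", None) for s in stats]
    pools = [p for p in pools if p is not None and len(p)]
    if pools:
        pooled = np.concatenate(pools)
    else:
        qs = [s.null_quantiles for s in stats if s.null_quantiles is not None]
        if not qs:
            raise PrioritizationError("qq_table requires permutation nulls")
        pooled = np.concatenate(qs)
    pos = (np.arange(1, observed.size + 1) - 0.5) / observed.size
    expected = np.quantile(pooled, pos)
    return pd.DataFrame({"expected": expected, "observed": observed})
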