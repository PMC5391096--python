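"""Seeded synthetic cohort with planted ground truth for every stage.

The generator emits a complete input bundle in the exact formats the other
modules read — three GWAS source tables, an LD-proxy table, a significant
eQTL table, super-enhancer intervals, a PWM collection, per-variant sequence
contexts, annotation categories — together with a truth record naming the
planted causal genes, LD blocks, super-enhancer-covered variants, motif
disruptions, and the enriched category.

Causal genes carry SNP-level (-log10 p, oriented beta) pairs drawn from a
bivariate normal with correlation ``rho_causal``; null genes are drawn with
zero correlation.  GWAS significance is generated directly on the -log10
scale (the pipeline consumes only summary statistics), centered well above
the significance threshold so thresholding does not truncate the planted
correlation.  Coordinates live on a small pseudo-genome with variants on a
fixed grid, which keeps interval overlaps exactly controllable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .regulatory import BASES, Pwm, write_jaspar

TISSUE_POOL = [
    "Brain_Cortex", "Brain_Cerebellum", "Whole_Blood", "Liver", "Lung",
    "Muscle_Skeletal", "Thyroid", "Nerve_Tibial", "Skin_Sun_Exposed",
    "Adipose_Subcutaneous",
]
SOURCE_LABELS = ["source1", "source2", "source3"]
CELL_TYPES = ["brain", "blood", "liver"]


class SimulationError(ValueError):
    """Raised on inconsistent cohort configuration."""


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort.

    Defaults describe the reference study condition: 500 egenes, 50 of them
    causal with planted correlation 0.8, 30 risk SNPs per gene, a third of
    variants inside super-enhancers, and half of those disrupting a planted
    motif.
    """
    n_genes: int = 500
    n_causal: int = 50
    snps_per_gene: int = 30
    rho_causal: float = 0.8
    n_tissues: int = 5
    n_index_snps: int = 100          # extra background index SNPs without eQTLs
    n_proxies_per_block: int = 3
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_scale: float = 0.4
    se_fraction: float = 0.3
    motif_fraction: float = 0.5
    seed: int = 0
    # pseudo-genome layout
    n_chroms: int = 8
    spacing: int = 2000              # grid distance between variants, bp
    context_halfwidth: int = 20      # sequence context = 2*hw + 1 bases
    motif_length: int = 11
    n_decoy_pwms: int = 4
    n_categories: int = 10

    def validate(self) -> None:
        if self.n_causal > self.n_genes:
            raise SimulationError("n_causal cannot exceed n_genes")
        if not 0 < self.rho_causal < 1:
            raise SimulationError("rho_causal must lie in (0, 1)")
        for name in ("n_genes", "snps_per_gene", "n_tissues", "n_chroms", "spacing"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if not (0 < self.maf_range[0] < self.maf_range[1] <= 0.5):
            raise SimulationError("maf_range must satisfy 0 < lo < hi <= 0.5")
        for name in ("se_fraction", "motif_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery testing."""
    causal_genes: list[str]
    null_genes: list[str]
    ld_blocks: list[dict]
    se_covered_rsids: list[str]
    motif_disrupted_rsids: list[str]
    enriched_category: str
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
        Path(path).write_text(Path(path).read_text() + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticBundle:
    """Paths of all generated input files."""
    sources: list[Path]
    proxies: Path
    eqtls: Path
    superenhancers: Path
    pwms: Path
    contexts: Path
    categories: Path
    truth: Path
    outdir: Path


def _sample_planted_pairs(rng: np.random.Generator, n: int, rho: float,
                          beta_scale: float) -> tuple[np.ndarray, np.ndarray]:
    """(neglogp, oriented beta) with Pearson correlation rho.

    neglogp ~ N(8, 1) resampled on the < 4.01 tail (probability ~3e-5) so
    every planted variant clears the p < 1e-4 catalog threshold and the
    correlation is not truncated.
    """
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho * rho) * e
    neglogp = 8.0 + x
    while (bad := neglogp < 4.01).any():
        repl = rng.standard_normal(int(bad.sum()))
        neglogp[bad] = 8.0 + repl
        y[bad] = rho * repl + np.sqrt(1 - rho * rho) * rng.standard_normal(int(bad.sum()))
    return neglogp, beta_scale * y


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _planted_pwm(rng: np.random.Generator, pwm_id: str, length: int,
                 peak_pos: int | None = None) -> Pwm:
    """High-information PWM: consensus base prob 0.94 per position, one
    near-deterministic (0.997) maximum-information position."""
    consensus = rng.integers(0, 4, size=length)
    probs = np.full((length, 4), 0.02)
    probs[np.arange(length), consensus] = 0.94
    if peak_pos is not None:
        probs[peak_pos] = (1 - 0.997) / 3
        probs[peak_pos, consensus[peak_pos]] = 0.997
    return Pwm(pwm_id=pwm_id, probs=probs / probs.sum(axis=1, keepdims=True))


def generate_cohort(config: CohortConfig, outdir: str | Path) -> tuple[SyntheticBundle, SyntheticTruth]:
    """Write a full input bundle with planted structure; reproducible from seed.

    Each gene owns ``snps_per_gene`` index SNPs so GWAS significance varies
    within the gene (a single LD block would make it constant and the
    planted correlation undefined); LD proxies are generated as non-eQTL
    offspring of each gene's first SNP to exercise the expansion stage
    without perturbing per-gene correlations.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    rng_gwas, rng_eqtl, rng_se, rng_motif, rng_cat, rng_misc = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    tissues = (TISSUE_POOL + [f"Tissue{k}" for k in range(len(TISSUE_POOL), config.n_tissues)])[: config.n_tissues]
    genes = [f"GENE{g:04d}" for g in range(config.n_genes)]
    causal_idx = np.sort(rng_misc.choice(config.n_genes, size=config.n_causal, replace=False))
    causal = {genes[i] for i in causal_idx}

    chrom_cursor = {f"chr{c + 1}": 10_000 for c in range(config.n_chroms)}

    def next_pos(chrom: str) -> int:
        pos = chrom_cursor[chrom]
        chrom_cursor[chrom] += config.spacing
        return pos

    rs_counter = 1000
    variant_rows = []     # rsid chrom pos ref alt neglogp odds_ratio
    eqtl_rows = []
    proxy_rows = []
    ld_blocks = []

    for g, gene in enumerate(genes):
        chrom = f"chr{g % config.n_chroms + 1}"
        tissue = tissues[g % len(tissues)]
        rho = config.rho_causal if gene in causal else 0.0
        neglogp, oriented = _sample_planted_pairs(
            rng_gwas, config.snps_per_gene, rho, config.beta_scale
        )
        block_rsids = []
        for k in range(config.snps_per_gene):
            rsid = f"rs{rs_counter}"
            rs_counter += 1
            pos = next_pos(chrom)
            ref, alt = rng_misc.choice(list(BASES), size=2, replace=False)
            orx = float(np.exp(rng_gwas.normal(0.15, 0.1)))
            variant_rows.append((rsid, chrom, pos, ref, alt, neglogp[k], orx))
            block_rsids.append(rsid)
            minor_is_alt = int(rng_eqtl.random() < 0.5)
            beta = oriented[k] if minor_is_alt else -oriented[k]
            eqtl_rows.append((
                rsid, gene, f"G{g}", tissue, beta,
                float(10.0 ** -rng_eqtl.uniform(4, 12)),
                float(rng_eqtl.uniform(*config.maf_range)),
                minor_is_alt,
            ))
        # LD block: proxies of the gene's first SNP, no eQTLs of their own
        parent = block_rsids[0]
        proxy_ids = []
        for _ in range(config.n_proxies_per_block):
            rsid = f"rs{rs_counter}"
            rs_counter += 1
            pos = next_pos(chrom)
            ref, alt = rng_misc.choice(list(BASES), size=2, replace=False)
            r2 = float(rng_misc.uniform(0.8, 1.0))
            proxy_rows.append((parent, rsid, r2, chrom, pos, ref, alt))
            proxy_ids.append(rsid)
        span_lo = min(p for (_, _, p, *_ ) in variant_rows[-config.snps_per_gene - config.n_proxies_per_block:])
        ld_blocks.append({
            "chrom": chrom,
            "span": [int(span_lo), int(chrom_cursor[chrom])],
            "index_rsid": parent,
            "member_rsids": proxy_ids,
        })

    # background index SNPs: half significant (exponential -log10 p tail),
    # half uniform p (removed by the catalog threshold)
    for b in range(config.n_index_snps):
        rsid = f"rs{rs_counter}"
        rs_counter += 1
        chrom = f"chr{b % config.n_chroms + 1}"
        pos = next_pos(chrom)
        ref, alt = rng_misc.choice(list(BASES), size=2, replace=False)
        if b % 2 == 0:
            neglogp = 4.0 + float(rng_gwas.exponential(1.0)) + 1e-6
        else:
            neglogp = float(-np.log10(rng_gwas.uniform(1e-4, 1.0)))
        orx = float(np.exp(rng_gwas.normal(0.1, 0.1)))
        variant_rows.append((rsid, chrom, pos, ref, alt, neglogp, orx))

    variants = pd.DataFrame(
        variant_rows, columns=["rsid", "chrom", "pos", "ref", "alt", "neglogp", "or"]
    )
    variants["pvalue"] = 10.0 ** -variants["neglogp"]

    # --- three overlapping GWAS source tables -------------------------------
    n_var = len(variants)
    membership = rng_gwas.random((n_var, 3)) < 0.5
    none = ~membership.any(axis=1)
    membership[none, rng_gwas.integers(0, 3, size=int(none.sum()))] = True
    # the most significant listing carries the planted p; duplicates inflated
    first_src = membership.argmax(axis=1)
    source_paths = []
    for s, label in enumerate(SOURCE_LABELS):
        rows = variants[membership[:, s]].copy()
        is_first = first_src[membership[:, s]] == s
        inflate = 10.0 ** rng_gwas.uniform(0.0, 0.3, size=len(rows))
        rows["pvalue"] = np.where(is_first, rows["pvalue"], np.minimum(rows["pvalue"] * inflate, 1.0))
        path = outdir / f"gwas_{label}.tsv"
        rows[["rsid", "chrom", "pos", "pvalue", "or", "ref", "alt"]].to_csv(path, sep="\t", index=False)
        source_paths.append(path)

    proxies = pd.DataFrame(
        proxy_rows, columns=["index_rsid", "proxy_rsid", "r2", "chrom", "pos", "ref", "alt"]
    )
    proxies_path = outdir / "ld_proxies.tsv"
    proxies.to_csv(proxies_path, sep="\t", index=False)

    eqtls = pd.DataFrame(eqtl_rows, columns=[
        "rsid", "gene_id", "gene_symbol", "tissue", "beta", "pvalue", "maf", "minor_is_alt",
    ])
    eqtls_path = outdir / "eqtls.tsv"
    eqtls.to_csv(eqtls_path, sep="\t", index=False)

    # --- super-enhancers: cover a fixed fraction of catalog variants --------
    catalog_variants = pd.concat([
        variants[variants["pvalue"] < 1e-4][["rsid", "chrom", "pos", "ref", "alt"]],
        proxies.rename(columns={"proxy_rsid": "rsid"})[["rsid", "chrom", "pos", "ref", "alt"]],
    ], ignore_index=True)
    n_se = int(round(config.se_fraction * len(catalog_variants)))
    se_idx = np.sort(rng_se.choice(len(catalog_variants), size=n_se, replace=False))
    se_rows = catalog_variants.iloc[se_idx]
    half = min(150, config.spacing // 2 - 1)
    se_path = outdir / "superenhancers.bed"
    bed = se_rows.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    with open(se_path, "w") as fh:
        for i, row in enumerate(bed.itertuples()):
            start = max(0, row.pos - 1 - half)
            fh.write(f"{row.chrom}\t{start}\t{row.pos - 1 + half}\tSE{i:05d}\t"
                     f"{CELL_TYPES[i % len(CELL_TYPES)]}\n")
    se_covered = sorted(se_rows["rsid"])

    # --- motifs: planted high-information PWM + decoys ----------------------
    peak = config.motif_length // 2
    planted_pwm = _planted_pwm(rng_motif, "TF_PLANTED", config.motif_length, peak_pos=peak)
    pwms = [planted_pwm] + [
        _planted_pwm(rng_motif, f"TF_DECOY{k}", config.motif_length)
        for k in range(config.n_decoy_pwms)
    ]
    pwms_path = outdir / "motifs.jaspar"
    write_jaspar(pwms, pwms_path)

    n_dis = int(round(config.motif_fraction * len(se_rows)))
    dis_idx = np.sort(rng_motif.choice(len(se_rows), size=n_dis, replace=False))
    disrupted = set(se_rows.iloc[dis_idx]["rsid"])

    consensus = planted_pwm.consensus()
    hw = config.context_halfwidth
    alleles: dict[str, tuple[str, str]] = {}
    contexts_path = outdir / "contexts.fasta"
    with open(contexts_path, "w") as fh:
        ordered = pd.concat([
            variants[["rsid", "ref", "alt"]],
            proxies.rename(columns={"proxy_rsid": "rsid"})[["rsid", "ref", "alt"]],
        ], ignore_index=True)
        for row in ordered.itertuples():
            if row.rsid in disrupted:
                # embed the planted motif with the variant at its
                # maximum-information position; alt = least-favored base
                flank_l = _random_seq(rng_motif, hw - peak)
                flank_r = _random_seq(rng_motif, hw - (config.motif_length - peak - 1))
                seq = flank_l + consensus + flank_r
                ref = consensus[peak]
                low = BASES[int(planted_pwm.probs[peak].argmin())]
                alleles[row.rsid] = (ref, low)
            else:
                seq = _random_seq(rng_motif, 2 * hw + 1)
                ref = row.ref
                seq = seq[:hw] + ref + seq[hw + 1:]
                alleles[row.rsid] = (ref, row.alt)
            fh.write(f">{row.rsid}\n{seq}\n")

    # rewrite alleles of disrupted variants into the GWAS/proxy tables so the
    # catalog, contexts, and truth agree
    for path in source_paths:
        df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
        sel = df["rsid"].isin(disrupted)
        df.loc[sel, "ref"] = [alleles[r][0] for r in df.loc[sel, "rsid"]]
        df.loc[sel, "alt"] = [alleles[r][1] for r in df.loc[sel, "rsid"]]
        df.to_csv(path, sep="\t", index=False)
    sel = proxies["proxy_rsid"].isin(disrupted)
    proxies.loc[sel, "ref"] = [alleles[r][0] for r in proxies.loc[sel, "proxy_rsid"]]
    proxies.loc[sel, "alt"] = [alleles[r][1] for r in proxies.loc[sel, "proxy_rsid"]]
    proxies.to_csv(proxies_path, sep="\t", index=False)

    # --- annotation categories: one planted, rest random --------------------
    null_genes = [g for g in genes if g not in causal]
    n_causal_in_cat = min(30, config.n_causal)
    planted_members = sorted(
        list(rng_cat.choice(sorted(causal), size=n_causal_in_cat, replace=False))
        + list(rng_cat.choice(null_genes, size=min(5, len(null_genes)), replace=False))
    )
    cat_path = outdir / "categories.gmt"
    with open(cat_path, "w") as fh:
        fh.write("SET_PLANTED\tplanted over-represented category\t" + "\t".join(planted_members) + "\n")
        for k in range(1, config.n_categories):
            size = min(35, config.n_genes)
            members = sorted(rng_cat.choice(genes, size=size, replace=False))
            fh.write(f"SET{k:02d}\trandom category\t" + "\t".join(members) + "\n")

    truth = SyntheticTruth(
        causal_genes=sorted(causal),
        null_genes=null_genes,
        ld_blocks=ld_blocks,
        se_covered_rsids=se_covered,
        motif_disrupted_rsids=sorted(disrupted),
        enriched_category="SET_PLANTED",
        seed=config.seed,
    )
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)

    bundle = SyntheticBundle(
        sources=source_paths, proxies=proxies_path, eqtls=eqtls_path,
        superenhancers=se_path, pwms=pwms_path, contexts=contexts_path,
        categories=cat_path, truth=truth_path, outdir=outdir,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

@dataclass
class RecoveryMetrics:
    correlation_sensitivity: float
    correlation_specificity: float
    null_pass_rate: float
    se_recall: float
    motif_sensitivity: float
    planted_category_rank: int
    n_causal: int
    n_null: int

    def as_dict(self) -> dict:
        return asdict(self)


def truth_report(truth: SyntheticTruth, result) -> RecoveryMetrics:
    """Score pipeline output against the planted truth.

    Stage recalls are computed over the planted variants *entering* each
    stage, so they measure the stage's own semantics rather than upstream
    attrition.  Raises if the result was produced from a different cohort
    (seed mismatch).
    """
    if getattr(result, "cohort_seed", None) is not None and result.cohort_seed != truth.seed:
        raise SimulationError(
            f"truth seed {truth.seed} does not match pipeline cohort seed {result.cohort_seed}"
        )
    causal = set(truth.causal_genes)
    null = set(truth.null_genes)
    passed = set(result.passed_genes)
    scored = set(result.aggregated.loc[result.aggregated["stat"].notna(), "gene_id"])
    causal_scored = causal & scored
    null_scored = null & scored
    sens = len(passed & causal_scored) / len(causal_scored) if causal_scored else float("nan")
    fpr = len(passed & null_scored) / len(null_scored) if null_scored else float("nan")

    se_in = set(result.corr_variants["rsid"]) & set(truth.se_covered_rsids)
    se_out = set(result.se_variants["rsid"])
    se_recall = len(se_out & se_in) / len(se_in) if se_in else float("nan")

    motif_in = se_out & set(truth.motif_disrupted_rsids)
    motif_out = set(result.motif_variants["rsid"])
    motif_sens = len(motif_out & motif_in) / len(motif_in) if motif_in else float("nan")

    final_enrich = result.enrichment["motif"]
    ranked = final_enrich.sort_values(["adjusted_p", "p_value", "set_id"], kind="mergesort")
    rank = int(np.where(ranked["set_id"].values == truth.enriched_category)[0][0]) + 1

    return RecoveryMetrics(
        correlation_sensitivity=sens,
        correlation_specificity=1 - fpr if np.isfinite(fpr) else float("nan"),
        null_pass_rate=fpr,
        se_recall=se_recall,
        motif_sensitivity=motif_sens,
        planted_category_rank=rank,
        n_causal=len(causal_scored),
        n_null=len(null_scored),
    )
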