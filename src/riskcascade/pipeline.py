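"""Stage cascade orchestration: catalog -> LD -> eQTL -> correlation -> SE -> motif.

``run_pipeline`` executes the full funnel on an input bundle (real files or
a synthesized cohort), writes one TSV per stage plus enrichment tables, a
Q-Q table, and a JSON report of stage counts mirroring the study funnel.
The variant count must be non-increasing across filtering stages and the
gene count non-increasing from the eQTL stage onward; both are asserted on
every run.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from . import eqtl as eq
from . import prioritize as pri
from . import regulatory as reg
from . import enrich as enr
from .simulate import CohortConfig, SyntheticTruth, generate_cohort

log = logging.getLogger(__name__)


class PipelineError(ValueError):
    """Raised on invalid configuration, missing inputs, or broken invariants."""


@dataclass
class PipelineParams:
    """Cascade thresholds; defaults are the reference analysis settings."""
    pvalue_max: float = 1e-4          # GWAS significance threshold
    r2_min: float = 0.8               # LD proxy admission
    correlation_cutoff: float = 0.4   # gene selection statistic cutoff
    min_n: int = 3                    # SNPs needed for a defined correlation
    min_pairs: int = 100              # pairs needed for the pairwise statistic
    n_perm: int = 1000                # permutation-null size
    strong_threshold: float = 2.0     # bits of |delta| for a strong motif call
    match_frac: float = 0.8           # fraction of max PWM score for a motif hit
    aggregation_mode: str = "mean_across_tissues"
    run_permutations: bool = True


@dataclass
class PipelineInputs:
    sources: list[Path]
    proxies: Path
    eqtls: Path
    superenhancers: Path
    pwms: Path
    contexts: Path
    categories: Path
    locus_map: Path | None = None


@dataclass
class PipelineResult:
    report: dict
    catalog: pd.DataFrame
    expanded: pd.DataFrame
    assoc: pd.DataFrame
    scores: pd.DataFrame
    aggregated: pd.DataFrame
    passed_genes: list[str]
    corr_variants: pd.DataFrame
    se_variants: pd.DataFrame
    motif_variants: pd.DataFrame
    motif_calls: pd.DataFrame
    pairwise: pd.DataFrame
    qq: pd.DataFrame | None
    enrichment: dict[str, pd.DataFrame]
    truth: SyntheticTruth | None = None
    cohort_seed: int | None = None
    stage_counts: list[dict] = field(default_factory=list)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"{path}: config must be a YAML mapping")
    return cfg


def _inputs_from_config(cfg: dict, outdir: Path, seed: int | None) -> tuple[PipelineInputs, SyntheticTruth | None, int | None]:
    if "synthesize" in cfg:
        sim_cfg = dict(cfg["synthesize"] or {})
        if seed is not None:
            sim_cfg["seed"] = seed
        if "maf_range" in sim_cfg:
            sim_cfg["maf_range"] = tuple(sim_cfg["maf_range"])
        config = CohortConfig(**sim_cfg)
        bundle, truth = generate_cohort(config, outdir / "inputs")
        inputs = PipelineInputs(
            sources=bundle.sources, proxies=bundle.proxies, eqtls=bundle.eqtls,
            superenhancers=bundle.superenhancers, pwms=bundle.pwms,
            contexts=bundle.contexts, categories=bundle.categories,
        )
        return inputs, truth, config.seed
    if "inputs" not in cfg:
        raise PipelineError("config needs an 'inputs' or 'synthesize' section")
    paths = cfg["inputs"]
    inputs = PipelineInputs(
        sources=[Path(p) for p in paths["sources"]],
        proxies=Path(paths["proxies"]),
        eqtls=Path(paths["eqtls"]),
        superenhancers=Path(paths["superenhancers"]),
        pwms=Path(paths["pwms"]),
        contexts=Path(paths["contexts"]),
        categories=Path(paths["categories"]),
        locus_map=Path(paths["locus_map"]) if paths.get("locus_map") else None,
    )
    for f in [*inputs.sources, inputs.proxies, inputs.eqtls, inputs.superenhancers,
              inputs.pwms, inputs.contexts, inputs.categories]:
        if not Path(f).exists():
            raise PipelineError(f"missing input file: {f}")
    return inputs, None, None


def validate_inputs(inputs: PipelineInputs) -> dict:
    """Schema checks for every input file; aggregates all violations."""
    violations: list[str] = []
    counts: dict[str, int] = {}

    for path in inputs.sources:
        try:
            df = cat.read_source_table(path)
            counts[str(path)] = len(df)
            bad = df[(df["pvalue"] <= 0) | (df["pvalue"] > 1)]
            for row in bad.itertuples():
                violations.append(f"{path}: p-value out of (0,1] at rsid {row.rsid} (row {row.Index + 1})")
        except Exception as exc:  # noqa: BLE001 - aggregate all problems
            violations.append(f"{path}: {exc}")
    try:
        prox = cat.read_proxy_table(inputs.proxies)
        counts[str(inputs.proxies)] = len(prox)
        bad = prox[(prox["r2"] < 0) | (prox["r2"] > 1)]
        for row in bad.itertuples():
            violations.append(f"{inputs.proxies}: r2 out of [0,1] at row {row.Index + 1}")
    except Exception as exc:
        violations.append(f"{inputs.proxies}: {exc}")
    try:
        eqtls = eq.read_eqtl_table(inputs.eqtls)
        counts[str(inputs.eqtls)] = len(eqtls)
        bad = eqtls[(eqtls["maf"] <= 0) | (eqtls["maf"] > 0.5)]
        for row in bad.itertuples():
            violations.append(f"{inputs.eqtls}: MAF out of (0,0.5] at row {row.Index + 1}")
    except Exception as exc:
        violations.append(f"{inputs.eqtls}: {exc}")
    try:
        ivs = reg.read_bed(inputs.superenhancers)
        counts[str(inputs.superenhancers)] = len(ivs)
    except Exception as exc:
        violations.append(f"{inputs.superenhancers}: {exc}")
    try:
        counts[str(inputs.pwms)] = len(reg.read_jaspar(inputs.pwms))
    except Exception as exc:
        violations.append(f"{inputs.pwms}: {exc}")
    try:
        counts[str(inputs.contexts)] = len(reg.read_contexts_fasta(inputs.contexts))
    except Exception as exc:
        violations.append(f"{inputs.contexts}: {exc}")
    try:
        counts[str(inputs.categories)] = len(enr.read_gmt(inputs.categories))
    except Exception as exc:
        violations.append(f"{inputs.categories}: {exc}")
    return {"violations": violations, "row_counts": counts, "ok": not violations}


def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path,
    seed: int | None = None,
) -> PipelineResult:
    """Execute the full cascade and write per-stage outputs under ``outdir``.

    ``config`` is a YAML path or an equivalent mapping with ``inputs`` (file
    paths) or ``synthesize`` (cohort parameters) plus optional ``params``
    overrides and a ``seed``.  An explicit ``seed`` argument overrides the
    config for both synthesis and permutation nulls.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else config.get("seed", 0)
    params = PipelineParams(**(config.get("params") or {}))
    inputs, truth, cohort_seed = _inputs_from_config(config, outdir, seed)

    t0 = time.time()
    stage_counts: list[dict] = []

    def record(stage: str, n_variants: int, n_genes: int | None, paths: list[str]) -> None:
        stage_counts.append({
            "stage": stage, "n_variants": int(n_variants),
            "n_genes": None if n_genes is None else int(n_genes),
            "outputs": paths,
        })

    # 1. catalog: union of source tables under the significance threshold
    tables = [cat.read_source_table(p) for p in inputs.sources]
    catalog = cat.merge_risk_sources(tables, pvalue_max=params.pvalue_max)
    cat.write_catalog(catalog, outdir / "catalog.tsv")
    record("catalog", len(catalog), None, ["catalog.tsv"])

    # 2. LD expansion
    proxies = cat.read_proxy_table(inputs.proxies)
    expanded = cat.expand_ld(catalog, proxies, r2_min=params.r2_min)
    cat.write_catalog(expanded, outdir / "expanded.tsv")
    record("ld_expansion", len(expanded), None, ["expanded.tsv"])

    # 3. eQTL join + orientation
    eqtls = eq.read_eqtl_table(inputs.eqtls)
    assoc, join_report = eq.join_eqtls(expanded, eqtls)
    assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    summary = eq.summarize_egenes(assoc)
    summary.table.to_csv(outdir / "egene_summary.tsv", sep="\t", index=False)
    eq.manhattan_table(assoc).to_csv(outdir / "manhattan.tsv", sep="\t", index=False)
    egenes = sorted(set(assoc["gene_id"]))
    record("eqtl_join", assoc["rsid"].nunique(), len(egenes),
           ["associations.tsv", "egene_summary.tsv", "manhattan.tsv"])

    # 4. correlation filter
    scores = pri.score_genes(assoc, min_n=params.min_n)
    aggregated = pri.aggregate_gene_scores(scores, mode=params.aggregation_mode)
    passed_genes = pri.filter_genes(aggregated, cutoff=params.correlation_cutoff)
    scores.to_csv(outdir / "gene_scores.tsv", sep="\t", index=False)
    aggregated.to_csv(outdir / "gene_scores_aggregated.tsv", sep="\t", index=False)
    pri.heatmap_matrix(scores, passed_genes).to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
    (outdir / "genes_pass.txt").write_text("\n".join(passed_genes) + ("\n" if passed_genes else ""))
    corr_variants = expanded[expanded["rsid"].isin(
        set(assoc.loc[assoc["gene_id"].isin(passed_genes), "rsid"])
    )].reset_index(drop=True)
    corr_variants.to_csv(outdir / "corr_variants.tsv", sep="\t", index=False)
    record("correlation_filter", len(corr_variants), len(passed_genes),
           ["gene_scores.tsv", "gene_scores_aggregated.tsv", "heatmap_matrix.tsv",
            "genes_pass.txt", "corr_variants.tsv"])

    # 4b. pairwise difference statistic with permutation null (reporting only)
    pairwise_rows = []
    stats: list[pri.PairwiseStat] = []
    if params.run_permutations:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 17]))
        for (gene, tissue), grp in assoc.groupby(["gene_id", "tissue"], sort=True):
            s = pri.permutation_null(grp, n_perm=params.n_perm, seed=rng,
                                     min_pairs=params.min_pairs)
            if np.isfinite(s.r_pairwise):
                stats.append(s)
                pairwise_rows.append((gene, tissue, s.n_snps, s.n_pairs,
                                      s.r_pairwise, s.empirical_p))
    pairwise = pd.DataFrame(pairwise_rows, columns=[
        "gene_id", "tissue", "n_snps", "n_pairs", "r_pairwise", "empirical_p"])
    pairwise.to_csv(outdir / "pairwise_stats.tsv", sep="\t", index=False)
    qq = None
    if len(stats) >= 2:
        qq = pri.qq_table(stats)
        qq.to_csv(outdir / "qq.tsv", sep="\t", index=False)

    # 5. super-enhancer overlap
    intervals = reg.read_bed(inputs.superenhancers)
    se_variants = reg.overlap_superenhancers(corr_variants, intervals)
    se_variants.to_csv(outdir / "se_variants.tsv", sep="\t", index=False)
    se_genes = sorted(set(assoc.loc[
        assoc["rsid"].isin(set(se_variants["rsid"])) & assoc["gene_id"].isin(passed_genes),
        "gene_id"]))
    record("superenhancer_overlap", len(se_variants), len(se_genes), ["se_variants.tsv"])

    # 6. motif-disruption filter
    pwms = reg.read_jaspar(inputs.pwms)
    contexts = reg.read_contexts_fasta(inputs.contexts)
    motif_variants, calls, motif_stats = reg.filter_by_motif(
        se_variants, pwms, contexts,
        strong_threshold=params.strong_threshold, match_frac=params.match_frac,
    )
    motif_variants.to_csv(outdir / "motif_variants.tsv", sep="\t", index=False)
    calls.to_csv(outdir / "motif_calls.tsv", sep="\t", index=False)
    reg.write_variant_bed(motif_variants, outdir / "final_variants.bed")
    motif_genes = sorted(set(assoc.loc[
        assoc["rsid"].isin(set(motif_variants["rsid"])) & assoc["gene_id"].isin(passed_genes),
        "gene_id"]))
    record("motif_filter", len(motif_variants), len(motif_genes),
           ["motif_variants.tsv", "motif_calls.tsv", "final_variants.bed"])

    # 7. enrichment per stage against the egene background
    categories = enr.read_gmt(inputs.categories)
    locus_map = enr.read_locus_map(inputs.locus_map) if inputs.locus_map else None
    background = set(egenes)
    stage_gene_sets = {
        "eqtl": background,
        "correlation": set(passed_genes),
        "superenhancer": set(se_genes),
        "motif": set(motif_genes),
    }
    enrichment: dict[str, pd.DataFrame] = {}
    for stage, genes in stage_gene_sets.items():
        query, bg, cats = genes, background, categories
        if locus_map:
            query = enr.collapse_locus(query, locus_map)
            bg = enr.collapse_locus(bg, locus_map)
            cats = {k: enr.collapse_locus(v, locus_map) for k, v in categories.items()}
        table = enr.hypergeometric_enrichment(query, cats, bg)
        table.to_csv(outdir / f"enrichment_{stage}.tsv", sep="\t", index=False)
        enrichment[stage] = table
        (outdir / f"genes_{stage}.gmt").write_text(
            f"{stage}\tgene set after {stage} stage\t" + "\t".join(sorted(genes)) + "\n"
        )

    _assert_funnel(stage_counts)

    report = {
        "params": dataclasses.asdict(params),
        "seed": int(seed),
        "cohort_seed": cohort_seed,
        "stages": stage_counts,
        "join": dataclasses.asdict(join_report),
        "egene_summary": {"median": summary.median_egenes, "max": summary.max_egenes},
        "motif_stats": dataclasses.asdict(motif_stats),
        "timestamps": {"started": t0, "finished": time.time()},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)

    return PipelineResult(
        report=report, catalog=catalog, expanded=expanded, assoc=assoc,
        scores=scores, aggregated=aggregated, passed_genes=passed_genes,
        corr_variants=corr_variants, se_variants=se_variants,
        motif_variants=motif_variants, motif_calls=calls, pairwise=pairwise,
        qq=qq, enrichment=enrichment, truth=truth, cohort_seed=cohort_seed,
        stage_counts=stage_counts,
    )


def _assert_funnel(stage_counts: list[dict]) -> None:
    """Variant counts non-increasing across filtering stages (LD expansion
    may grow the set); gene counts non-increasing from the eQTL stage on."""
    filtering = [s for s in stage_counts if s["stage"] != "ld_expansion"][1:]
    variants = [s["n_variants"] for s in filtering]
    if any(b > a for a, b in zip(variants, variants[1:])):
        raise PipelineError(f"variant funnel is not monotone: {variants}")
    genes = [s["n_genes"] for s in stage_counts if s["n_genes"] is not None]
    if any(b > a for a, b in zip(genes, genes[1:])):
        raise PipelineError(f"gene funnel is not monotone: {genes}")
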