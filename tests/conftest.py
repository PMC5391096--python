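import numpy as np
import pandas as pd
import pytest

from riskcascade import CohortConfig, run_pipeline


def make_assoc(sig, beta, gene="GENE0001", tissue="Liver", rsids=None):
    """Association frame for one (gene, tissue) group from raw vectors."""
    sig = np.asarray(sig, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = sig.size
    rsids = rsids if rsids is not None else [f"rs{i}" for i in range(n)]
    return pd.DataFrame({
        "rsid": rsids,
        "gene_id": gene,
        "gene_symbol": gene,
        "tissue": tissue,
        "beta": beta,
        "eqtl_pvalue": 1e-6,
        "maf": 0.2,
        "alt_is_minor": True,
        "oriented_beta": beta,
        "gwas_neglogp": sig,
        "odds_ratio": 1.2,
        "chrom": "chr1",
        "pos": np.arange(1000, 1000 + n),
    })


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the reference synthetic cohort (500 genes, 50 causal
    at rho 0.8, 30 SNPs/gene), permutations off for speed; shared across
    recovery tests."""
    outdir = tmp_path_factory.mktemp("default_run")
    result = run_pipeline(
        {"synthesize": {}, "params": {"run_permutations": False}},
        outdir, seed=7,
    )
    return result


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Small synthetic cohort bundle for IO round-trip and stage tests."""
    from riskcascade import generate_cohort
    outdir = tmp_path_factory.mktemp("small_bundle")
    config = CohortConfig(n_genes=24, n_causal=6, snps_per_gene=12,
                          n_index_snps=20, seed=5)
    bundle, truth = generate_cohort(config, outdir)
    return bundle, truth
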