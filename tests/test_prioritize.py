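"""Gene correlation scoring, filtering, and the pairwise difference statistic."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from riskcascade import (
    PrioritizationError, aggregate_gene_scores, filter_genes, gene_correlation,
    pairwise_snp_statistic, pearson, permutation_null, qq_table, score_genes,
)
from riskcascade.prioritize import PairwiseStat, _pair_diffs
from tests.conftest import make_assoc


def test_perfect_linearity_gives_unit_correlation():
    up = gene_correlation(make_assoc([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4]))
    assert up.pearson_r == pytest.approx(1.0, abs=1e-9)
    down = gene_correlation(make_assoc([1, 2, 3, 4], [0.4, 0.3, 0.2, 0.1]))
    assert down.pearson_r == pytest.approx(-1.0, abs=1e-9)


def test_correlation_matches_direct_formula():
    score = gene_correlation(make_assoc([1, 2, 3], [0.2, 0.1, 0.5]), min_n=3)
    x, y = np.array([1, 2, 3.0]), np.array([0.2, 0.1, 0.5])
    direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    assert score.pearson_r == pytest.approx(direct, abs=1e-12)
    assert score.n_snps == 3


def test_pearson_agrees_with_scipy_on_random_vectors():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = rng.integers(3, 40)
        x, y = rng.normal(size=n), rng.normal(size=n)
        assert pearson(x, y) == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-12)


def test_undefined_below_min_n_or_constant():
    assert np.isnan(gene_correlation(make_assoc([1, 2], [0.1, 0.2])).pearson_r)
    assert np.isnan(gene_correlation(make_assoc([1, 1, 1], [0.1, 0.2, 0.3])).pearson_r)
    dup = make_assoc([1, 2, 3], [0.1, 0.2, 0.3], rsids=["rs1", "rs1", "rs2"])
    assert gene_correlation(dup).n_snps == 2  # distinct SNPs only


def test_mixed_group_raises():
    mixed = pd.concat([make_assoc([1, 2, 3], [0.1, 0.2, 0.3], gene="A"),
                       make_assoc([1, 2, 3], [0.1, 0.2, 0.3], gene="B")])
    with pytest.raises(PrioritizationError):
        gene_correlation(mixed)


def test_aggregation_mean_and_modes():
    scores = pd.DataFrame({
        "gene_id": ["A", "A", "B"],
        "tissue": ["T1", "T2", "T1"],
        "n_snps": [5, 5, 5],
        "pearson_r": [0.5, 0.3, 0.7],
    })
    agg = aggregate_gene_scores(scores, mode="mean_across_tissues").set_index("gene_id")
    assert agg.loc["A", "mean_r"] == pytest.approx(0.4)
    assert agg.loc["B", "mean_r"] == pytest.approx(0.7)
    per = aggregate_gene_scores(scores, mode="per_tissue").set_index("gene_id")
    assert per.loc["A", "stat"] == pytest.approx(0.5)
    # undefined-everywhere gene is excluded from filtering
    allnan = pd.DataFrame({"gene_id": ["C"], "tissue": ["T1"], "n_snps": [2],
                           "pearson_r": [np.nan]})
    agg2 = aggregate_gene_scores(allnan)
    assert np.isnan(agg2.iloc[0]["stat"])
    assert filter_genes(agg2, cutoff=-1.0) == []


def test_filter_boundary_inclusive_at_cutoff():
    agg = pd.DataFrame({"gene_id": ["A", "B", "C"], "n_tissues": 1, "n_defined": 1,
                        "n_snps": 9, "mean_r": [0.9, 0.39, 0.41],
                        "stat": [0.9, 0.39, 0.41]})
    assert filter_genes(agg, cutoff=0.4) == ["A", "C"]
    assert filter_genes(agg, cutoff=-1.0) == ["A", "B", "C"]
    assert filter_genes(agg, cutoff=1.0) == []


def test_score_genes_invariant_to_row_order():
    rng = np.random.default_rng(8)
    assoc = pd.concat([
        make_assoc(rng.normal(5, 1, 8), rng.normal(0, 1, 8), gene="A", tissue="T1"),
        make_assoc(rng.normal(5, 1, 8), rng.normal(0, 1, 8), gene="B", tissue="T2"),
    ], ignore_index=True)
    shuffled = assoc.sample(frac=1, random_state=1)
    pd.testing.assert_frame_equal(score_genes(assoc), score_genes(shuffled))


# ---------------------------------------------------------------------------
# Pairwise SNP-SNP statistic
# ---------------------------------------------------------------------------

def test_pairwise_collinear_points_give_unit_statistic():
    assoc = make_assoc([1, 2, 3], [0.1, 0.2, 0.3])
    stat = pairwise_snp_statistic(assoc, min_pairs=3)
    assert stat.n_pairs == 3
    assert stat.r_pairwise == pytest.approx(1.0, abs=1e-9)


def brute_force_pairwise(sig, beta):
    dsig, dbeta = [], []
    n = len(sig)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sig[i] - sig[j], beta[i] - beta[j]
            if a < 0:
                a, b = -a, -b
            dsig.append(a)
            dbeta.append(b)
    return sps.pearsonr(dsig, dbeta).statistic


def test_pairwise_matches_double_loop_oracle():
    rng = np.random.default_rng(12)
    sig = rng.uniform(4, 10, 10)
    beta = rng.normal(0, 0.4, 10)
    stat = pairwise_snp_statistic(make_assoc(sig, beta), min_pairs=10)
    assert stat.n_pairs == 45
    assert stat.r_pairwise == pytest.approx(brute_force_pairwise(sig, beta), abs=1e-12)


def test_pairwise_undefined_below_min_pairs():
    stat = pairwise_snp_statistic(make_assoc([1, 2, 3], [0.1, 0.2, 0.3]), min_pairs=100)
    assert np.isnan(stat.r_pairwise)


def test_permutation_null_add_one_formula_and_determinism():
    rng = np.random.default_rng(5)
    sig = np.linspace(4, 9, 15)
    beta = 0.1 * sig  # perfect correlation: observed r = 1 beats every null
    assoc = make_assoc(sig, beta + 0)
    s1 = permutation_null(assoc, n_perm=199, seed=7, min_pairs=100)
    assert s1.empirical_p == pytest.approx(1 / 200)
    s2 = permutation_null(assoc, n_perm=199, seed=7, min_pairs=100)
    np.testing.assert_array_equal(s1.null_quantiles, s2.null_quantiles)
    s3 = permutation_null(assoc, n_perm=199, seed=8, min_pairs=100)
    assert not np.array_equal(s1.null_quantiles, s3.null_quantiles)


def test_permutation_p_uniform_under_null():
    # independent vectors: empirical p should look uniform (KS sanity check)
    rng = np.random.default_rng(6)
    pvals = []
    for _ in range(100):
        assoc = make_assoc(rng.uniform(4, 10, 15), rng.normal(0, 0.4, 15))
        s = permutation_null(assoc, n_perm=200, seed=rng, min_pairs=100)
        pvals.append(s.empirical_p)
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_qq_table_diagonal_and_shift():
    rng = np.random.default_rng(13)
    null = rng.normal(0, 0.1, 5000)
    stats = []
    for r in rng.normal(0, 0.1, 200):
        s = PairwiseStat("G", "T", 15, 105, float(r))
        s._null = null
        stats.append(s)
    qq = qq_table(stats)
    assert np.abs(qq["observed"] - qq["expected"]).mean() < 0.02
    shifted = []
    for r in rng.normal(0.3, 0.1, 200):
        s = PairwiseStat("G", "T", 15, 105, float(r))
        s._null = null
        shifted.append(s)
    qq2 = qq_table(shifted)
    assert (qq2["observed"] > qq2["expected"]).mean() > 0.95
    assert (qq["observed"].values == np.sort(qq["observed"].values)).all()


def test_pair_orientation_makes_dsig_nonnegative():
    rng = np.random.default_rng(14)
    dsig, dbeta = _pair_diffs(rng.normal(size=12), rng.normal(size=12))
    assert (dsig >= 0).all()
    assert dsig.size == 66
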