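"""Build a risk-variant catalog from multiple GWAS sources and expand by LD.

Three small source tables share one variant; the catalog unions them, keeps
the most significant p-value, applies the p < 1e-4 threshold, and then pulls
in LD proxies at r^2 >= 0.8, annotating each proxy with its most significant
parent.
"""
import pandas as pd

from riskcascade import expand_ld, merge_risk_sources


def table(rows, label):
    df = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "pvalue", "or", "ref", "alt"])
    df["source"] = label
    return df


sources = [
    table([("rs111", "chr4", 90_640_000, 2e-8, 1.30, "A", "G"),
           ("rs222", "chr17", 43_720_000, 5e-6, 1.15, "C", "T")], "catalogA"),
    table([("rs111", "chr4", 90_640_000, 4e-7, 1.28, "A", "G"),
           ("rs333", "chr6", 32_580_000, 8e-5, 1.22, "G", "A")], "catalogB"),
    table([("rs444", "chr12", 40_310_000, 3e-2, 1.05, "T", "C")], "catalogC"),
]

catalog = merge_risk_sources(sources, pvalue_max=1e-4)
print(catalog[["rsid", "chrom", "gwas_pvalue", "sources"]].to_string(index=False))
# rs111 appears once with both sources and p = 2e-8 (the smaller of its two
# listings); rs444 (p = 0.03) fails the threshold and is dropped.

proxies = pd.DataFrame({
    "index_rsid": ["rs111", "rs111", "rs222"],
    "proxy_rsid": ["rs555", "rs666", "rs777"],
    "r2": [0.95, 0.72, 0.88],
})
expanded = expand_ld(catalog, proxies, r2_min=0.8)
print()
print(expanded[["rsid", "is_index", "parent_rsid", "r2_to_parent", "gwas_pvalue"]]
      .to_string(index=False))
# rs666 (r^2 = 0.72) is excluded; each admitted proxy inherits its parent's
# GWAS p-value, which is how downstream stages rank proxy variants.
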