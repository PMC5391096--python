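"""Test a filtered gene set for category over-representation.

The query (genes surviving the cascade) is compared to annotation
categories against a background of all egenes with the one-sided
hypergeometric test; collapse_locus demonstrates how clustered paralogs
(e.g. an MHC-like locus) are reduced to a single signal first.
"""
from riskcascade import collapse_locus, hypergeometric_enrichment

background = {f"GENE{i:03d}" for i in range(60)}
immune = {f"GENE{i:03d}" for i in range(10)}          # 10-gene category
metabolic = {f"GENE{i:03d}" for i in range(30, 45)}   # 15-gene category
query = {f"GENE{i:03d}" for i in range(8)} | {"GENE050"}  # 8 of 10 immune genes

table = hypergeometric_enrichment(query, {"immune": immune, "metabolic": metabolic},
                                  background)
print(table.to_string(index=False))
# immune: 8/10 category genes in a 9-gene query from a 60-gene background
# is wildly unlikely by chance (p ~ 1e-8); metabolic overlaps nothing (p = 1).

locus_map = {g: "shared_locus" for g in list(immune)[:6]}
collapsed_query = collapse_locus(query, locus_map)
collapsed_bg = collapse_locus(background, locus_map)
collapsed_cats = {"immune": collapse_locus(immune, locus_map)}
table2 = hypergeometric_enrichment(collapsed_query, collapsed_cats, collapsed_bg)
print()
print(table2.to_string(index=False))
# After collapsing six clustered genes to one representative the enrichment
# weakens but survives - the signal is not an artifact of counting one locus
# many times.
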