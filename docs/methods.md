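# Methods

## Model and assumptions

The pipeline operationalizes one causal hypothesis: a risk variant acts by
changing the expression of a nearby gene through a regulatory element. Under
that model, among a gene's associated SNPs, those with larger expression
effects should carry stronger GWAS signal, so the per-gene correlation
between GWAS significance and eQTL effect size is the central statistic.
The cascade assumes:

- **Summary statistics suffice.** No genotypes are used anywhere. GWAS
  evidence enters as p-values and odds ratios; eQTL evidence as
  per-allele effect sizes (β), p-values and MAF from an external
  significant-eQTL table. eQTL significance is taken as given and not
  re-assessed.
- **LD proxies are exchangeable with their index SNP.** A proxy at
  r² ≥ 0.8 inherits the most significant p-value among its linked parents;
  the parent attaining the minimum is recorded. Ties are broken by parent
  rsID so reruns are identical.
- **Effect signs are only comparable after orientation.** Supplied betas are
  per alt allele; they are flipped to per-minor-allele using the table's
  `minor_is_alt` flag. When the flag is absent the alt allele is assumed
  minor and the assumption is counted in the join report, since a silent
  convention mismatch would scramble every downstream sign.
- **GWAS significance is −log₁₀ p** throughout (Manhattan-plot convention).

## Statistics

**Per-gene correlation.** Pearson r of (−log₁₀ p, β_minor) over a gene's
distinct SNPs, per tissue; undefined (NaN, excluded from filtering) when
fewer than `min_n = 3` SNPs are available or either variable is constant —
a low-n correlation is noise and deliberately does not default to 0.
Per-tissue values are averaged (unweighted) across tissues; a `per_tissue`
mode using the per-tissue maximum is available. Genes pass at mean r ≥ 0.4
(boundary inclusive). No multiple-testing correction is applied at this
stage: the cutoff is a sensitivity choice, not a significance test.

**Pairwise difference statistic.** For all unordered SNP pairs of a
(gene, tissue) group, Δsig and Δβ are formed and each pair is oriented so
Δsig ≥ 0 (this fixes the sign ambiguity of unordered pairs; pairs with
Δsig = 0 keep their index order). The statistic is the Pearson r of
(Δsig, Δβ), defined only when at least `min_pairs = 100` pairs exist
(n ≥ 15 SNPs). The null is built by shuffling the β vector against the
significance vector `n_perm = 1000` times (the pair orientation depends only
on the significance vector, so it is computed once and the null is fully
vectorized); the empirical p is the add-one rank
(1 + #{null ≥ observed}) / (n_perm + 1), which is exactly uniform on a
discrete lattice under the null. Q-Q tables plot sorted observed statistics
against pooled-null quantiles at positions (k − ½)/n.

**Motif disruption.** PWM probabilities are pseudocount-adjusted,
(p + c)/(1 + 4c) with c = 0.001, and scored as log₂ odds against a
background (uniform 0.25 by default). Every window covering the variant is
scored on both strands for the reference and alternate sequence; the call
maximizing |Δ| among windows whose better allele reaches the match
threshold is returned. "Strong disruption" is defined by two explicit
thresholds: the better allele must score ≥ 80 % of the PWM's maximum
achievable log-odds (it must look like a motif hit at all), and
|Δ| ≥ 2 bits. These defaults are this package's own operational definition
of a strong call — external motif tools classify disruption strength by
their own internal rules, so counts are comparable only qualitatively.
Because Δ for a SNV reduces to a single-position log-odds difference, the
same magnitude can be attained by more than one (strand, offset) window;
the reported window is the first attaining the maximum (ascending offset,
'+' before '−'). Only SNVs are scored; indels pass the interval filter but
are skipped here with a counted warning.

**Enrichment.** Upper-tail hypergeometric probability of the observed
overlap, categories intersected with the background first, query genes
outside the background dropped with a logged count, Benjamini–Hochberg
across the categories tested at a stage. `collapse_locus` replaces genes
sharing a locus label by the lexicographically first member, applied
consistently to query, background and categories, as a mitigation for
clustered paralogs violating the test's independence assumption.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `pvalue_max` | 1e-4 | GWAS inclusion threshold (catalog stage) |
| `r2_min` | 0.8 | LD proxy admission, comparison is ≥ |
| `correlation_cutoff` | 0.4 | gene selection on tissue-averaged r |
| `min_n` | 3 | distinct SNPs for a defined correlation |
| `min_pairs` | 100 | pairs for a defined pairwise statistic |
| `n_perm` | 1000 | permutation-null size |
| `match_frac` | 0.8 | motif-hit threshold as fraction of max score |
| `strong_threshold` | 2.0 bits | allele score difference for a strong call |

All are explicit in `PipelineParams` / the YAML config.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
a population-genetic process. For each gene, SNP-level (−log₁₀ p, β_minor)
pairs are drawn from a bivariate normal with correlation ρ (0.8 for causal
genes, 0 for null genes); −log₁₀ p is centered at 8 (sd 1) and resampled on
the < 4.01 tail (probability ≈ 3·10⁻⁵) so the catalog threshold never
truncates the planted correlation. The stored alt-allele β is sign-flipped
wherever the minor allele is the reference allele, so the orientation step
is exercised non-trivially. Each gene owns its own index SNPs — a single
LD block per gene would make GWAS significance constant within the gene and
the target correlation undefined — while LD proxies are generated as
non-eQTL offspring of each gene's first SNP, exercising expansion without
perturbing per-gene correlations. Super-enhancer intervals are placed
around an exact, known subset of catalog variants on a 2-kb coordinate grid
(interval half-width 150 bp), so interval recall and precision are both
exactly measurable. Motif-disrupted variants get the planted
high-information PWM's consensus embedded in their sequence context with
the variant at the maximum-information position and the least-favored base
as the alternate allele. One annotation category is stacked with causal
genes; the rest are random draws.

The default configuration — 500 genes, 50 causal at ρ = 0.8, 30 SNPs per
gene, 5 tissues (each gene measured in one tissue), MAF ~ U(0.05, 0.5),
β scale 0.4, 30 % super-enhancer coverage, 50 % of covered variants
motif-disrupted — is the reference condition for the recovery metrics. At
n = 30 and cutoff 0.4, the Fisher-z approximation predicts sensitivity
≈ 0.9998 for ρ = 0.8 and a null pass rate ≈ 0.014, which the simulation
reproduces (measured 1.00 and ≈ 0.018).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: LD-induced correlation of GWAS statistics
*within* a gene's SNP set (planted pairs are i.i.d., real neighboring SNPs
are not independent), shared eQTL signal across tissues, winner's-curse
inflation of reported effects, allele-frequency-dependent power,
cross-gene sharing of variants at a locus, and realistic motif-score
background distributions in genomic sequence. Recovery rates on real
cohorts will be worse than the planted-simulation figures; the simulation
validates the machinery and its thresholds' internal consistency, not
field performance.

## Numerical and design choices

- Pearson correlation is computed by the covariance/σ formula in one shared
  routine (cross-checked against scipy in tests to 1e-12); the permutation
  path vectorizes the same formula.
- Deterministic ordering everywhere: catalogs sorted by rsID, stable
  (mergesort) sorts, ties in parent selection broken by rsID, enrichment
  sorted by (p, set_id). Identical config + seed reproduces every output
  file byte for byte; seeding is hierarchical (one root seed spawns
  per-component generators).
- Duplicate rsIDs across GWAS sources are merged keeping the minimum
  p-value and the union of source labels, consistent with the
  proxy-annotation rule.
- Variants are not required to be SNPs; non-SNV alleles ride through the
  catalog and interval stages and are excluded (counted) from motif
  scoring.
- Degenerate inputs: constant significance or effect vectors yield
  undefined statistics (flagged, never 0); an empty stage output does not
  abort the pipeline — downstream stages report 0 and enrichment returns
  p = 1 rows.
- The funnel invariant (variant counts non-increasing across filtering
  stages, gene counts non-increasing from the eQTL stage) is asserted on
  every run; violation is a hard error, not a warning.
- Stage recalls in `truth_report` are computed over planted items
  *entering* each stage, measuring the stage's own semantics rather than
  upstream attrition.

## Problem sizes

The test suite and the acceptance script run the reference cohort
(500 genes × 30 SNPs ≈ 15,000 eQTL associations, ≈ 16,600 catalog
variants), a 200-gene null cohort at n_perm = 1000 for the uniformity
check, and 100-instance random-oracle sweeps per core operation; the whole
suite completes in well under a minute on one CPU.

## Known limitations

- Correlation-based gene selection inherits all caveats of small-n Pearson
  correlations; `min_n = 3` admits very noisy estimates by design (the
  cutoff, not a test, does the filtering).
- The motif filter's thresholds are heuristic and PWM-information-content
  dependent; low-information PWMs can never produce a strong call at the
  80 % match threshold.
- `collapse_locus` requires a user-supplied locus map; no positional
  clustering is inferred.
- Enrichment p-values depend entirely on the user's category files and
  background; they are not comparable across annotation databases.
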