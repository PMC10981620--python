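# Methods

## The screen

The package implements a per-miRNA enrichment screen over immunological
GO terms, followed by an immune-signature correlation analysis. All
stages operate on complete (no missing values) features × samples
expression matrices; samples are aligned between the miRNA and gene
matrices by ID intersection, never positionally.

### Ranked gene lists

For miRNA *m*, each gene's score is the sample Pearson correlation
between the gene's and the miRNA's expression over shared samples.
Genes with zero variance over the shared samples are excluded and
counted (`n_dropped_constant`); remaining genes are sorted by score
descending with exact ties broken by gene ID, so the ranking is a
deterministic function of the input. P-values for individual
correlations use the t transformation `t = r·sqrt((n−2)/(1−r²))`
(two-sided); Spearman coefficients are Pearson coefficients of
average-ranked vectors.

### Pre-ranked GSEA

The enrichment score is the classic weighted running sum: walking the
ranked list, an in-set gene raises the sum by `|r|^w / Σ_hits |r|^w`
and every other gene lowers it by `1/(N − N_hits)`; ES is the running
sum's maximal signed deviation from zero. `w = 1` by default (`w = 0`
reduces the statistic to the unweighted Kolmogorov–Smirnov form, which
the tests verify against a direct ECDF-difference computation). The
extrema of the walk occur only at hit boundaries, so ES is computed in
O(k) per set after position lookup; the full-length walk is
materialised only when the caller asks for the running sum. When the
positive and negative extrema tie in magnitude to within 1e−12 the
positive one is reported; such ties are measure-zero for continuous
scores but systematic at `w = 0`.

Because the input is a pre-ranked list, the null is gene-label
permutation: ES values of uniformly random same-size gene subsets of
the same ranking. Identical set sizes share one null sample per ranked
list (the screen's hot loop: 500 permutations × many GO terms), drawn
in sorted-size order from the stage seed for determinism. Subsets are
drawn by duplicate-rejection integer sampling when `8k < N` (uniform by
symmetry, O(n_perm·k)) and by arg-partitioned uniform noise otherwise.

Nominal p-values are sign-sided with an add-one correction:

    p = (1 + #{same-sign null ES at least as extreme}) / (1 + #{same-sign null ES}).

The matching-sign count appears in the denominator as well as the
numerator: with a symmetric null this makes p uniform under the null
(the package's calibration tests measure type-I error 0.047 at
α = 0.05), whereas dividing by the total permutation count would double
the realised error rate. `NES = ES / mean(|null ES| of the matching
sign)`, and FDR follows the canonical pooled-permutation procedure:
each size's null sample is normalised the same way, pooled over tested
sets, and the observed-vs-null tail-fraction ratio is clipped to
[0, 1]. Results are ordered by FDR, then |NES|, then set ID. Sets whose
intersection with the ranked list falls below `min_set_size` (default
3), above `max_set_size`, or covers the whole list are excluded and
reported, never silently dropped.

### Immune filtering, categories, counting

A GO term is immunological when any keyword of the configured
vocabulary occurs case-insensitively as a substring of its name (the
description can be matched too via `match_fields`). The default
20-keyword vocabulary and the 7-category map (immune response
regulation; inflammatory response; lymphocyte activation &
differentiation; myeloid & dendritic cell activation; antigen
processing & presentation; cytokine production & signalling; leukocyte
migration) are editable stand-ins for a curated list — the exact
published word list is not available — and everything downstream is
parameterised by them. Terms may belong to several categories; retained
terms matching no category land in a residual *other immune* bin so
they are counted rather than lost.

A miRNA's score is the number of tested immune terms with nominal
p < α (default α = 0.05; GSEA FDR selectable via `criterion="fdr"`,
since the platform setting the screen emulates ranked by FDR while the
reported threshold was nominal p < 0.05). The per-category colour score
is −log₂ of the best p among **all tested** terms of the category, not
only the significant ones: when the count is positive the minimum is
attained by a significant term anyway, and defining it over all tested
terms makes the ranking tie-break continuous — under a global null the
rank-1 miRNA is then exchangeable, which the uniformity tests verify.
Ranking is by count descending, then summed colour score, then miRNA
ID.

### ssGSEA and signature correlation

For one sample, genes are ordered by expression descending (gene-ID
tie-break) and given rank values N..1. The signature score is
`Σ_i [P_in(i) − P_out(i)]` with `P_in` the cumulative, normalised sum
of `rank^α` over in-set genes and `P_out` the cumulative fraction of
out-of-set genes; α = 0.25, the canonical exponent. The score depends
on expression only through within-sample ranks, so any per-sample
monotone transform leaves it unchanged — the property the tests check
exactly. Both cumulative sums telescope, so the score is evaluated in
closed form in O(k) per signature per sample. Optional normalisation
rescales the whole matrix by its global range into [0, 1], preserving
between-signature comparability; miRNA/signature Spearman correlation
is computed on unnormalised scores, and a test confirms the two give
identical coefficients (rank invariance). Signatures with fewer than
two genes in the matrix, or covering it entirely, are dropped with a
report.

### ΔΔCt

`ΔCt = mean(Ct_target − Ct_reference)` within each group,
`ΔΔCt = ΔCt_treatment − ΔCt_control`, fold change `2^−ΔΔCt` — group
aggregation by mean before differencing, the standard convention.
Per-sample fold changes relative to the control mean are also exposed.

## The synthetic cohort

One latent immune-activity factor `A_s ~ N(0,1)` per sample couples the
planted miRNAs (`x = γA + ε`) to the members of the immune gene sets
(`y = βA + ε`), `ε ~ N(0, σ²)`; every other feature is independent
noise with variance `σ² + max(γ,β)²`, so marginal variance carries no
information about which features are planted. The expected planted-pair
correlation is `ρ = γβ / sqrt((γ²+σ²)(β²+σ²))` (0.5 at the default
γ = β = σ = 1), and the generators are bit-deterministic under their
seeds. Gaussian noise is the default; a variance-matched Student-t
option exists for heavier tails.

Default study conditions: 200 patients, 4000 genes of which 40 immune
sets × 10 genes load on the factor, 20 miRNAs with one planted
regulator, a 120-term GO universe with a one-third immune fraction
(immune terms draw their gene sets from the immune pool, background
terms from the rest; set sizes uniform on 5–20 so the minimum-size
filter is exercised), and 68 immune signatures of 30 genes with 20%
background contamination. The immune genes are deliberately a ~10%
minority of the transcriptome, as in real expression data; this
proportion is a first-order determinant of the screen's power, because
gene-label permutation draws mostly background genes only when the
coherent compartment is small (see limitations).

The GO-universe generator guarantees that immune term names embed a
vocabulary keyword and that background names contain none (candidates
are checked against the vocabulary, so e.g. "latent cell" can never
leak a "t cell" match), which is what makes downstream keyword-filter
recovery exactly testable.

What the generator does **not** emulate: batch effects, library-size or
count-distribution artefacts, copy-number structure, multiple or
antagonistic immune programmes, negative regulators, or survival
annotations. Passing tests therefore demonstrate that the screen's
machinery is correct and that it recovers a linear, single-factor
immune coupling; they do not establish power against real TCGA noise
structure.

## Properties of the single-latent-factor design worth knowing

* **Inter-gene correlation inflates gene-permutation GSEA.** All immune
  genes share A, so for *any* miRNA their sample correlations carry a
  common random offset (~N(0, 1/2n) at β = σ). Coherent immune sets
  therefore cluster somewhere in every ranked list, and the
  gene-permutation null — valid for independent genes — is
  anti-conservative for them: null miRNAs' significant-immune-term
  counts are inflated well above α × n_terms, and in some replicates
  saturate. This is the textbook behaviour of pre-ranked GSEA under
  inter-gene correlation, reproduced faithfully rather than patched.
  The planted regulator still separates because its coupling (ρ = 0.5)
  dwarfs the chance offset (~0.05), and the p-value magnitudes (colour
  score) break count ties. The α-calibration property is asserted where
  it actually holds: γ = β = 0, i.e. i.i.d. genes.
* **Directionality of a null miRNA is volatile within one cohort.** All
  68 signature scores co-move through A, so a null miRNA's 68 Spearman
  correlations rise and fall together with its chance alignment to A;
  its fraction of positive correlations in a single cohort is close to
  a coin flip. The 0.5 expectation is recovered by averaging across
  null miRNAs and replicate cohorts, which is how the tests and the
  acceptance script measure it. The planted regulator's fraction
  exceeds 0.9 in every replicate.

## Determinism and seeds

A single master seed drives everything: the pipeline derives one seed
per stage through a seed sequence on (master, stage index), GSEA draws
its per-size nulls in sorted-size order, and all written tables use
fixed float formatting (6 significant digits), so two runs with the
same configuration are byte-identical — asserted at file level by the
tests. Written files carry a comment header with the package version
and seed.

## Problem sizes used in the verification suite

Oracle equivalence of the enrichment score uses 1000 random instances
(N ≤ 50, |S| ≤ 10, w ∈ {0,1}) against an independent step-by-step
walk; the permutation null is compared to exhaustive enumeration of all
C(20,3) = 1140 subsets at 10,000 permutations; type-I calibration uses
2000 null set-tests at 200 permutations; planted-regulator recovery
runs 100 replicate cohorts at the default conditions with 200
permutations (the screen's reference setting is 500; 200 keeps the
replicated run short and the recovery result is insensitive to the
difference), and null-screen uniformity 200 replicates with 10 miRNAs.

## Known limitations

* The keyword vocabulary and category map are substring-based and
  English-only; curated GO slims would be more faithful for real data.
* Gene-permutation FDR (pooled NES) inherits the inflation described
  above for correlated gene sets; a Benjamini–Hochberg alternative on
  nominal p can be obtained by post-processing the result tables.
* ssGSEA normalisation is global min–max; per-signature alternatives
  (GSVA, z-score) are out of scope.
* The ΔΔCt utility assumes perfect amplification efficiency and
  aggregates by group means; no efficiency correction is attempted.
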