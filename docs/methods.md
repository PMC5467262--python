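# Methods

## The problem being modeled

Joint-called germline exome cohorts often mix DNA libraries prepared
directly from tissue with libraries amplified by multiple displacement
amplification (MDA) because of limited input material. MDA has two known
failure modes with direct consequences for variant calling: polymerase
slippage at homopolymer tracts, and chimeric rearrangements in which the
displaced strand re-primes on nearby template. In variant calls these
manifest as (i) recurrent 1–6 bp single-base-type indels adjacent to
homopolymer runs, (ii) large insertions whose inserted sequence is a copy
of reference sequence from within a few kilobases, and (iii) highly
variable per-gene depth causing dropout (no-call) genotypes. Because
frameshift indels are counted as loss-of-function (LOF), both indel artifact
classes inflate rare-LOF burden specifically in amplified samples; when
amplification status correlates with a phenotype group, naive burden
association tests become inflated.

`wgaqc` implements the analysis stages needed to detect and quantify this
contamination, driven by a simulator that generates cohorts with known
artifact content so every stage can be scored against truth.

## Cohort simulator

One contig carries `n_genes` non-overlapping single-exon genes of
`gene_length` bp separated by `intergenic` bp spacers. The background
sequence is uniform over A/C/G/T with single-base runs capped at three, and
homopolymer tracts of 4–8 bp are planted on a 40 bp slot grid at
`hp_tract_density` per bp (default 0.012/bp, about one tract per 85 bp —
the natural run density of uniform random sequence). Capping the background
makes the realized tract count binomial around the request, so density is a
controlled dial rather than an emergent property.

**True variation.** SNV and indel site counts are Poisson with per-bp cohort
rates `true_snv_rate` (0.0075) and `true_indel_rate` (0.0015). Site allele
frequencies follow a rare-skewed Beta(0.25, 8) spectrum; genotypes are
Hardy–Weinberg per individual, shared across that individual's replicate
samples. True coding indels are biased toward in-frame lengths
(`inframe_bias` = 0.6 probability of a multiple of 3), reflecting purifying
selection against frameshifts; intergenic true indels and all artifacts are
frame-agnostic. Five percent of true indels are large (15–60 bp) with novel
(not template-copied) inserted sequence, providing the background class for
the chimera search.

**Slippage artifacts.** A fraction `hp_recurrence` (0.04) of tracts is
slippage-prone; each prone tract draws a per-WGA-sample error probability
from a Beta(1.2, ·) with mean `hp_error_rate / hp_recurrence`, the rest
never slip. The marginal rate `hp_error_rate` (0.0035 per tract per
amplified sample) fixes the expected artifact load (~13–18 slippage indels
per amplified sample at default scale). Concentrating the rate on few
tracts makes artifacts recur across amplified samples, so homopolymer+
alleles reach much higher WGA-group allele frequencies than other variant
classes — the recurrence signature the analysis looks for. Each tract's
artifact identity (insertion vs deletion, 1–6 copies of the tract base) is
fixed; carriers are heterozygous and re-drawn independently per sample, so
replicates disagree. The uniform 1–6 length makes the slippage mod-3
fraction exactly 1/3.

**Chimeric artifacts.** Each amplified sample draws Poisson(`chimera_rate`
= 3) large indels; 90% are insertions of a verbatim forward-strand copy of
reference starting at an exponential distance (scale
`chimera_origin_scale` = 1500 bp, capped at 9500 bp) from the insertion
point, so most origins fall within 2 kb and all within 10 kb. Insertion
sites are re-drawn when the copy would be left-shiftable, keeping emitted
alleles normalized without rotating the copied sequence. The remaining 10%
are large deletions.

**Depth and missingness.** Per-sample per-gene depth is Normal(165, 40) for
DNA and Normal(165, 140) for amplified samples, truncated at zero — the
amplified group's dispersion drives dropout. All genotypes in a gene with
depth below `missing_threshold` (10×) are set missing; at defaults an
amplified sample loses ≈ 27 of 200 genes. The capture-efficiency covariate
C20X is computed from the realized depth matrix as the fraction of genes at
≥ 20×, so it is honestly correlated with amplification. Missingness, like
artifacts, is independent per replicate.

**Quality scores.** Each allele carries a simulated site quality score:
true variants ~ Normal(8, 1), artifacts ~ Normal(5.5, 1.5). The overlap is
deliberate: tiered filtering can enrich for truth but cannot separate the
classes cleanly, reproducing the practical sensitivity/precision trade-off.

**Cohort structure.** Defaults are 1800 DNA + 200 WGA samples with 40
DNA:DNA, 8 WGA:DNA and 12 WGA:WGA replicate pairs (≈ the 9004/614 and
435/13/44 proportions of a large amplified pan-cancer cohort, scaled to
desk size) across four phenotype groups. The confounded group (250
individuals) draws `phenotype_confound` = 0.6 of its members from
WGA-only individuals, emulating cancer types whose samples were
predominantly amplified.

Randomness flows from one seed through named substreams
(reference/metadata/truth/slippage/chimera/depth/quality), so each stage is
independently reproducible and the whole cohort is bit-stable per seed.

## Analysis stages

**Variant model.** Multi-allelic records are split into per-ALT alleles,
left-aligned and trimmed to parsimony; dosage is per allele (a 1/2
genotype contributes 1 to each allele's record). Missing genotypes leave
both the allele-count numerator and denominator, so group totals shrink
with dropout; with complete genotypes the fixed 2N accounting is recovered.

**Enrichment screen.** For each indel allele, a 2×2 table of alternate vs
reference counts in WGA vs DNA is tested by the one-sided (upper-tail
hypergeometric) Fisher's exact test toward WGA excess. The threshold is the
exactly computed p of a WGA-only singleton, 2·n_WGA/(2·n_WGA + 2·n_DNA);
the screen calls p ≤ threshold enriched so the boundary singleton counts,
with `strict=True` available for the strict `<` convention (under which a
lone singleton is excluded — for 614/9004 the computed 0.0638 exceeds the
three-decimal truncation 0.063). No multiple-testing correction: this is a
screening rule, not inference.

**Chimera search.** The inserted (or deleted) sequence of each ≥ 15 bp
indel is matched ungapped at every offset within ± 10 kb of the indel
start; best match by identity, ties to the smallest distance; deletions
exclude candidates overlapping the deleted span so the self-match never
counts. Ungapped matching suffices because MDA chimera insertions are
verbatim template copies; `min_identity` (default 0.9, 1.0 in the
acceptance analyses) tolerates point mismatches, and reverse-complement
search is available behind a flag. A gapped aligner would be needed for
real data with indel-containing copies; that equivalence is only asserted
on simulated data.

**Concordance.** Replicate pairs are derived from shared individual IDs.
Calls are matched by (contig, position, alternate), zygosity disregarded;
discordance is one minus Jaccard similarity. Missing genotypes count as
absent — this is what converts amplification dropout into measurable
discordance. A configurable discordance ceiling flags suspect pairs (e.g.
sample swaps) instead of silently dropping them.

**Burden and ANOVA.** Rare-LOF burden sums dosage at frameshift/stop-gained
sites with cohort AF strictly below 0.05, total and by indel category and
gene. The Type II ANOVA regresses burden on C20X (continuous) plus
amplification status, center, aligner version and ancestry (dummy-coded,
first-level reference, no interactions); each factor's sum of squares
compares the full main-effects model to the model omitting that factor.
Percent variance explained is factor SS over (sum of factor SS + residual
SS), so shares are non-negative and sum to one. Perfectly aliased factor
pairs are detected by rank comparison and raised with both names. The
response is raw counts; transformation is left to the caller. Bootstrap
CIs for means use the basic interval (2m − q_hi, 2m − q_lo) from 1000
resamples.

**Association.** Per phenotype group and gene, logistic regression of the
one-vs-rest indicator on gene burden with ancestry and age covariates,
restricted to one sex for sex-specific groups; genes require ≥ 2 carriers.
The burden p-value is the likelihood-ratio test — with rare burdens the
Wald statistic is badly calibrated under the null, while the LRT is
accurate once carrier counts are moderate. On complete separation (common
for rare burdens in small groups) the fit falls back to a ridge-penalized
(λ = 10⁻³) IRLS logistic with Wald p from the penalized information
matrix, and the gene is flagged. Bonferroni control uses
α/(groups × genes) with the realized tested-gene count by default and an
option to fix the denominator to a rounded convention. Samples with
missing covariates are dropped with a logged count.

## Numerical and design choices

- Coordinates are 0-based half-open internally; 1-based only at the VCF
  boundary.
- The homopolymer+ rule requires a run of ≥ 4 copies of the indel's base
  starting within ± 1 bp of the indel start, searched in the reference
  sequence only (not the alternate haplotype); large (≥ 15 bp) takes
  precedence, making the categories mutually exclusive.
- Indels straddling exon boundaries are classified noncoding rather than
  partially evaluated; consequence calling is coding-strand only, and the
  simulator emits +-strand genes.
- Site-level collisions between injected alleles are resolved by capping
  per-sample dosage at 2, zeroing artifact dosage before true dosage;
  alleles left carrier-free are dropped from both the VCF and the ledger.
- The VQSR-style filter is a quantile rule: keep alleles with quality at
  or above the (1 − stringency) quantile of the true-variant calibration
  scores. Only the property the analysis needs — nested truth-sensitivity
  tiers — is preserved; no mixture model is fitted.

## What the simulator does not emulate

No read-level error model (no FASTQ/BAM), no mapping or alignment error,
no multi-exon genes, splice-site LOF, strand effects or transcript
isoforms, no population structure beyond a categorical ancestry label, no
somatic variation, and artifact magnitudes are desk-scale rather than
matched to any real cohort. Passing tests therefore demonstrate that the
statistical machinery recovers the modeled structure — not that real-data
effect sizes will match.

## Problem sizes used in the checks

The default study cohort is ~2000 samples (200 amplified) × 200 genes
(~340 kb contig), where the full pipeline runs in about a minute on one
core. Null calibration uses 200 replicate artifact-free cohorts of 150
samples × 40 genes for family-wise error, and a 500-sample × 200-gene
cohort with a common-variant spectrum (Beta(10, 300)) for permutation
uniformity — the common spectrum puts tested genes in the asymptotic
regime (median ≈ 50 carriers) where the LRT null distribution is smooth;
with the default rare spectrum the discrete p-values are conservative,
which is a limitation of rare-burden score tests generally, not of the
calibration.
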