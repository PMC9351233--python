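# Methods

## Scope and data model

The pipeline operates post-alignment. Its inputs are per-sample,
per-strand CpG methylation counts (Bismark-coverage-style: chromosome,
1-based position, percent methylation, methylated count, unmethylated
count), strand-resolved base pileups at cytosine positions, a genome
FASTA, gene/exon/CDS (+ optional TE and lncRNA) annotation, and a
gene→GO mapping. Read trimming, bisulfite alignment, and deduplication
are out of scope; the synthetic generator therefore emulates counts,
not reads.

Internally all intervals are 0-based half-open (BED convention); GFF3
I/O converts from/to 1-based closed coordinates. A destranded CpG locus
is addressed by the 1-based position of its plus-strand C and occupies
the two bases [p−1, p+1).

## Processing order

destrand → per-sample coverage filter → cross-sample normalization →
unite → (DML test on the united background, SNP exclusion at the
candidate stage) and (SNP-excluded matrix for global
characterization).

* **Destranding** sums the plus-strand record at p with the
  minus-strand record at p+1; orphan minus-strand records are reported
  at their own CpG start.
* **Filtering** voids, per sample, loci with coverage < 5 and loci
  above that sample's 99.9th coverage percentile (PCR-duplicate
  guard; linear interpolation between order statistics).
* **Normalization** rescales both counts of each sample by
  (median of sample median coverages) / (sample median coverage),
  rounding half away from zero and flooring covered cells at total
  coverage 1. This equalizes sample medians up to rounding; it exists
  because libraries never sequence to identical depth.
* **Uniting** keeps loci covered ≥ 5× in *every* sample. This united
  set is the CpG background for testing and the gene universe for
  enrichment.
* **SNP exclusion** removes a destranded locus when either of its
  strand positions is in the C→T exclusion set. Global
  characterization (class shares, correlations, PCA) uses the excluded
  matrix; the treatment test runs on the full united background and
  applies the exclusion to its candidates, which is where the
  candidate → SNP-removed → retained accounting lives.

## SNP screen

Only the opposite strand is informative: the alternative-allele
fraction is f = A/(A+G) on the strand opposite the reference C, and
this-strand T is never treated as variant evidence. Calls need
informative coverage A+G ≥ 5; f ≥ 0.85 is homozygous C→T, 0.1 ≤ f <
0.85 heterozygous (boundaries inclusive at the lower edge). These
thresholds mirror documented defaults of bisulfite SNP callers; the
full Bayesian genotyper is intentionally not reproduced because the
downstream contract is only the exclusion set. Screening runs in
merged mode (counts summed across samples: deep, but private
heterozygotes are diluted below 0.1) and per-sample mode (catches
private variants at the cost of per-sample coverage); the exclusion
set is their union — the most conservative combination. Both strand
positions of a CpG are screened and either position excludes the
destranded locus.

At the default 0.1% uniform error rate, a single miscall at
informative coverage 10 lands exactly on the het boundary, so the
per-sample screen produces rare false positives (≈1 per 10⁴
sample-sites). This is accepted: over-exclusion is conservative for
the methylation questions the screen protects.

## Treatment test

Full model logit(p) = β₀ + β₁·treatment + β₂·stage, reduced model
drops β₁. Fits are Newton/IRLS with step-halving (≤ 50 iterations,
log-likelihood tolerance 1e-8, steps clipped and a 1e-9 ridge guard
against separation-singular Hessians), vectorized across loci; fits
agree with statsmodels GLM to ~1e-13 in the test suite's cross-check.
The maturation stage enters as a single ordinal term (0 =
indeterminate … 3 = spawn-ready): eight samples cannot support a dummy
column per stage plus treatment; a categorical encoding is available
behind a flag. Non-converged loci are flagged and reported with p = 1.

G = 2(ℓ_full − ℓ_reduced) is referred to χ²(1) after dividing by the
full-model Pearson dispersion φ = Σr²/(n−k) when φ > 1 (never
deflating). **Known limitation:** with n = 8 samples φ has ~5 residual
degrees of freedom, and the noise in 1/φ̂ leaves the corrected test
anti-conservative — on null beta-binomial simulations (ρ = 0.05,
coverage 30, 4+4) the empirical p < 0.05 rate is ≈ 0.09–0.12 rather
than 0.05 (uncorrected: ≈ 0.21; with the true φ: ≈ 0.06). An F(1, n−k)
reference would calibrate, but the chi-squared reference is the
method's specified form and is kept. In practice the DML definition is
dominated by the 50-point effect-size threshold, so the practical
false-discovery impact is small (empirical FDR ≈ 0 in the recovery
suite).

The per-locus effect size is the pooled percent difference: counts are
summed within each treatment group before taking proportions
(coverage-weighted), matching the count-level uniting; the unweighted
alternative exists behind a flag. DML: q < 0.01 (strict) and |diff| ≥
50 (inclusive) and no SNP overlap. Hypermethylated means higher
percent methylation under low pH.

## SLIM q-values

π₀ is estimated from the empirical p-value CDF: slopes of ordinary
least-squares fits over sliding λ-windows (width 0.2 of the [0,1]
range, 100 bins) decrease toward π₀ as the window leaves the
signal-rich region; the first slope whose change between consecutive
windows falls below 0.01 is taken, with the minimum slope as fallback,
clipped into (0, 1]. q-values are π₀ × BH-adjusted p-values — with π₀
= 1 they reduce exactly to Benjamini–Hochberg. Fewer than 100 p-values
triggers the π₀ = 1 fallback with a warning.

## Feature characterization and enrichment

A CpG belongs to a feature class if it overlaps it by ≥ 1 base;
overlap tables are *not* mutually exclusive (a locus can be genic and
in a TE), so their percentages can sum past 100. Contingency tests
need a partition, so a precedence order CDS > exon_UTR > intron >
flank_up > flank_down > intergenic assigns each locus exactly one
label (genic-first, reproducible); TE and lncRNA appear only in the
overlap table. The 2×k chi-squared test uses no continuity correction
(matching R's behavior on tables larger than 2×2, applied uniformly),
drops zero-margin categories with a note, and warns when expected
counts fall below 5. Flanks are 1000 bp strand-aware windows with gene
bases subtracted; upstream flanks stand in for putative promoters.
Flanks of adjacent genes may overlap and are merged within their
class.

Enrichment is gene-level: a gene is "of interest" if it contains ≥ 1
retained DML (SNP-overlapping DML never count), the universe is genes
containing ≥ 5×-united CpGs, and each GO term gets a one-sided
Fisher's exact p (hypergeometric upper tail). No multiple-testing
correction is applied — deliberately matching topGO defaults; treat
the p < 0.01 flags as screening, not inference.

## Synthetic world

The generator emits a genome whose background is scrubbed of CG so
every CpG is planted and truth-tracked (default 5 × 60 kb chromosomes,
20 CpG/kb), nested gene/exon/CDS annotation with TEs and lncRNAs,
per-sample counts, pileups and a gene→GO map. Counts: coverage ~
negative binomial (mean 30, size 8) scaled by lognormal per-sample
depth factors (sd 0.2); methylation ~ beta-binomial via a site-level
Beta draw (intra-site correlation ρ = 0.05) around logit(base) +
Δ·treatment + 0.3·(stage − mean); baseline mixture 80% low / 10% mid /
10% high methylation, as in molluscan genomes. Planted DML (default 2%
of loci, ±60 points) choose their baseline so the target difference is
achievable in probability space; planted SNPs (2% of cytosines, 30%
het) zero (hom) or halve (het) apparent methylation on the plus strand
only by default. Sequencing errors are uniform per-read miscalls
(default 0.1%) applied to pileups. Operations called independently
agree on truth because every stage draws from a fixed-key child stream
of the seed; identical configs give byte-identical outputs.

What a green test does *not* establish: the generator has no mapping
bias, no non-CpG methylation, no correlated neighboring loci, no
conversion-efficiency drift, and genotypes are population-wide rather
than per-individual — so SNP-confounded *differential* signal (the
worst real-world case) only arises through the planted DML∩SNP
overlap, not through genotype-by-treatment imbalance.

## Numerical conventions

Rounding half away from zero in normalization; percentile via linear
interpolation; class boundaries ≥ 50% high and ≤ 10% low, exactly as
stated; q-threshold strict, difference threshold inclusive; χ² df = 1
throughout the treatment test; PCA by SVD of the locus-centered
percent matrix with NaN cells mean-imputed per locus; Pearson
correlations on per-sample percent columns with constant columns
reported as missing.
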