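# dmlpipe

SNP-aware differential-methylation analysis for whole-genome bisulfite
sequencing (WGBS), built around the design of a two-treatment oyster
gonad methylome experiment: 4 low-pH vs 4 ambient-pH samples with an
ordinal gonad-maturation covariate. The pipeline starts from
strand-resolved CpG counts (Bismark-coverage-style files) and ends at
differentially methylated loci (DML), their genome-feature context, and
GO-term enrichment — with every statistical step testable against a
synthetic genome with planted truth.

## Why SNP-aware?

Bisulfite treatment converts unmethylated C to T, so a C→T SNP is read
as a permanently unmethylated cytosine and can masquerade as a
treatment-associated methylation difference. The opposite strand
disambiguates: a T paired with an **adenine** is a C→T SNP, while a T
paired with a **guanine** is a converted unmethylated cytosine. The
`snps` module screens strand-resolved pileups (merged across samples
and per sample, taking the union) and the resulting C→T exclusion set
removes confounded loci from the analysis.

## The model

At each united CpG locus with methylated/unmethylated counts
(y<sub>i</sub>, n<sub>i</sub> − y<sub>i</sub>) per sample *i*, a
binomial logistic regression is fitted by maximum likelihood:

    logit(p_i) = β₀ + β₁·treatment_i + β₂·stage_i

The treatment term is tested with the likelihood-ratio statistic
G = 2(ℓ_full − ℓ_reduced). Extra-binomial variance is handled with a
McCullagh–Nelder-style dispersion correction: the Pearson dispersion
φ = Σr²/(n − k) from the full model scales the statistic (G/φ, applied
only when φ > 1) before the χ²(1) tail is taken. False discovery is
controlled with SLIM q-values — a sliding-linear-model estimate of the
true-null proportion π₀ multiplying Benjamini–Hochberg adjusted
p-values. A locus is a DML when q < 0.01, the pooled percent difference
is ≥ 50 points in magnitude, and it does not overlap a C→T SNP.

Feature context is computed with bedtools-style interval algebra
(intron = gene ∖ exon, exon-UTR = exon ∖ CDS, 1 kb strand-aware flanks
as putative promoters/downstream regions, intergenic = the remainder),
and gene-level GO enrichment uses one-sided Fisher's exact tests
against the universe of genes containing ≥5× CpGs, uncorrected.

## Worked example

The `all` subcommand simulates a 5-chromosome, 6,000-CpG toy world
(127 planted DML, 114 planted C→T SNPs at seed 7) and runs every stage:

```bash
dmlpipe all --seed 7 --outdir demo/
```

Key lines of the printed report:

```json
"snps":        {"merged_calls": 114, "per_sample_calls": 122,
                "union_exclusion_set": 122},
"methylation": {"destranded_loci": 6000, "united_loci": 5894,
                "snp_excluded": 120, "analyzed_loci": 5774},
"dml":         {"candidates": 106, "snp_removed": 0, "retained": 106,
                "hyper": 53, "hypo": 53}
```

Reading: all 6,000 CpGs survive destranding, 5,894 are covered ≥5× in
every sample after coverage filtering/normalization, and 120 loci are
removed because one of their strand positions is in the C→T exclusion
set (the union screen slightly over-excludes at the default 0.1%
sequencing error rate — a deliberate, conservative choice). The
treatment test then calls 106 of the 127 planted DML (the misses are
planted effects whose sampled pooled difference fell under the 50-point
cut-off), split evenly into hyper- and hypomethylated, with zero false
positives. Per-stage outputs (BED/VCF/bedgraph/TSV, `report.json`)
land in `demo/`.

Each stage is also exposed as a library function (`simulate_dataset`,
`build_feature_tracks`, `screen_genome`, `destrand` → `filter_coverage`
→ `normalize_coverage` → `unite` → `apply_snp_exclusion`, `fit_matrix`,
`call_dml`, `overlap_features`, `go_enrichment`) — see
`docs/methods.md` for the statistical details and caveats.

## Acceptance script

`scripts/acceptance.py` re-runs the complete seeded synthetic pipeline
from scratch and writes its results file:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
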