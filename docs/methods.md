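# Methods

`xciescape` calls the X-chromosome-inactivation (XCI) status of genes —
escaping, subject to, or variably escaping inactivation — per gene and per
sample, from four kinds of evidence, and then asks whether variable escape
has a genetic component.  This note documents the models, the parameters
that matter, the synthetic benchmark the package ships with, and the design
choices that were genuinely open.

## Allelic-expression calling

In a female sample whose X-inactivation is skewed (the same parental X is
inactive in essentially all cells), RNA-seq reads at a heterozygous exonic
SNP can be attributed to the inactive (Xi) or active (Xa) X.  A gene is
said to escape XCI when its Xi expression is at least 10% of the Xa level.
With read counts Xi and Xa, the caller forms the binomial proportion
p̂ = Xi/(Xi+Xa) and the Wald interval

    p̂ ± z · sqrt( p̂(1−p̂) / (Xi+Xa) ),   z = 1.96 (95%),

clipping to [0, 1].  The 10% Xi/Xa *ratio* threshold converts to the
proportion p\* = 0.1/1.1 = 1/11; the gene is called escaping when the whole
interval lies above p\*, subject when it lies below, and uninformative when
the interval straddles the threshold — a call is made only when the
interval resolves it.  At p̂ ∈ {0, 1} the Wald interval has zero width and
the call follows the point estimate; no continuity correction is applied.

Supporting steps:

* **Xi orientation** — alleles arrive as A/B counts, not Xi/Xa.  The
  haplotype silenced (minor allele) at the majority of genes with a
  literature consensus ("meta-status") of *subject* is labelled Xi; a tie
  leaves the sample unoriented.
* **Skew filter** — a sample is dropped when strictly more than 25% of its
  informative meta-subject genes are called escaping: in an unskewed
  sample both alleles are expressed everywhere, so known-silenced genes
  spuriously look biallelic.
* **Variable escape** — a gene with at least two samples escaping *and*
  two subject is variably escaping; otherwise it takes the majority
  constitutive status.

## Promoter DNA methylation

At genes subject to XCI the promoter CpG island is methylated on the Xi
and unmethylated on the Xa, so the female mean sits near 40%; at escaping
genes both alleles are unmethylated.  The threshold table (on the female
promoter mean, with the male mean as an Xa control):

| band | call |
|---|---|
| male ≥ 0.15 | uninformative (Xa already methylated) |
| female < 0.10 | escape |
| 0.15 < female < 0.60 | subject |
| female > 0.60 | hypermethylated |
| gaps (0.10–0.15, exactly 0.60) | intermediate |

The threshold gaps map to an explicit *intermediate* status rather than
snapping to the nearest band — the buffer is deliberate in the source
thresholds.  The across-sample rule: a transcript is variably escaping
when escape and subject each cover ≥ 1/3 of *informative* samples, and
constitutive at ≥ 66%; a gene whose transcripts reach opposite
constitutive statuses is flagged variable-between-TSSs.

**Per-read resolution.**  Each bisulfite read carries its own methylation
fraction (methylated / total CG dinucleotides on the read, as sequenced —
not the island CpG count).  Genes are binned by mean island DNAme in
deciles (floor rule, top bin closed: [0.9, 1] → bin 9) and reads
summarised into three deliberately non-exhaustive bands (< 25%, 33–66%,
\> 75%).

**Allele resolution.**  Reads overlapping a promoter-proximal heterozygous
SNP are split by tagged base into a C/T group and a G/A group.  C↔T and
G↔A polymorphisms are excluded outright: bisulfite conversion turns
unmethylated C to T (G to A on the opposite strand), so those alleles are
indistinguishable from conversion.  With ≥ 5 reads per group, both group
means < 0.25 → escape, one < 0.25 and one > 0.75 → subject, both > 0.75 →
hypermethylated, else uninformative.  For binned display the gene bin uses
the mean of the two per-allele means (robust to lopsided read depth), and
equal allele means tie-break to the C/T group as "low allele" — display
only, never a call.

**Array-style filters.**  For 450k-like probe matrices, probes with male
mean > 15% are removed, and female samples whose across-probe mean falls
more than two standard deviations below the female average are removed as
presumed mislabelled males or Xi loss.

## Histone-mark quantification and Xi:Xa fold change

Six histone marks plus DNAme are quantified as length-weighted means over
the region kind that suits each mark: a strand-aware 500 bp window
upstream of the TSS for H3K4me3, H3K9me3, H3K27ac, H3K27me3 and DNAme;
exon bodies for H3K36me3; annotated enhancers for H3K4me1.  The strand
awareness of the promoter window is this package's choice (TSS-proximal
marks are strand-asymmetric).  Samples are depth-normalised by scaling
every sample to the maximum genome-wide total.  Uncovered positions are
missing, never zero, and a region under 50% covered returns missing.

The Xi:Xa fold change treats the paired male value as the Xa contribution:
(female − male)/male.  Its log2 is defined only for female > male; a
negative difference is stored as missing-with-sign rather than shifted by
a pseudocount (none is justified).  Group comparisons are Welch t-tests
("t-tests" alone would not pin the variance assumption; unequal variance
is the safer default) with Benjamini–Hochberg correction within one family
per mark × comparison at α = 0.01; the small expression-based
variable-gene analysis (2–3 samples per status) uses uncorrected 0.05.

## The ensemble predictor

Per female sample, each transcript gets 14 features: the seven marks in
that sample and the mean of the same marks over "similar" male samples,
where similarity is k-means (k = 3) on standardised autosomal mark levels.
Missing features are imputed with the sample-wide median and flagged.

Training labels are meta-status escape/subject genes.  A global holdout of
3 escape + 3 subject genes is removed first; each of 20 models then draws,
without replacement and fresh per model, floor(75% of the remaining escape
genes) escape genes and twice that count of subject genes, and fits a
random forest of 1500 trees.  The features-per-split value is chosen from
5 evenly spaced values in [1, 14] by out-of-bag AUC on the pooled training
genes, once per ensemble and reused by its 20 models (a per-model
cross-validated search would multiply the tree budget fivefold for no
observable gain at these feature counts); the search forests are capped at
300 trees, where the OOB ranking is already stable.  Per-model accuracy is
recorded on the labelled genes that model did not draw.

Vote rules per transcript per sample: 15+ of 20 models on a side is a firm
escape/subject call; 12–14 is a tentative *leaning* call; 10–11 splits are
inconsistent.  Across samples, firm fractions are tested first —
constitutive at ≥ 66% of samples with a vote result (inconsistent samples
stay in the denominator, matching the rule's worked arithmetic), variable
at ≥ 1/3 each — and only then are leaning votes folded into their side and
the 66% rule retried, yielding a leaning overall status.  A
variable-threshold sweep re-runs only the variable rule at lower
fractions; counts are monotone non-increasing in the threshold by set
containment.

Feature importance is summarised as the mean per-model rank of each
feature's impurity importance (14 = most important; ties break by feature
order).  A mean ± 2 SD simple threshold classifier per mark is kept as the
baseline; when the two class bands overlap, the midpoint of the class
means becomes a single threshold, with the exact midpoint assigned to the
lower-mean class.

## Genotype association and DNAme-QTLs

Variable-escape genes are tested against genotype with a 2×2 Pearson
chi-square (no continuity correction) over the two homozygote classes —
heterozygotes are excluded because the test targets a cis effect and a
heterozygote's Xi allele is unknown.  Classes with fewer than 5 samples
skip the test (no exact-test fallback).  BH correction runs over all
gene × locus pairs in the run as one family; an X-only family is available
as a second mode.  For large cohorts a relaxed variable definition (> 100
samples with each status, strict) replaces the 1/3 fractions.

Attributable risk is reported as the population attributable risk of the
escape outcome: AR = (P(escape) − P(escape | non-carrier)) / P(escape),
computed over the two homozygote classes with "carrier" the genotype
showing the higher escape rate, clipped to [0, 1].  This estimator is this
package's explicit definition and is labelled in the output headers.

DNAme-QTLs are ordinary least-squares fits of island methylation on
genotype dosage (0/1/2), run separately per sex — an Xi-mediated effect
should appear only in females — with BH within sex at α = 0.01 (the global
significance convention; no test-specific threshold is defined elsewhere).
A locus *spans a status change* when its two homozygote methylation
medians fall one in the escape band [0, 0.10) and one inside the subject
band (0.15, 0.60).

## The synthetic benchmark

The generator plants known structure so every stage is testable offline:

* **Genes** (default 200): 12% escaping, 80% subject, 8% variable —
  roughly the published population proportions.  Variable genes redraw
  their state per sample (base escape probability 0.5), or follow a
  planted locus's per-genotype escape probabilities (default one locus
  with probabilities 0.7/0.5/0.3 for dosage 0/1/2 at allele frequency
  0.5).
* **Samples** (default 8 female + 4 male over three tissues, half the
  females skewed): a deliberately small cohort of the size the healthy
  comparison dataset offered; `skew_fraction` is a proportion, so exactly
  that many females are skewed.
* **Allelic counts**: totals Poisson(depth), Xi reads binomial with Xi/Xa
  ratio uniform in (0.15, 1.0) at escaping and (0, 0.05) at silenced
  genes.  Unskewed samples mix the two Xi choices 50:50 per cell, so their
  allelic imbalance vanishes — the skew filter needs something to reject.
* **Bisulfite reads**: DNA reads sample both chromosomes equally
  regardless of expression skew.  Per-CpG offsets ~ Normal(0, 0.2),
  clipped, shared by all reads of an island in a sample, create
  intermediate methylation through CpG-to-CpG inconsistency rather than
  cell mixtures — per-read offsets would make whole reads intermediate,
  which is not what partially methylated islands look like.  Some SNPs are
  drawn as C/T- or G/A-type pairs specifically to exercise the exclusion
  rule.
* **Marks**: female signal = Xa baseline + state-dependent Xi component +
  Gaussian noise, male = baseline + noise.  Heterochromatic marks carry
  the larger Xi component at silenced genes; DNAme (on the proportion
  scale, female mean = Xa/Xi average) is deliberately the most separating
  feature, so the predictor's importance ranking has a known answer.
* **Genotypes**: Hardy–Weinberg draws; null loci independent of the truth
  table.

All randomness flows through explicitly passed `numpy` generators seeded
from one integer, with a fixed stream per stage: regeneration under one
seed is bit-identical, and so is the whole pipeline (verified by hashing
every artifact of two runs).

What the generator does **not** emulate: alignment artifacts and reference
bias, copy-number changes, linkage disequilibrium, population structure,
tissue-specific baselines in the marks, and real biological overlap
between the escape and subject feature distributions.  Passing tests
therefore demonstrate that the calling machinery is correct and calibrated
under its stated model — not that the accuracies reached here transfer to
real cohorts, where class separation is far smaller.

## Numerical and scale choices

* Coordinates are 0-based half-open throughout; GTF input is converted on
  read; BED12 is the native on-disk dialect.
* Multi-array genotype disagreement yields missing, not a majority vote —
  "consensus" read strictly.
* Metagene profiles use 100 gene-body bins and 50 fixed-width bins per
  50 kb flank, strand-flipped so 5′→3′ reads left to right.
* Test and acceptance problem sizes: the predictor's recovery checks use
  ~200 labelled genes and full 20 × 1500-tree ensembles; its degradation
  sweep uses 10 × 150-tree ensembles, since the monotone loss of signal is
  a property of the features, not the ensemble size.  Association
  calibration uses 20 replicate cohorts of 400 samples × 200 loci; power
  uses 0.7-vs-0.3 planted escape rates at n = 400; QTL recovery uses a
  planted slope of 0.15 with noise SD 0.05 at 300 samples per sex.

## Known limitations

* The expression route requires skewed samples and an orientable Xi; in
  small cohorts most genes end uninformative, which is faithful to the
  method but easy to misread as failure.
* The Wald interval is anti-conservative at extreme proportions and small
  depth; calls at boundary counts follow the point estimate by
  construction.
* The predictor's accuracy on the synthetic benchmark is near-perfect by
  design and should be read as a correctness check, not a performance
  claim.
* `pyBigWig` input is not wired in: signal arrives as bedGraph or
  precomputed region-mean tables; binary bigWig writing is out of scope.
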