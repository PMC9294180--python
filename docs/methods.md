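# Methods

## Metatranscript model

All genomic intervals are 0-based half-open internally (BED convention); GTF
records (1-based closed) are converted on read. One representative transcript
per gene is chosen by maximal *spliced* length (ties broken by smallest
transcript id); region lengths and windows are likewise spliced, not genomic
spans, since the metatranscript concatenates exonic sequence. Genes whose
representative transcript has a 5'UTR < 50 nt, a 3'UTR < 100 nt or a CDS
< 100 nt are removed (strict inequalities, so boundary lengths pass).

The spliced 5'UTR / CDS / 3'UTR are split into 10 / 20 / 20 windows. When a
region length is not divisible by its window count, the remainder bases are
distributed one per window starting from the 5' end, making the windowing
deterministic; summed per-window base counts recover the three region lengths
exactly. Transcripts with incomplete CDS annotations (GTF `cds_*_NF` tags)
are kept but flagged, and the codon-multiple invariant is not enforced for
them.

## Peaks

narrowPeak column 7 (signalValue) is read as IP/input fold enrichment and
column 9 (qValue) as -log10 FDR; plain BED input is treated as pre-filtered
(fold = +inf, FDR = 0). Confident peaks have fold > 2 and FDR < 0.05, both
strict. Replicate reproducibility uses the `bedtools intersect -f 0.5`
convention: a peak survives when the union of the other replicate's peaks
covers at least half of its own length, applied symmetrically; survivors are
merged (overlapping or book-ended intervals coalesce, matching the merging
tool's default). With more than two replicates the sets are reduced by
sequential pairwise intersection in input order, with a warning — how peaks
are matched across more than two samples is a genuinely open choice.

Peak annotation priority is fiveUTRs > Promoters > threeUTRs > Exons >
Introns, any-overlap, with Intergenic as fallback and gene ties broken by
smallest gene id. The promoter is TSS +/- 3,000 bp (a conventional default;
no established width exists for this analysis). The stop-codon flank is
measured in spliced nucleotides, up to 100 on each side of the CDS/3'UTR
junction, crossing it.

Region-average signal (e.g. conservation scores) is the arithmetic per-base
mean over the covered bases of the query intervals; bases absent from the
track are excluded from the denominator, and zero covered bases yields NaN
rather than 0.

## Window matrix and classification

Each matrix cell is the fraction of the window's spliced bases covered by at
least one merged peak — a continuous density in [0, 1], not a binary overlap
flag, so peak extent contributes to the profile. K-means uses k = 5,
Euclidean distance, 10 initialisations, 300 max iterations, tolerance 1e-4,
and a fixed seed (default 42); given the seed the classification is
deterministic and invariant to gene order. A diagnostic reports within-
cluster variance for k in 2..8, but classification always uses k = 5.

Centroid labeling: the NMG centroid is the one with the smallest overall
mean, required to be below half the second-smallest mean (otherwise a
labeling error is raised — the clustering is degenerate and a different seed
or the k diagnostic should be inspected). The remaining four centroids take
the label of the window band holding their largest mean: windows 1-10
(5'UTR) -> 5MG, 11-27 (CDS body) -> CMG, 28-32 (stop flank) -> SMG, 33-50
(3'UTR body) -> 3MG. The 5-window stop flank approximates +/-100 nt around
the stop codon in window space. The mapping must be bijective. If more than
99 % of genes have empty rows, k-means would be degenerate and all genes are
reported as NMG directly.

Each stage is clustered independently (the per-stage panels of a two-stage
comparison), and transitions are computed over the intersection of the two
stages' filtered gene universes.

## Quantification

TPM follows counts x 1e6 / (length x sum_j counts_j/length_j); columns sum to
1e6 by construction. The m6A level is mean IP TPM over mean input TPM per
gene; genes with zero input are flagged `input_too_low` and excluded from
correlations rather than given pseudocounted ratios, keeping the level scale
interpretable.

TMM factors are *effective* relative sizes: the trimmed-mean-of-M-values
composition factor (M and A on count fractions, 30 % M-trim and 5 % A-trim by
rank, genes zero in either sample removed) multiplied by the library-size
ratio, rescaled to geometric mean 1. Defining the factor this way makes two
identities exact: identical columns give unit factors, and scaling one
sample's counts by c moves only that sample's factor, by exactly c (up to the
geometric-mean rescale). The trim weights are binomial inverse-variance
weights in fraction form, (1-p)/p + (1-p_ref)/p_ref — proportional to the
count-based form at equal library sizes and exactly scale-invariant, which
the count-based form is not. Factors agree with edgeR's
calcNormFactors x library size to ~0.3 % on typical tables (cross-checked in
the test suite). If fewer than 10 genes survive trimming, the untrimmed mean
is used with a warning.

Differential expression/methylation between two conditions uses the exact
two-Poisson conditional binomial test: p from the binomial law of count A
given A+B with success probability scale_A/(scale_A+scale_B), two-sided by
doubling the smaller tail (capped at 1), and log2FC with a 0.5 pseudocount.
Negative-binomial dispersion estimation is deliberately out of scope — the
analysis consumes thresholded gene sets (p < 0.05 and |log2FC| > 1, both
strict), and the exact test is well calibrated for them (empirical size
~0.04 at nominal 0.05 in the calibration test; the discrete test is
conservative). Both counts zero gives (log2FC 0, p 1).

## Statistics

- tau = sum_i (1 - x_i/x_max) / (n-1) on linear expression values (a
  log2(x+1) option exists but is off by default); all-zero genes are
  undefined (NaN). 0 = broadly expressed, 1 = single-tissue.
- The two-proportion z-test uses the pooled proportion, making z^2 equal the
  2x2 Pearson chi-square exactly; degenerate pooled proportions (0 or 1) give
  statistic 0, p 1. No continuity corrections anywhere.
- Fisher's exact test (two-sided, sum of hypergeometric probabilities not
  exceeding the observed table's) is computed in exact integer arithmetic:
  all tables with fixed marginals share the denominator C(n, r1), so the
  tie comparison `P(table) <= P(observed)` is an integer comparison and the
  result is exact to final-rounding precision.
- Odds ratios use (ad)/(bc) with the Haldane-Anscombe +0.5 correction when b
  or c is zero, flagged.
- Gene-set enrichment builds the (in-group/out-group) x (in-set/out-set)
  table per set over a user universe (defaulting, in pipeline use, to the
  filtered gene set — the same universe the clustering sees), applies the
  two-sided Fisher test, and adjusts across the query's sets with
  Benjamini-Hochberg; significance means adjusted p < 0.05.

## Synthetic data generator

The generator emulates the *structure* the pipeline consumes, not read-level
reality. Per gene: single-exon models by default (a multi-exon mode with 2-4
exons exercises spliced mapping), 5'UTR ~ U(150, 400) nt, CDS ~ U(300, 1500)
rounded to codons, 3'UTR ~ U(250, 800) nt, random strand, genes laid out with
7 kb gaps so promoters stay clear of neighbours. 5 % of genes violate one
length filter to exercise filtering.

Stage-1 classes are drawn from equal class probabilities; stage-2 classes
follow a planted row-stochastic transition matrix (default: diagonal 0.6,
off-diagonal 0.1, except the 5MG row, where 0.5 of the mass moves to NMG and
0.2 stays — the "half of 5'UTR-methylated genes lose their m6A during
development" scenario). Methylation of a region is planted as a target
coverage fraction U(0.5, 0.9): peaks of 100-200 nt are laid down uniformly
inside the class's region (5MG: 5'UTR; CMG: CDS minus its last 100 nt; 3MG:
3'UTR minus its first 100 nt; SMG: one peak centred within +/-60 nt of the
stop codon) until the target coverage is reached. Replicates jitter peak
boundaries with sd 10 nt (clamped to a fifth of the peak length, so
reciprocal overlap stays >= 50 %); 5 % of genes carry a decoy peak that fails
both the fold and FDR filters. Counts are negative binomial
(dispersion 0.02) around lognormal expression means, ~10 counts per
expression-unit-kb; IP means are multiplied by a per-gene enrichment (4-fold
centre, 0.6 log2 sd) for methylated genes. The planted negative correlation
between log2 m6A level and log2 expression (target -0.5) couples the latent
enrichment to expression through a bivariate normal whose correlation is
inflated by an analytic estimate of count-noise attenuation; the realized
correlation is then verified empirically by `truth_report`, not assumed. A
12-tissue panel plants tissue-specific expression (one home tissue, 50-fold
contrast) in 50 % of NMGs versus 15 % of other genes, reproducing the
qualitative NMG-tau contrast.

What passing tests on these data do *not* show: robustness to alignment
artefacts, antibody biases, motif-dependent peak placement (RRACH), isoform
mixtures, or dispersion heterogeneity across genes — none of which the
generator models.

## Problem sizes and numerical choices

The standard simulated studies use 2,000 genes for topology recovery, 5,000
for transition recovery, and 1,000 for correlation recovery — sizes at which
multinomial noise in a 5x5 transition ratio is ~0.02 per cell, comfortably
inside the +/-0.05 reporting tolerance, while a full pipeline run stays in
seconds. K-means tie-breaking, remainder-window placement and gene ordering
are all deterministic, so `run-all` output is byte-identical across runs for
a fixed seed.

## Known limitations

- Clustering each stage independently means group labels are comparable only
  through the centroid-shape naming, not through a joint embedding.
- The reproducibility rule assumes exactly two replicates; >2 are reduced
  pairwise in input order.
- Per-region m6A levels and peak annotation use the single representative
  transcript; multi-isoform metagenes are out of scope.
- The exact rate-ratio test ignores biological overdispersion between
  replicates; it is a test of rates, not of population means.
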