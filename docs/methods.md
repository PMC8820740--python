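# Methods

`ca1kit` reimplements, as a tested pipeline, the analysis logic used to map
the compartment-specific transcriptome of hippocampal CA1 pyramidal
neurons: which mRNAs (and which 3'UTR/splice isoforms of them) are on
dendritic ribosomes, which of those are bound by FMRP in dendrites, and how
smFISH spot positions relate to the cell-body layer. External sequencing
data are not required: a synthetic-data module generates every input with
known ground truth, and the test suite validates each stage against that
truth or against independent brute-force oracles.

## 3'UTR isoform discovery

Expressed final exons are assembled from two evidence layers: polyA-site
peaks (PAPERCLIP-like 3'-end tags) define 3' boundaries, and splice
junctions from ribosome-bound (TRAP) reads define 5' boundaries.

Filters use the published thresholds. Whole-cell polyA peaks are kept when
they have >= 10 tags AND >= 5% of the gene's tags; compartment peaks when
they have tags in >= 2 replicates. Junctions are kept when found in >= 10
reads OR >= 10% of the gene's junction reads; the fraction denominator
counts all junctions of the gene (the alternative — junctions sharing a
donor — is not what the wording implies and is not implemented). Each kept
polyA site is paired with the acceptor of its nearest upstream kept
junction (strand-aware); when none exists the 5' boundary falls back to
the annotated start of the stop-codon-containing exon, which covers
single-exon 3'UTRs. Ties between equidistant acceptors (possible with
overlapping annotation) are broken by read count, then by the 5'-most
acceptor. Candidates need >= 80% covered bases in at least one experiment
(inclusive comparison), must not overlap another gene's span or UTR, and
"ambiguous genes" — operationalized as genes whose annotated spans overlap
another same-strand gene — are removed entirely.

Genes with >= 2 surviving isoforms are classified: sites downstream of the
stop codon are tandem (3'UTR-APA, CDS unchanged; most stop-proximal =
proximal, most distal = distal, rest internal), sites upstream are
UR-APA (CDS-truncating); genes with both kinds are type `both`.

Coordinates are 0-based half-open throughout; a polyA "position" is the
right edge of the last transcribed base on the plus strand and the left
edge on the minus strand.

## Differential abundance and localization calls

The count test is a negative-binomial Wald test built from standard
pieces: median-of-ratios size factors; per-feature method-of-moments
dispersions on normalized counts, shrunk toward a fitted `a0 + a1/mean`
trend with weight `df / (df + prior_df)` (prior_df = 6) on the feature's
own estimate; an IRLS NB log-linear fit with the dispersion fixed; a Wald
p-value on the contrast coefficient against the standard normal (a
t-reference on residual df is available but makes the test conservative at
n = 4 per group — measured type-I error ~0.02 vs ~0.045 for the normal);
Benjamini-Hochberg FDR with all-zero features excluded from the
denominator. "Batch correction" is an additive batch covariate in the
log-linear model. This is deliberately not a re-implementation of any
published DE engine; it stands in at the level of decision logic, and its
calibration (type-I error within [0.03, 0.07] at alpha = 0.05) and power
(>= 0.9 for 4-fold changes at mean 100, dispersion 0.05, n = 4/group) are
verified by simulation in the acceptance suite.

Localization calls combine three contrasts, all in neuropil samples
unless stated: dendrite-present requires FDR < 0.05 and LFC > 0 for TRAP
vs bulk RNA-seq plus LFC > 0 for Cre+ vs Cre- TRAP (the Cre- control
removes background not specific to the tagged cell type); dendrite-enriched
additionally requires FDR < 0.05 and LFC > 0 for neuropil-vs-cell-body
TRAP. The LFC > 0 requirement on the enrichment contrast is implied but
not spelled out in the published wording ("significantly enriched"); it is
required here. The dendritic-localization metric exported for ranking is
the neuropil/cell-body LFC together with stat = LFC/SE.

## Differential 3'UTR usage

Isoform usage is tested with a beta-binomial likelihood-ratio test of
isoform-vs-rest-of-gene counts on the logit scale, rather than an
exon-bin GLM: the proportion semantics are direct and the type-I error is
testable. The beta-binomial concentration is estimated once under the
null and held fixed when fitting the alternative; refitting it freely
makes the chi-squared LRT markedly anti-conservative at n = 4 + 4
(measured ~0.08-0.11 vs ~0.05 with the fixed-concentration scheme). The
reported LFC is the log2 ratio of pooled empirical usage proportions
(with a half-count guard), not the shrunken model fit, which is attenuated
when the null concentration is small. An optional genotype x region
interaction term supports knockout designs; samples with a zero gene total
are dropped for that gene.

## CLIP scores and dendritic targets

CLIP expression is `E = (tags / length_kb) * 1e4 / library_total` per gene
and replicate — length first, then depth, scaled to 10,000 tags. The
library-normalized `tags_per_10k` (no length term) feeds the
reproducibility rule; reading "normalized tags per 10,000" literally as
length-free is a deliberate choice and configurable. Transcript length is
the gene's most highly expressed transcript. Per replicate and
compartment, ordinary least squares of log10(E) on log10(TPM) is fit over
genes with TPM > 1 and CLIP tags in >= 3 replicates; the CLIP score is
the raw log10 residual (observed minus fitted). The prior work this
construction follows does not restate whether the residual is
standardized; the raw residual is used. Genes outside the fit universe
still get scores when E > 0, via the fitted line; genes with zero tags in
a replicate get no score for that replicate (no pseudocount). Mean CLIP
score is the arithmetic mean over replicates with defined scores.

A gene is a dendritic FMRP target if it is reproducibly detected in the
neuropil (> 5 tags_per_10k, strict, in >= 3 of 5 replicates) OR its mean
neuropil CLIP score exceeds 1 (strict, in log10 residual units — the unit
is implied rather than stated in the source wording).

Preranked GSEA uses the weighted Kolmogorov-Smirnov walk (weight exponent
1) with a gene-label permutation null: nominal p compares |ES| with the
full permutation null with an add-one correction (so a maximally enriched
set reaches exactly 1/(n_perm+1)), NES divides ES by the mean |null ES| of
the same sign, and FDR is Benjamini-Hochberg across sets. Sets with < 5
genes in the universe are skipped.

## Splicing

PSI from junction reads only (the exon-coverage mode of the published
splicing tool is out of scope; junction-count PSI is what CLIP tags
admit). Skipped-exon and mutually-exclusive-exon events have two
inclusion junctions against one skipping junction, so
PSI = (I/2) / ((I/2) + S); alternative 5'/3' splice sites use the
one-vs-one ratio. Significant localized events are FDR < 0.05 and
|dPSI| > 0.1, labeled neuropil- or cell-body-included by the dPSI sign.
PSI vectors are compared by Pearson correlation with the two-sided
t-approximation p-value.

## FISH quantification

The pipeline starts at spot and nuclei coordinates (detection from raw
images is upstream commercial software). The cell-body-layer boundary is
estimated by cutting the image into 25 vertical slices, computing a
Gaussian-kernel-smoothed nuclei density along y per slice (bandwidth 5 µm,
configurable), and anchoring each slice where the density first falls
below 10% of the slice maximum moving toward the neuropil. The 10% point
of a Gaussian-smoothed sharp edge lies `z_0.90 * bandwidth` (≈ 6.4 µm at
the default) beyond the true edge, so that known offset is subtracted —
without it the fitted curve is biased toward the neuropil by several µm.
Anchors are fit with a degree-3 polynomial (degree configurable 1-5, not
stated in the source) in two rounds; anchors with |residual| > 2 SD after
round 1 are removed before the refit, a reproducible, automated stand-in
for the manual outlier curation described in the source. An orientation
flag states which side of the layer the neuropil is on; the anchor is
always the neuropil-facing edge.

Spot distance is the minimum Euclidean distance to the curve (densely
sampled at 0.1 µm), signed positive toward the neuropil; for gently curved
layers this nearly coincides with the vertical distance and matches the
"distance between the spot and the fitted curve" reading. The z coordinate
is recorded but unused (the analysis is in the section plane). Spots are
neuropil when distance > 10 µm (strict). Distribution comparisons use the
two-sample KS test on distances and the Wilcoxon rank-sum test on
per-image neuropil fractions (exact enumeration for <= 8 per group). The
genotype comparison samples 1000 spots per image (seeded; with replacement
if an image has fewer, flagged), bins distances into 15 equal-width bins
over 0-150 µm (range not stated in the source, configurable), and runs
per-bin two-sample t-tests with BH correction.

## G-quadruplex motifs

The motif is four `[AU]GGA` units with gaps of up to six nucleotides,
matched leftmost non-overlapping with greedy gaps (mirroring the behavior
of the R scanning function named in the source); an exhaustive-overlap
mode exists behind a flag. Greedy versus lazy gaps can alter match extents
but not per-sequence presence, and presence is the exported statistic
(whether counts rather than presence were compared in the source is not
stated; both are reported). Experimentally determined G4 sequences are
matched as exact substrings after T→U mapping; that set is user-supplied.
Enrichment between gene sets is Fisher's exact two-sided test.

## Synthetic data

The generator encodes the distributions the analysis assumes, at the real
study's design points: 4 TRAP/RNA replicates, 5 CLIP replicates, 4
PAPERCLIP replicates, 2 compartments, 2 genotypes, and a neuropil CLIP
library 80,749/746,827 ≈ 0.108 times the cell-body one. Genes (default
200; simulations that need a realistic transcriptome-wide tag-share
distribution use 1,000-10,000) lie on one synthetic chromosome with three
coding exons and a final exon; 40% carry a second tandem polyA site, an
intronic (CDS-truncating) site, or both. Counts are negative binomial
(dispersion 0.05) around library-scaled expression x isoform usage;
expression propensities are log-normal (median 100, sigma 0.8) with a
floor of 30 so that discovery-scale simulations exercise the count
filters rather than dropout. Junction reads split between isoforms by
true usage. Dendrite-enriched genes (20%) carry a +2 log2 boost in
Cre-positive neuropil TRAP only. CLIP intensity is log-linear in TPM with
a +1 log10 spike on FMRP-bound genes and 0.15 log10 replicate noise;
bound genes default to the top-expression stratum (`top_tpm`), matching
the biology that FMRP targets are abundant, long mRNAs — the `random`
mode decouples binding from abundance and is what the parameter-recovery
simulations use, since enrichment recovery is only identifiable there.
The recovered enrichment is measured as the difference between mean
scores of bound and unbound genes, which cancels the intercept shift that
spiked genes induce in the regression. FISH fields place nuclei pixels in
a 25 µm band on the cell-body side of a cubic boundary over a
135 x 135 µm frame (0.14 µm/pixel); spots mix a uniform cell-body
component with a neuropil component whose distance beyond the boundary is
exponential (mean 30 µm), weight 0.4, plus 0.5 µm coordinate noise.

What the generator does not emulate: read-level artifacts (mapping bias,
duplicates), annotation errors, overlapping gene neighborhoods beyond the
ambiguity filter's needs, cell-type contamination structure in bulk
RNA-seq, batch effects beyond an additive covariate, 3-D tissue geometry,
and spot-detection errors. Passing tests therefore demonstrate that the
decision logic and estimators behave as specified under the assumed noise
model, not that the thresholds are optimal for real data.

## Problem sizes and numerical choices

The acceptance computations use 200 genes for discovery, 1,000 null
features/genes for test calibration, 100 spiked features for power, 20
replicate simulations at 1,000 genes for CLIP-score recovery, 5,000 genes
(100 bound) for the target classifier, 20 fields for boundary recovery,
and 500 simulations x 400 permutations for GSEA calibration — sizes chosen
to put Monte-Carlo error comfortably inside the tolerance bands.
Dispersions are clipped to [1e-8, 10]; IRLS runs at most 50 iterations
with a 1e-8 relative tolerance; beta-binomial fits use Nelder-Mead; the
boundary density grid has 400 points per slice; Fisher/KS/rank-sum tests
come from scipy. Percentages that mirror printed values are rounded
half-up to one decimal.

## Known limitations

The NB test's dispersion shrinkage is simpler than empirical-Bayes
schemes and will under-shrink with very few features. The usage test's
fixed-concentration LRT trades a little power for calibration. Rule A of
the target classifier is abundance-confounded by construction (it flags
reproducibly detected genes, which at small transcriptome sizes is most
of them — interpret it at realistic transcriptome scale). GSEA FDR is BH
across sets rather than the permutation-based NES FDR of the original
method. The boundary estimator assumes the nuclear layer's density edge
is sharp relative to the smoothing bandwidth.
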