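# Methods

This note documents the statistical models, the numerical choices, and
the synthetic study conditions behind `tepseq`, at the level a
maintainer needs to change a default responsibly.

## Data model and quality control

The unit of measurement is the intron-spanning read: a read whose
alignment crosses an exon–exon junction and therefore evidences a
spliced transcript. Counting only these reads makes the assay robust to
contaminating plasma DNA, which cannot produce junction-crossing
alignments. Counts are stored genes-as-rows with library sizes defined
as column sums and kept consistent with the matrix at all times; gene
and sample order is preserved from input files because downstream
tie-breaks (TMM reference selection, correlation-filter removal order)
depend on it. The count array is normalized to C-contiguous memory on
construction: BLAS routines return bitwise-different results for
different memory layouts, and the classifier's locking guarantees are
stated at byte level.

Three label-agnostic filters run before any modeling, in this order:

1. **Gene abundance** — remove genes with fewer than 30 intron-spanning
   reads in more than 90% of the cohort. A gene survives if at least 10%
   of samples reach 30 reads.
2. **Detected genes** — remove samples detecting fewer than 750 genes
   (strictly fewer; a sample at exactly 750 stays).
3. **Leave-one-sample-out correlation** — for each sample, the reference
   is the per-gene median counts-per-million of all other samples;
   samples whose own CPM profile correlates below r = 0.5 with that
   reference are removed in a single pass (references are not
   recomputed after removals). Plain CPM on raw counts is used here, not
   the corrected expression: the filter runs before any training-cohort
   choice exists, and using model-derived normalization would create a
   circularity. No log transform is applied before the correlation;
   the filter targets gross profile corruption, for which the
   count-scale correlation is the sharper instrument.

Zero-variance profiles have an undefined correlation; they are treated
as failing the filter, with a warning, since a constant profile is by
definition low-complexity.

## Normalization and latent-factor correction

The correction module assumes unwanted variation (sequencing batch,
isolation timing, depth) is (a) approximately additive on the log-count
scale, (b) low-rank across samples, and (c) visible in genes that carry
no biology. Its stages, all locked to the training cohort:

**Stable genes.** A gene is a negative control when its raw counts
correlate with the intron-spanning library size at Pearson r ≥ 0.8 and
with donor age at |r| ≤ 0.2. The intuition: a gene whose counts are
proportional to depth is exactly the gene whose CPM is constant — it
carries technical variation but no per-sample biology. The age rule is
an exclusion (a gene tracking age is not stable); samples with missing
age are skipped in the age correlation only and are still corrected.
Both criteria must hold (intersection, not union).

**Factor estimation.** Let Y be the samples × controls matrix of
log(counts + 1), column-centered. Its first k left singular vectors
scaled by their singular values are the per-sample factor scores W;
the right singular vectors (gene loadings) and the control-gene means
are stored so held-out samples can be projected onto the same
directions without re-estimation. Default k = 3.

**Factor triage.** A factor is removed iff it does not separate the
clinical groups (two-sided t-test p > 1e-5 — a deliberately extreme
floor that protects even weak signal from deletion) and it correlates
with a named confounder (library size or age) at p < 0.01. A factor
matching no confounder is left in place even if it looks technical:
removing unattributed variation risks removing biology.

**Correction.** Per gene, log(counts + 1) is regressed on the removed
factor scores (coefficients estimated on the training cohort and then
locked); the fitted factor component is subtracted and the counts
back-transformed with `exp(·) − 1`, clipped at zero. The corrected
library size is the per-sample sum of corrected values.

**TMM.** The reference sample is the training candidate whose
75th-percentile CPM is closest to the candidates' mean (first in sample
order on ties), then locked. Each sample's factor is the doubly trimmed
(30% by M, 5% by A, rank-based with the `floor(np) + 1` trim bounds)
weighted mean of log2 expression ratios against the reference, with
inverse asymptotic-variance weights, exponentiated. Factors are
rescaled to geometric mean one over the *training* cohort; the
training-time rescaling constant is reused at prediction. Rescaling
over all samples would couple training factors to validation data and
break the byte-identity lock.

**logCPM.** `log2(1e6 (y + 0.5) / (N_eff + 1))` with
`N_eff = corrected library size × TMM factor`. Pseudo-counts: +1 inside
logs for factor estimation and correction, +0.5/+1 in logCPM.

**RLE diagnostics.** Relative log expression subtracts each gene's
across-sample median; the per-sample statistic is the absolute
deviation of the sample's median RLE from the overall median, compared
before/after correction with a paired two-sided t-test.

## Differential splicing

NB GLM with log link and log-effective-library-size offsets, fit by
iteratively reweighted least squares vectorized across genes (each
iteration solves one 2×2 weighted system per gene via batched solves;
linear predictors are clipped to ±50 to prevent overflow; convergence
is declared at a relative log-likelihood change below 1e-10, 50
iteration cap, non-convergent genes flagged and excluded from the FDR
denominator). This machinery is hand-written rather than delegated to a
per-gene GLM library because the swarm objective refits tens of
thousands of models per training run; it is verified in the test suite
against a brute-force likelihood-grid oracle and against an external
reference implementation at fixed dispersion (agreement ≈ 1e-10 on LR
and logFC).

Dispersions use the Cox–Reid adjusted profile likelihood
(`ll − ½ log det X'WX`): the common value maximizes the adjusted
likelihood summed over genes; per-gene values are maximized on a
15-point log-spaced grid (1e-5 to 10); a lowess of log dispersion
against average logCPM (frac 0.5) gives the trend; tagwise values shrink
the per-gene estimate toward the trend on the log scale with weight
`w = 10` (prior) against the residual degrees of freedom — an infinite
prior collapses tagwise onto the trend. Without the Cox–Reid term the
dispersion maximizer is biased low (the fitted group means consume two
degrees of freedom per gene) and the LRT runs measurably liberal.

The LRT compares intercept+group against intercept (χ², 1 df); logFC is
the group coefficient on the log2 scale, with factor levels ordered
lexicographically unless a reference level is named — this makes
label-swapping negate logFC exactly. Results are BH-adjusted; default
reporting keeps genes at logCPM ≥ 3 and FDR < 0.01. Two input paths are
exposed: corrected counts for signal exploration, raw counts for
classifier training (reproducibility of the locked pipeline on new
samples takes priority over maximal cleaning there). Clustering
diagnostics use Ward linkage on 1 − Pearson distances with a two-sided
Fisher exact test on the 2-cluster × group table.

## Classifier

Stages and their defaults:

- **ANOVA ranking**: NB-LRT on raw training counts (offsets = raw
  library sizes), panel = FDR < threshold ordered by LR descending.
  Inside swarm evaluations a fixed dispersion can be supplied to skip
  re-estimation (the acceptance script does this at the generator's
  dispersion).
- **Correlation filter**: while any pair of panel genes exceeds the
  cutoff in |Pearson r| (on logCPM), the member of the worst pair with
  the larger mean absolute correlation is dropped (later panel position
  on ties). Guarantees max pairwise |r| ≤ cutoff.
- **SVM-RFE**: linear-kernel SVM (C = 1) on per-gene standardized
  features; drop the lowest 10% by w² (at least one) per round until
  the target size remains; final order by last-round rank. The linear
  kernel is used only for ranking — the classifier itself is RBF — the
  standard RFE construction, since the RBF machine has no per-feature
  weights.
- **(C, gamma) selection**: full 21 × 21 powers-of-two grid
  (C ∈ 2^0..2^20, gamma ∈ 2^−20..2^0), mean AUC over 2-fold stratified
  CV with a fixed fold seed; ties break toward smaller C then larger
  gamma; degenerate single-class folds are re-folded (5 attempts). A
  `grid_step` parameter thins the grid for swarm-internal evaluations.
  A 2-particle-swarm then refines (log2 C, log2 gamma) in a ±2 box
  around the grid optimum with the grid point seeded as a particle, so
  refinement never loses CV AUC.
- **Outer swarm**: global-best PSO (inertia 0.72, cognitive = social =
  1.49, velocity clamped to 20% of box width — canonical
  constriction-equivalent values) over θ = (stable-gene libsize
  threshold ∈ [0.5, 0.95], ANOVA FDR ∈ [1e-4, 0.2], correlation cutoff
  ∈ [0.5, 1.0], RFE size ∈ [10, 1000], rounded at evaluation),
  minimizing 1 − AUC on the disjoint evaluation cohort. Stage failures
  (e.g. an empty panel) score 1. The correction module is recomputed
  per particle because θ₁ changes the stable-gene set.
- **Locking**: the final RBF SVM is fit on all training samples;
  per-gene training medians, feature means/SDs, and a Platt-style
  sigmoid `P = expit(a·d + b)` (Newton iterations on smoothed targets,
  damped steps for near-separable data) are stored. Prediction applies,
  in order: imputation (panel-gene counts with 0 ≤ y ≤ trigger replaced
  by training medians; triggers 12 for matched-style designs, 2 for
  full-cohort-style designs, bounds inclusive; absent panel genes count
  as zero), locked normalization, panel restriction, standardization,
  decision values, sigmoid. Class calls default to score ≥ 0.5.

Positive-class orientation follows the second sorted group label and is
recorded in the model; every evaluation in the package uses the same
orientation, so AUC and accuracy are unaffected by it.

Resampling procedures (LOOCV, label-permutation null with the
add-one-corrected p-value `(1 + #{AUC* ≥ AUC}) / (1 + B)`, random
training-cohort re-draws) refit only the SVM support vectors — the
panel, normalization and (C, gamma) stay locked, matching the stated
inputs of those procedures. Permutation replicates do not refit
cost/gamma.

## RBP motif engine

IUPAC motifs are expanded by Cartesian product of per-symbol base sets
and deduplicated across each RBP's motif list (U → T, uppercase).
Counting is non-overlapping left-to-right per expanded string, summed
over the set; N never matches because expanded strings contain only
A/C/G/T. UTRs are taken per transcript and side from a GTF (derived
from exon/CDS geometry when UTR features are absent; 0-based half-open
internally; minus-strand sequence reverse-complemented; transcripts
without CDS skipped with a warning). Coverage gating keeps 5′ UTRs at
≥ 3 reads and 3′ UTRs at ≥ 5 (the 3′ bar is higher to offset oligo-dT
amplification bias). Hits are summed over a gene's surviving
transcripts per side; per (RBP, side) the site counts are correlated
with DE log fold-changes (Pearson by default, Spearman behind a flag)
and BH-adjusted within side.

## Splice events

Isoform tables are filtered like genes (< 10 reads in > 90% of
samples), TMM+CPM normalized, and tested with the same NB LRT;
selection is FDR < 0.01 AND logCPM > 1. Loci with several selected
isoforms are *concordant* when all group-median differences share a
sign and *alternative* otherwise; a zero median difference is
sign-neutral (counts as agreeing with either direction). Exon-skipping
events must show > 10 assigned reads with nonzero inclusion *and*
exclusion support in strictly more than 60% of samples; surviving
events get a two-sided Welch t-test on PSI (the unequal-variance form
is the safer default for proportions with group-dependent coverage;
pooled-variance available), BH-FDR, and ΔPSI = median PSI difference.
Missing PSI values are excluded pairwise, never imputed. The
P-selectin-style signature correlates every gene's logCPM with a target
gene's, keeping r > 0 at FDR < 0.01, and reports the overlap with an
up-regulated DE set.

## Synthetic study conditions

`simulate_counts` emulates a shallow platelet RNA-seq cohort: per-gene
log-normal baseline abundances; log-normal library sizes (median
7.5e5, log-SD 0.35 — the shallow-sequencing regime above the 2e5
intron-spanning-read re-sequencing bar); NB counts at dispersion 0.2;
default scale 4,500 genes × 263 samples with training / evaluation /
validation roles at 35/15/50%. Planted structure, all recorded in a
truth object: a fraction of genes (default 10%) shifted by 2^±1 in the
disease group (half up, half down); 10% depth-tracking stable genes
sampled at dispersion 0.005 and excluded from all biology; a rank-one
latent batch factor additive on the natural-log scale (SD 0.5,
gene loadings ~|N(1, 0.25)|) that loads on the stable genes too —
negative controls must carry the unwanted variation for a factor model
to see it, and a batch confined to non-control genes would be invisible
to the method by construction; and an age-coupled 5% gene subset
(coefficient 0.4 per age SD). Ages are N(60, 10), matching the cohort
demographics the platform targets.

What the generator does *not* emulate: overdispersion heterogeneity
across genes (one φ), zero inflation, GC/length biases, correlated gene
modules beyond the planted factor, multi-site cohort structure, or
label noise. Passing tests therefore demonstrate correctness of the
algorithms under their stated model, not clinical performance; the
separable synthetic cohorts make AUC ≈ 1 expected, and the interesting
checks are the null calibrations (type-I error, permuted-label AUC) and
the recovery/locking contracts.

`simulate_utr_fixture` builds one single-exon plus-strand gene per
contig (5′ UTR, CDS, 3′ UTR), plants `round(effect × max(logFC, 0)) +
Poisson(0.3)` copies of one RBP's motifs into 3′ UTR background
scrubbed of accidental matches (and re-drawn if a junction creates
one), so the scanner recovers inserted counts exactly.
`simulate_psi_fixture` draws event baselines from a scaled Beta(2, 2),
per-sample PSI around the (shifted) group mean at concentration 60, and
inclusion/exclusion reads binomially given PSI and a Poisson(60) + 2
total.

## Problem sizes and calibration measurement

The test suite and acceptance script run cohorts of 400–2,000 genes and
80–160 samples with swarm settings of a few particles and iterations:
large enough to measure dispersion recovery to a few percent, stable
recall, batch-correction residuals and classifier behavior, while
keeping a full run in tens of seconds. Null calibration rates at
nominal 0.01 are measured on 2,000 events/genes so the Monte Carlo
standard error (~0.002) is small relative to the acceptance band.
Seeds are fixed throughout; every generator is a pure function of
(parameters, seed).

## Known limitations

- The outer swarm re-runs the full correction per particle; at
  publication-scale settings (hundreds of particles × thousands of
  genes) this is hours of compute and would want process-level
  parallelism (the objective evaluations are embarrassingly parallel).
- Dispersion trend estimation assumes enough genes (≥ ~100) for lowess
  stability; tiny panels fall back toward the common value via
  shrinkage.
- `exon_skipping_test` loops per event (Welch test with pairwise
  missing-data handling); vectorization is possible if event counts
  grow beyond ~10^5.
- Multi-level group designs, quasi-likelihood F-tests and exact NB
  tests are out of scope; the group factor must have exactly two
  levels.
- UTR derivation from annotations without explicit UTR features relies
  on CDS+exon geometry and skips CDS-less (non-coding) transcripts.
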