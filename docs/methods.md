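# Methods

This note records the models the package implements, the defaults and
why, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Genome arm

**Variant evidence model.** Each SNV record carries total depth, alt
depth split by strand, the in-read offsets of every alt-supporting base
(distance from the read's 5' start and 3' end), and the flanking
reference bases.  When only a VCF is available these fields travel in
INFO tags (`DP`, `ADF`/`ADR`, `RO`, `F5`/`F3`); `annotate_variants`
derives them from an aligned-read table otherwise.

**Filter cascade.** Fixed order: SNV extraction → blacklist → panel of
normals → germline sites → VAF = 1.0 → strand discordance → MNV →
read end.  Interpretations where the rules are qualitative:

* *Strand discordance* = alt allele observed on only one strand
  (`min(fwd, rev) == 0` with positive alt depth).
* *MNV* = two same-sample variants at distance exactly 1 bp on one
  chromosome; both members are removed.  The distance is a documented
  constant, not a tunable.
* *Read end* = the first/last 10 bp of a read (`read_end_bp = 10`,
  0-based offsets `< 10`).  A variant is removed only when **every**
  supporting read places the alt within the end region — one interior
  read rescues the call, since a single well-placed read argues against
  a position-specific error.
* VAF is compared with 1.0 after rounding to 6 decimals to avoid float
  jitter; VCF 1-based positions are converted to 0-based half-open
  coordinates at the module boundary (blacklist intervals are 0-based
  half-open).

**LMD reference.** Mutations are counted in non-overlapping 1-Mb
windows ("running windows" interpreted as a tiling; a sliding grid
would multiply-count mutations and is inconsistent with the window
count the downstream feature space assumes).  Chromosome-end remnants
shorter than half a window are dropped — density estimates on very
short windows are unstable.  Library sizes are normalized with TMM
(trimmed mean of M-values; 30% two-sided trim on M, 5% on A,
inverse-binomial-variance weights, reference column = upper-quartile
closest to the mean, factors rescaled to geometric mean 1).  The
implementation is from scratch and agrees with edgeR's
`calcNormFactors` to 1e-6 on test matrices.  Differential selection per
cancer type is a one-vs-rest negative-binomial GLM per window with
offset `log(libsize × TMM factor)` and a likelihood-ratio test, using a
method-of-moments common dispersion (median over windows of
`(s² − μ)/μ²` on depth-scaled counts; Poisson when the estimate is ~0).
This is a deliberate approximation to a quasi-likelihood F-test; the
package's correctness standard is planted-truth recovery (≥90%
sensitivity for 8-fold effects at 20 samples/type), not coefficient
parity with any specific count-model package.  P-values are BH-adjusted
per type; significant windows at FDR 0.05 are split by fold-change sign
and the top 25 per direction kept, ordered by |log2FC| with ties broken
by smaller FDR then window id.  One-vs-rest contrasts and log2
fold-change ordering are the package's choices where alternatives
(all-pairs, raw FC) were equally defensible.

**Genome features.** LVD divides each retained window's variant count
by the sample's *total* variant count (including variants in dropped
windows — "total per sample" taken literally), so the LVD block sums to
≤ 1.  Window retention (zero in at most 50% of training samples;
equality retains) is fitted on the training cohort and frozen into the
model manifest.  The 150 context features collapse substitutions to the
pyrimidine-reference strand.  Dinucleotide contexts are counted for
*both* flanks (one 5' and one 3' count per variant, so the 48-feature
block sums to 2): the category enumeration mentions "either" flank but
not a contribution rule, and two-flank counting discards no
information.  Variants with an undefined flank count toward the
substitution block only.

## Epigenome arm

**NDR reference.** Samples with fewer than 30,000 peaks are excluded
(strict `<`; configurable for desk-scale data).  Meta-peak merging
resolves overlap groups iteratively: keep the highest-score peak,
discard everything overlapping it, recurse — so peaks that only touched
a discarded peak survive.  Score ties keep the leftmost peak.
Cross-sample comparability of peak scores is assumed, as peak callers
emit comparable signal values.  Counting: fragments shorter than 150 bp
(strict) whose [start, end) contains the meta-peak midpoint
(`floor((start+end)/2)`).  Selection: TMM factors (shared
implementation with the LMD arm), log2-CPM with a 0.5 pseudo-count,
and a per-tissue one-vs-rest t-test with empirical-Bayes variance
shrinkage toward a fitted scaled-inverse-chi² prior (prior df by moment
matching on log s²; precision weights omitted) — an approximation to
the voom/limma route, again held to planted-truth recovery (≥90%
precision).  The 10,000-peak cap is applied **per tissue** (the V-plot
featurizer needs a per-tissue channel of equal size); peaks are ranked
by smallest p with ties broken by peak id.  Tissues with one sample are
excluded with a warning.

**V-plots.** The size axis is 100 one-bp bins over [100, 200) bp
(half-open, hence exactly 100 bins; length 200 is excluded).  The
position axis is 250 four-bp bins.  A stated ±1000 bp range is
internally inconsistent with 250 × 4 bp = 1000 bp of span; the bin
count and width are kept — they fix the tensor shape the CNN consumes —
and the range is ±500 bp (`col = (offset + 500) // 4`, offsets in
[−500, 500)).  `halfspan=1000` selects the alternative ±1000 bp / 8-bp
reading.  The x-coordinate is the **fragment center** offset from the
NDR midpoint; MNase-style fragment halving (`[start + L//4,
start + L//4 + L//2)`, floor rules, lengths < 2 skipped) is retained as
a diagnostic attribute only.  Every qualifying (fragment, NDR) pair
increments one cell, so a fragment near two midpoints counts twice.
Min-max normalization spans the whole per-sample tensor (the "per
sample" reading); per-channel scope is available via a flag; a constant
tensor maps to all zeros.

## Models and evaluation

Genome net: dense layers (default widths 256/64/16) each followed by
batch norm, ReLU and dropout 0.3, then a sigmoid (detection) or softmax
(localization) head.  Epigenome net: 3×3 stride-1 same-padding
convolution with `conv1_kernels` kernels → BN → ReLU → dropout → a
second convolution with a single kernel → BN → ReLU → dropout → flatten
→ dense → head.  Kernel size 3×3 and the dense widths are declared
defaults (the reference protocol leaves them to hyperparameter search).
Class imbalance is handled twice, deliberately: balanced class weights
in the loss *and* output-bias initialization to log prior odds — the
two are complementary and reduce to no-ops on balanced data.
Optimization is AdamW with early stopping (restore-best) and selection
of the best of N random restarts by validation loss.

The reference training profile is 30 restarts, patience 50, 250
first-layer kernels, and a 200-trial hyperparameter search
(`fit_gbdt_baseline` exposes the random-search hook for the tree
baselines).  The desk profile used throughout the examples and tests —
genome: 3 restarts, patience 20; epigenome: 1 restart, patience 3, ≤15
epochs, 4 kernels — was chosen once to keep a 200-sample cohort's
5-fold protocol in single-CPU minutes, and both profiles are plain
configuration (`PipelineConfig.profile`).

Cross-validation is stratified 5-fold; the four non-test folds are
re-split 3:1 (stratified) into train/validation, so every sample
receives exactly one out-of-fold score.  Scores are combined across
models by the arithmetic mean.  ROC-AUC uses the Mann–Whitney rank
statistic (ties shared).  Sensitivity at specificity level s uses the
smallest threshold whose control specificity is ≥ s (predicted positive
= score ≥ threshold), with a stratified percentile bootstrap (default
1000 resamples) for the 95% CI.  Localization reports argmax accuracy
and a row-normalized confusion matrix.

## Attribution

Integrated gradients with a zero baseline and 50 steps.  The
integration grid is the **midpoint rule** `α_k = (k + ½)/steps`: a
left-Riemann grid of the same gradients carries an O(1/steps) bias
that measurably exceeds the 1% completeness tolerance at 50 steps on
sigmoid heads, while the midpoint rule's O(1/steps²) error does not.
Completeness (Σ attributions = F(x) − F(0)) is tested against a
5000-step reference.  Interpretation-sample selection uses strict
thresholds (cancer > 0.8, normal < 0.2; localization: correct argmax
with score > 0.6).  "Top-100 regions" are taken over LVD features only
— the variant-type block is excluded because the region-level analyses
downstream compare against the LMD reference.  V-plot aggregations
follow the published axis conventions: image = mean |attr| over samples
and channels; size = additionally over positions, min-max normalized;
distance = matched vs unmatched channels per sample's class, averaged
over samples and sizes, with optional LOWESS smoothing for display.

## Synthetic cohort: what it emulates and what it does not

The generator's defaults are the package's study conditions:

| quantity | default | rationale |
| --- | --- | --- |
| fragment lengths | truncated normal, 166 ± 10 bp (normal), 145 ± 10 bp (tumor), bounds 60–400 | healthy cfDNA peaks near 166 bp; ctDNA is known to be shorter — the shift is stated qualitatively in the literature, so a ~20 bp mode shift was fixed once |
| tumor fraction | Uniform(0.05, 0.35) per cancer sample | the detectable range for WGS-level liquid biopsy |
| NDR depletion | 0.5 | fragments covering a matched-tissue NDR midpoint are kept with probability 1 − tf·0.5 |
| NDR geometry | 80 NDRs/tissue, 1 kb wide, ≥20 kb apart; 30% of fragment centers drawn within ±500 bp of some NDR | spacing guarantees a fragment covers at most one midpoint; the near-NDR mass reflects cfDNA's enrichment around regulatory chromatin and keeps desk-scale V-plots populated |
| tumor MAF | Poisson counts, background 2 mutations/window/sample, ×8 in planted high windows, ÷8 in low windows | the 8-fold effect is the benchmark the reference builder must recover |
| cfDNA variants | ~120 filter-passing background passengers/sample; tumor variants Poisson(tf × 1200), 80% placed in the label's high-LMD windows, VAF ≈ tf/2 | yields window occupancy high enough that the >50%-zero retention rule keeps windows, as it does on real WGS cohorts |
| contaminants | per sample ≈ 60 germline sites (cohort-shared; 30% homozygous), 8 VAF=1 artifacts, 8 single-strand, 4 MNV pairs, 8 read-end | no quantitative rates exist for these classes; values were fixed once so that every filter rule has positive and negative cases.  Each class carries exactly its own evidence signature (e.g. MNV pairs get guaranteed both-strand support) so per-rule sensitivity is testable |
| substitution spectra | one dominant substitution per cancer type | tumor types differ in mutational-signature composition; this gives the context features genuine localization signal |

All randomness derives from one seed through named CRC-keyed
substreams, so cohorts are bit-identical under a fixed seed and
per-sample draws are independent of cohort composition.

Not emulated: base-level sequencing error, alignment artifacts, real
genome sequence (flanking bases are drawn, not read from a reference),
GC content (the fragpattern GC covariate is caller-supplied), CNV
structure, and clinical covariates.  Passing tests therefore
demonstrate that the *algorithms* recover planted structure under the
stated noise model — not that the published cohort-level performance
transfers to real plasma data, which are controlled-access.

## Degenerate inputs and tie-breaks

Empty variant sets yield zero-count reports and flagged all-zero LVD
vectors; all-zero windows are excluded from LMD testing and reported;
constant GC degrades the LOWESS correction to a mean shift (warned);
constant tensors min-max to zeros; score ties in meta-peak merging keep
the leftmost peak; |log2FC| ties at the top-k boundary break by FDR
then window id; NDR selection ties break by p then peak id; k = 2
cross-validation splits the single non-test fold in half for
validation.

## Problem sizes

Desk-scale defaults used by the bundled tests and examples: 40 × 1-Mb
windows over four chromosomes, 30,000 fragments/sample, 200-sample
end-to-end cohorts (34 cancers/type × 3 types + 100 normals), 200-window
MAF benchmarks, 6,000–20,000-peak NDR matrices.  These sizes were
chosen once as the smallest at which every planted effect is
recoverable with comfortable margins; all caps and thresholds
(top 25, 10,000, FDR 0.05, 30,000-peak filter, 150 bp, 10 bp read end,
50 IG steps, 1000 bootstraps, 95/98/99% specificity) default to the
reference values and are ordinary configuration.
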