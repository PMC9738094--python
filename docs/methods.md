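# Methods

This note documents the models, thresholds and numerical choices behind the
`brcaness` pipeline, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the procedure was genuinely
open.

## Gene panel

The packaged panel holds 40 literature-curated BRCAness genes plus BRCA1
and BRCA2 as references.  Each gene carries an approximate
canonical-transcript TSS on **GRCh38** (1-based); the original analyses this
pipeline mirrors do not state a genome build, so the packaged table declares
its own and can be replaced wholesale via `read_panel`.  Gene-symbol
matching throughout is case-insensitive exact string match; no alias
resolution is attempted.

## Pathogenic-variant stage

Variant rows are kept when `FILTER` is passing (`PASS`, `pass`, `.`) and
`Variant_Classification` is in the configured non-silent set (missense,
nonsense, nonstop, frameshift ins/del, in-frame ins/del, splice site,
translation start site).  Unknown classification strings are excluded and
logged, never silently reclassified.

Catalog matching uses the genomic key (chrom, pos, ref, alt) after
**reference-free parsimony normalization**: the shared allele suffix is
trimmed first, then the shared prefix (advancing the 1-based position), with
at least one base kept per allele.  This canonicalizes the common padded
MAF/catalog representations of the same indel.  True left-alignment within
homopolymer runs needs the reference genome and is out of scope; two
representations anchored at different run positions will not match.  A
protein-level match mode (gene + HGVSp) exists but is off by default.

Carrier frequency is per-sample, not per-variant: a sample with several
PLPs in one gene is one carrier.  The denominator is every sample of the
cancer type; a type with no samples yields a missing cell, never zero.
Pearson correlations of frequency profiles against BRCA1/2 use the
two-sided t-transform p-value with pairwise-complete cancer types (n ≥ 3
required), and significance means p < 0.05 **and** |r| above the stage
threshold (0.5 for PLP frequencies, 0.4 for homozygous deletions, both
configurable).  Zero-variance vectors give an undefined, never-significant
result.

Per-cancer-type mutation means are reported raw and rounded with Python's
round-half-to-even.

## Copy-number stage

Only GISTIC code −2 counts as homozygous deletion.  The per-gene number
used for lower/higher classification against BRCA1/2 is the pan-cancer
pooled fraction (all samples pooled), because that comparison is a single
per-gene scalar; "lower" is a strict `<`, so ties are "not lower".  The
per-cancer-type burden is reported both as the sum and the mean over
non-reference genes, labeled as such, since a single canonical aggregation
is not defined for that summary.

## Promoter methylation stage

"Within 10 kb surrounding the TSS" is read as the closed window
TSS ± 10 kb; the half-width is the `tss_window` config knob for anyone
preferring a 10 kb total span.  A probe may fall in several genes' windows
and then counts for all of them.  "chr1" vs "1" chromosome naming is
normalized (and logged).

The per-gene, per-cancer mean beta averages over all (window probe, sample)
values; genes with no window probes are missing, never 0.  The
hypermethylation call is strictly `mean > 0.3`, with a 1e-12 tolerance
guard so a mean that is exactly the cutoff up to floating-point
representation is not called.  The methylation load sums per-gene means
over the 40 non-reference genes (BRCA1/2 reported separately).

For the silencing/enhancing association the per-sample promoter beta
(mean over window probes for that sample) is correlated with that sample's
expression within each cancer type; r ≤ −0.5 is silencing, r ≥ +0.5
enhancing, fewer than 3 shared samples undefined.  The per-sample level is
a documented choice: correlating across samples is the only way to get a
per-(gene, cancer) coefficient from one cohort.

## Differential expression stage

Cancer types with fewer than 5 normal samples are skipped entirely — the
expression feature is *missing* for them, not zero, and contributes 0 to
the composite Sum.  The test is the two-sided Wilcoxon rank-sum: exact
enumeration when the combined n ≤ 12 with no ties, otherwise the normal
approximation with midrank tie correction and continuity correction.
BH adjustment is applied within one cancer type across the tested panel
genes (the family in which the calls are made).  Fold change defaults to
the ratio of linearized means, mean(2^x − 1), because inputs are
log2(norm+1); a difference-of-log2-means variant is config-selectable.
"At least two-fold" is inclusive: fc ≥ 2 or ≤ 1/2.

## Survival stage

Patients are split at each gene's median expression; values strictly above
the median are "high", values equal to the median go to the **low** group
(documented tie rule), and an all-equal gene is degenerate and skipped.
The log-rank test accumulates the hypergeometric expectation and variance
of group-A deaths at each distinct event time; the two-sided p comes from
χ²(1).  The hazard ratio is the O/E estimator
HR = (O_A/E_A)/(O_B/E_B) with 95% CI exp(log HR ± 1.96·√(1/E_A + 1/E_B))
— self-contained, no iterative fitting; a proportional-hazards regression
is deliberately out of scope.  No multiple-testing adjustment is applied to
survival p-values (raw p < 0.05), which inflates the per-cancer prognostic
count under the null by design; the composite score inherits this caveat.
The prognosis feature counts non-reference genes with p < 0.05 in either
direction by default (`risky_mode="hr_gt_1"` restricts to HR > 1).

Patient stratification on panel expression uses hierarchical clustering
(Euclidean, average linkage — an explicit choice, since the mirrored
analysis names no algorithm), cut at k = 2, with groups named by mean
panel expression and separation reported as the silhouette coefficient.

## Composite score

Frequency features are sums over non-reference genes of per-gene
frequencies — the only aggregation consistent with reference-normalized
values well above 1.  Normalization divides by each reference type's
feature and requires all six reference features defined and non-zero
(a zero reference feature is an error naming the feature, since x/0 has no
meaning here).  The Sum treats missing cells as 0.  Qualification is
Sum > reference Sum, where the reference Sum is 2 × the number of defined
features (12.0 when all six are defined) — the value a reference scores
when every normalized cell is exactly 1.  With two distinct reference
types each reference row is 1.0 only in its own six columns; its realized
Sum therefore fluctuates around 12 and a reference can itself cross the
cutoff by noise.  An alternative "all columns ≥ 1" qualification rule was
considered and rejected: published candidate tables retain rows with
individual normalized cells below 1.

## Synthetic cohorts

The generator (`brcaness.simulate`) emulates the statistical shape of a
TCGA-style cohort, not its biology:

* carriers are independent Bernoulli draws at the planted per-gene,
  per-type probability; each carrier gets one catalog-matching variant;
  background variants (Poisson, mean 0.8/sample) span silent and
  non-silent classes with ~10% failing FILTER, exercising the filter path;
* GISTIC codes are −2 at the planted rate, else drawn from a fixed
  background distribution over {−1, 0, 1, 2};
* each gene gets 4 probes inside its TSS window and 1 outside; betas are
  Gaussian jitter (sd 0.05) around the planted mean, clipped to
  [0.01, 0.99] — a pragmatic stand-in for a beta distribution;
* tumor expression is a per-gene baseline (uniform 6–10) plus the planted
  log2 shift plus N(0, 0.5) noise; genes planted as methylation-silenced
  share a per-sample latent factor between promoter beta and expression,
  giving the anti-correlation the silencing call looks for;
* survival is exponential with baseline rate 1/1000 per day, each tumor's
  rate multiplied by the planted hazard ratio of every gene whose
  expression exceeds its within-type median, censored Uniform(0, 2000)
  days — the simplest model in which the true high-vs-low HR equals the
  planted rate ratio.

The default planted design (8 types: two references with moderate signal,
two BRCAness-high types with stronger and broader signal, four weak
background types; 120 tumors + 12 normals per type) fixes effect sizes at
magnitudes a pan-cancer cohort would show: carrier probabilities of 2–15%,
hypermethylation betas 0.4–0.5 over a 0.15 background, two- to four-fold
silencing, hazard ratios 2–2.5.  The generator is fully determined by
(design, seed): identical inputs give byte-identical cohorts.

What a green synthetic test does **not** establish: robustness to
mutational-signature structure, segment-geometry CNV artifacts, batch
effects, probe-level QC failures, informative censoring, or
between-feature correlations beyond the planted methylation–expression
coupling — none of which the generator emulates.

## Numerical choices and degenerate inputs

* Exact Wilcoxon path only without ties and combined n ≤ 12; verified
  against full enumeration of all rank assignments.
* BH adjustment is checked against the brute-force step-up definition at
  1e-12.
* Correlation, log-rank and hazard-ratio results on degenerate inputs
  (zero variance, no events, zero expected events) are *undefined* — NaN
  with an explicit flag — and excluded from significant sets and counts,
  never coerced to 0 or 1.
* Ranking ties in the composite Sum break by table order (stable sort), so
  ranks are always a permutation.
* Float tables are written with `%.17g` and parsed with round-trip float
  precision, making write→read an exact identity.

## Known limitations

* Indel matching is parsimony-trimmed, not reference-left-aligned.
* The O/E hazard-ratio estimator is mildly conservative (biased toward 1)
  relative to a Cox fit, with CI coverage verified empirically in
  [90%, 99%] at n = 300/arm.
* The pooled pan-cancer frequency weights cancer types by their sample
  counts; a mean-of-frequencies alternative is not provided for the
  per-gene classification (it is for the per-type burden).
* Survival p-values are unadjusted, as noted above.
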