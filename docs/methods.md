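# Methods

`txrescue` evaluates how far a candidate therapy moves a disease
transcriptome back toward its healthy state, in a design with a healthy
control group (CNT), a disease group (DM1) and one or more treated groups.
The motivating setting is myotonic dystrophy type 1, where expanded CUG
repeats sequester the Muscleblind-like (MBNL) splicing regulators:
antisense oligonucleotides either block a single miRNA binding site on an
*MBNL* 3′-UTR (a "blockmiR") or silence the miRNA outright (an
"antagomiR"), and the question is how much of the disease expression and
splicing signature each strategy reverses, and at what off-target cost.
All statistics operate on gene-level count matrices and junction-read
event tables; no read-level processing is performed.

## Differential expression

The disease signature and the treatment responses are defined by pairwise
contrasts on the count matrix:

1. **Normalization.** Median-of-ratios size factors: for each sample, the
   median over genes (restricted to genes with positive counts in every
   sample) of count / gene-wise geometric mean; factors are rescaled to
   geometric mean 1. If no gene is positive everywhere, factors fall back
   to total-count ratios. This removes library-size differences without
   assuming symmetric differential expression.
2. **Dispersion.** Counts are modeled as negative binomial with variance
   μ + φμ². Per-gene φ is estimated by pooled within-group moments:
   E[Σ(x − x̄)²] = df·(μ + φμ²) solved for φ on normalized counts, clipped
   at zero. A mean–dispersion trend φ(μ) = a + b/μ is fitted by least
   squares (moment estimates damped at their 95th percentile so a few wild
   genes cannot steer it) and each gene is shrunk toward the trend with
   weight df/(df + prior_df), prior_df = 10. The floor is 1e−8; a constant
   gene in an otherwise information-free matrix sits exactly at the floor.
   At the default design (4 + 4 samples) the estimator recovers a true
   φ = 0.2 with median ≈ 0.18 over 1000–2000 genes.
3. **Exact test.** Group sums of n i.i.d. NB(μ, φ) samples are NB with
   size n/φ. On size-factor-equalized pseudo-counts (normalized counts
   rounded to integers), the test conditions on the two-group total and
   computes the two-sided p-value by doubling the smaller tail of the
   conditional distribution of the group-A sum, capped at 1. For totals
   above 10⁵ the conditional support is truncated at ±50 SD, where the
   excluded mass is negligible.
4. **Thresholds.** Benjamini–Hochberg adjustment across genes; a gene is
   *altered* when padj < 0.05 and |log2FC| ≥ 1 (the fold-change threshold
   is inclusive). log2FC uses normalized group means with a pseudo-count
   of 0.5 so zero means cannot produce infinities. Genes with mean raw
   count < 5 over the tested samples are dropped before testing.

Under a global-null simulation (2000 genes, 4 vs 4, φ = 0.1) the raw
p-values are approximately uniform (fraction < 0.05 ≈ 0.055, KS distance
≈ 0.03); at |log2 effect| = 2 and mean 100 the procedure reaches recall
≈ 0.99 at empirical FDR ≈ 0.03. These numbers are recomputed by
`scripts/acceptance.py`, not quoted from anywhere.

This is a deliberately self-contained substitute for GLM-based DGE
toolchains; it does not claim numeric agreement with any of them, and it
fits no covariates or batch terms.

## % Recovery

For each disease-related gene (altered in CNT vs DM1) and each arm:

    % Recovery = 100 · (mean_treated − mean_disease) / (mean_control − mean_disease)

computed on *normalized* mean counts, since raw means confound library
size. 0% leaves the disease level untouched, 100% restores control
exactly. The ratio is unstable when control and disease means nearly
coincide, so genes with |mean_control − mean_disease| < 1 normalized
count are scored *undefined* and excluded from category counts (the guard
trips essentially never for genes that passed the 2-fold disease
threshold). Bins: unrecovered < 10 ≤ partial < 50 ≤ total ≤ 150 < over.
Negative recoveries (treatment moved expression away from control) fall
in "unrecovered". Boundary inclusivity is configurable because the bin
edges are conventions, not data.

A *reversal* is a disease-related gene altered in the treated-vs-disease
contrast in the direction opposing its disease direction; the summary
reports reversals as a fraction of all treatment-altered genes. An
*improvement* additionally requires at least partial magnitude recovery
(% Recovery ≥ 10); both statistics are emitted because the two published
fractions may not use the same rule. Cross-arm overlap uses the
intersection ratio |A ∩ B| / |A ∪ B| — the legend describing it divides
by "unaffected" genes, which we read as a typo for the affected union.

**Hard-target specificity.** Given a list of the miRNA's experimentally
supported targets, the report collects each target's log2FC and altered
flag per contrast and counts altered targets per arm. Targets below the
expression filter are reported as missing rather than counted.

## Splicing

PSI = 100 · inclusion / (inclusion + exclusion) junction reads. Group PSI
is computed from counts pooled (summed) across the group's samples —
merging reads before quantifying, as read-count-based splicing pipelines
do — and dPSI is the group difference in percentage points. Per event,
the disease-vs-control contrast is tested by a two-sided Fisher exact
test on the pooled 2×2 table, BH-adjusted across events. The event filter
keeps |dPSI| > 25, ≥ 10 pooled reads in each contrast group, and
padj < 0.05. The "very low coverage" quality class of splicing callers is
approximated by the read floor alone. A treatment *reverses* a filtered
event when its dPSI against disease opposes the disease shift's sign and
moves ≥ 5 percentage points (suppressing noise flips; configurable).
Percent splicing recovery is the PSI-scale analogue of % Recovery,

    PSR% = 100 · (PSI_treated − PSI_disease) / (PSI_control − PSI_disease),

undefined when the disease shift is under 1 percentage point. The PSR
formula is a design decision: the quantity is named but not defined in
print. Gel-densitometry splicing quantifications enter as pre-computed
PSI-like percentages; no image segmentation is performed.

## Assay formulas

* **Viability / TC50.** Percent inhibition = 100 − (A_transfected −
  mean A_media-only) · 100 / mean A_untransfected, exactly as printed
  (0 = fully viable; the denominator is deliberately not media-subtracted
  because the printed formula is not). TC50 is where the fitted
  log-dose curve crosses 50%. Because responses are percent-normalized by
  construction, the default fit fixes the 4PL asymptotes at 0 and 100 and
  estimates (log₁₀TC50, hill) by least squares with three hill-slope
  starts; `free_asymptotes=True` fits all four parameters (bottom ≤ top
  enforced via a non-negative span). The constrained default was chosen
  because, at realistic noise (SD 5 on six doses in triplicate), the free
  fit's sampling spread exceeds ±20% of the true TC50 in up to a quarter
  of replicates even at its global optimum, while the constrained fit —
  the standard model for normalized response data — stays within ±20% in
  ≈ 98/100 replicates. Flat profiles and non-convergence return a flagged
  degenerate result, never an exception.
* **2^−ΔΔCt.** Technical replicates are averaged per sample first; ΔCt =
  Ct_target − Ct_reference per sample; ΔΔCt subtracts the calibrator
  group's mean ΔCt (group means of per-sample ΔCt, not ratios of means),
  so the calibrator's relative quantity is exactly 1.
* **Mean pixel intensity** = thresholded gray-value sum / area (threshold
  10, pixels below it excluded from the sum and the default area).
* **Percent normal force** = 100 · (mean post-treatment grip / mean
  pre-treatment grip) / body weight, %/g.
* **Central nuclei** = 100 · central / total fibers.

## Synthetic data

The generator produces the four-group design with known ground truth.
Baseline gene means are log-normal (location 4, scale 1.5 on the natural
log), spanning means of roughly 1–10⁴ counts. A fraction (default 10%) of
genes are disease-affected with signed log2 effects uniform in [1, 3].
Counts are NB(μ, φ) with a single global φ (default 0.1; per-gene
override available). Treated means interpolate **linearly** between
disease and control, μ_t = μ_d + ρ(μ_c − μ_d), so the linear-count
% Recovery statistic has expectation exactly 100ρ and truth and estimate
are commensurable; ρ (default 0.8) may exceed 1 to express overshoot.
Off-target perturbations (multiplying the arm mean by 2^ε,
ε ~ Normal(0, sd)) apply only to antagomiR-like arms; the default
antagomiR arm derepresses each of the 57 designated hard-target genes
with probability 0.5 at sd 2, emulating the published contrast in which
whole-miRNA silencing altered about half the hard targets while the
site-blocker altered one. Group sizes default to 4 per group — the source
study does not state its RNA-seq replicate counts, so this is a
convention, not a reproduced fact.

Splicing events get binomial inclusion reads at a true PSI per group with
Poisson per-sample coverage (default mean 100); 30 of 200 events carry a
−40 point disease shift and the treatment moves 25 of them back by ρ.
Dose-response, Ct, grip and fiber generators follow the corresponding
assay models with Normal noise.

What the generator does *not* emulate: correlated genes, composition
effects, batch structure, outlier samples, isoform-level ambiguity, or
any fold-change structure copied from the deposited study data. Passing
the parameter-recovery tests therefore shows the estimators are correct
under the stated model, not that real data meet the model.

## Problem sizes and determinism

Validation studies run at 2000 genes × 16 samples (recovery, calibration,
power; 20 replicate seeds) and 400 genes × 100 seeds (specificity), sizes
at which the Monte-Carlo bands in the tests are comfortably resolved. All
draws flow from a single integer seed through spawned per-replicate
seeds; an end-to-end pipeline run writes a manifest of SHA-256 checksums,
and re-running with the same config is byte-identical.

## Known limitations

* The DGE procedure is two-group only (no covariates, no batch terms) and
  the conditional exact test is slightly conservative for very low
  counts, which the mean-count ≥ 5 filter mitigates.
* % Recovery is a per-gene ratio statistic; for weakly affected genes its
  sampling distribution is heavy-tailed, which the denominator guard only
  partially controls. Summaries over called (2-fold) disease genes are
  stable; summaries over arbitrary gene sets may not be.
* The published headline counts from the deposited study data (numbers of
  disease-related genes, altered hard targets, filtered events and so on)
  depend on that dataset and its upstream alignment/quantification
  toolchain and are out of scope here; the pipeline reproduces the rules,
  and its numbers on synthetic cohorts are validated against the
  simulation ground truth instead.
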