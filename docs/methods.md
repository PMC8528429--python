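# Methods

This note documents the statistical models, numerical choices and known
limitations of `cycleomics`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Data model

The central container is a gene × sample matrix with per-sample metadata
(subject, clinical group, treatment arm, hours after synchronization) and a
scale flag (`counts` or `logcpm`). All rhythm statistics operate on log2
CPM values after participant batch removal; library sizes are computed on
the unfiltered count matrix and frozen, so gene filtering never changes CPM
denominators (filtering and transformation therefore commute).

## Preprocessing

- **Filtering.** A gene survives when its raw count is ≥ `min_count`
  (default 10) in at least `min_samples` samples (default: the size of the
  smallest group × treatment cell) and its total is ≥ `min_total` (default
  15). This explicit three-parameter rule stands in for filter heuristics
  whose internals differ between toolkits; all three are exposed.
- **log2 CPM.** `log2((count + prior)/(lib + 2·prior) · 10⁶)` with prior
  0.5.
- **Batch removal.** Donors introduce additive per-subject offsets shared
  across genes. Per gene, expression is regressed by OLS on the protected
  design (group × treatment cells plus time as a categorical factor) and
  sum-to-zero batch contrasts, and the fitted batch component is
  subtracted. Because subjects are *nested* in clinical groups (each donor
  belongs to one group but crosses treatment arms), a global sum-to-zero
  subject coding would be collinear with the group effect; the contrasts
  are therefore built within the finest protection level in which batches
  nest (group × treatment cell, then group, then the whole cohort). On
  balanced designs this leaves every protected cell mean exactly unchanged
  (≤ 1e-14 in tests) and is idempotent. Genuine collinearity (e.g. a batch
  aliased with time) raises an error naming the offending columns.
  Between-group differences in mean donor offset are deliberately *not*
  removed — they are indistinguishable from a group effect.
- **Centering.** Mean-centering or z-scoring per gene within each
  group × treatment cell, used before differential-rhythmicity testing and
  for heatmap matrices. z-scoring refuses genes constant within a cell.

## Umbrella rank test for rhythmicity

Sampling times are folded to phases modulo the period `T`; the default
design (12–54 h every 6 h, T = 24) folds to four phases each observed twice
per subject. With `k` distinct phases, an **envelope** is a peak phase
crossed with a rise length `r ∈ 1..k−1`; its trough sits `r` phases before
the peak on the circle, giving a rising limb (trough→peak) and a falling
limb (peak→trough). The envelope induces expected orderings on phase pairs
within each limb (the shared trough–peak pair counted once). The statistic
sums, over subjects and over all sample pairs realizing those phase pairs,
`1[x_lo < x_hi] + ½·1[x_lo = x_hi]`. All `k(k−1)` envelopes are evaluated,
which makes the test sensitive to asymmetric (sawtooth-like) waveforms as
well as sinusoids; being rank-based, it is invariant to monotone
transforms of expression.

**Exact null.** Under the null, each subject's values are exchangeable
across its time slots. The per-subject null distribution is enumerated
exhaustively (≤ 8 observations per subject → ≤ 8! permutations, computed
vectorized and cached by envelope shape, per-phase observation counts and
tie multiset; tied values are permuted as the observed multiset so that
½-counts are handled exactly). Subjects are independent, so the cohort null
is the convolution of the per-subject distributions. For more than 8
observations per subject a normal approximation with continuity correction
is used, with the exact mean `m/2` and a variance assembled from the pair
covariance structure (±1/12 for pairs sharing an endpoint).

**Envelope-family correction.** The per-gene p-value is derived from the
minimum envelope p. Overlapping envelopes are strongly positively
correlated, and a Bonferroni multiplication by `k(k−1)` is measurably
conservative: at the 7-subject, 8-phase design the null rejection rate at
nominal 0.05 is ≈ 0.025. The default therefore calibrates the minimum
envelope p against its **exact joint permutation null**: because the
statistic is rank-based, i.i.d. continuous draws per subject reproduce the
joint null law of all envelope statistics, so 20 000 seeded standard-normal
null series (a fixed internal seed, configurable) yield the reference
distribution of the min-p, and the reported p is the empirical tail
probability `(1 + #{null ≤ observed})/(B + 1)`. Measured null rejection at
0.05 is 0.039–0.048 across seeds, and p-values have granularity
`1/(B+1) = 5·10⁻⁵`. `correction="bonferroni"` restores the conservative
closed-form variant (and is what the exhaustive single-subject oracle in
the tests reproduces exactly).

Peak time is the peak phase of the minimizing envelope, reported on the
phase grid in `[0, T)` with phase 0 displayed as `T` (a peak at the start
of the cycle is conventionally labeled hour 24). Oxygen-consumption series
are the same test at period 16 with one series per subject; no separate
code path exists.

## Differential rhythmicity

Comparing rhythm parameters between groups is only meaningful for genes
with some rhythmic evidence; testing everything inflates false positives.
Genes are therefore subset on the meta p-value
`1 − (1 − min(p₁, p₂))²` — the Beta(1,2) CDF of the smaller of the two
per-group rhythm p-values, i.e. the law of the minimum of two independent
uniforms — BH-adjusted within the comparison, threshold 0.10. For each
tested gene and group, `y ~ a·cos + b·sin + c + d·t` is fit by Huber
M-estimation (tuning constant 1.345; values re-centered per group
internally, since the test assumes identical means), and the Wald statistic
on `(a_A − a_B, b_A − b_B)` uses the sum of the two robust coefficient
covariances. Two finite-sample adjustments replace the asymptotic
chi-square reference, which at ~50 samples per group rejects ≈ 8% of true
nulls at the 0.05 level: the covariances are scaled by `n/(n − 4)` and the
statistic is referred to `2·F(2, n_A + n_B − 8)` (Hotelling-style). The
measured null error rate is 0.055–0.064 across seeds, with power 1.0 at a
threefold amplitude attenuation (log2 amplitude 0.9 vs 0.3, noise SD 0.25,
7 vs 5 donors). p-values are BH-adjusted across tested genes; untested
genes carry NaN.

## Amplitude algebra

On log2 data the cosinor amplitude `A_log = √(a² + b²)` is half the log2
peak-to-trough difference, so the natural-scale fold-change amplitude is
`A_fc = 2^(2·A_log)` and the relative amplitude — (peak − trough)/(peak +
trough), dimensionless and comparable across experiments — is
`A_rel = (A_fc − 1)/(A_fc + 1)`. The round trip `A_log → A_fc → A_rel →
A_log` is the identity to 1e-10 over `A_log ∈ [0, 3]`. Group comparisons
use per-gene `log2(A_rel,alt/A_rel,ref)` (genes with a zero amplitude in
either group excluded and counted), a two-sided KS test contrasting
rhythmic vs non-rhythmic ratio distributions, and a paired Wilcoxon test
(exact for n ≤ 25 without ties, else normal approximation with continuity
correction). The written phase is `(T/2π)·atan2(b, a) mod T`, clamped to
`[0, T)` against floating-point wrap.

Detrending subtracts the OLS straight line through the *fitted* curve, so
the post-detrend OLS slope is 0 by construction (< 1e-9 in tests). Note
that for a cosine sampled on a discrete grid the OLS slope is generally
nonzero unless the grid is symmetric about a multiple of the half-period —
detrending is therefore not identical to mean removal on asymmetric grids.
Phase clustering uses the circular metric `min(|Δφ|, T − |Δφ|)` with Ward
linkage on the precomputed distances (the `ward.D2`-style criterion).

## Enrichment, trait correlation, integration

- **ORA.** Hypergeometric upper tail (or probability-mass two-sided) on the
  2×2 of list × set membership over an explicit universe; the odds ratio is
  the sample value `ad/bc` (infinite when `bc = 0 < ad`), not the
  conditional MLE some packages report. Collections are BH-adjusted and
  ranked by *gene ratio* — overlap divided by the number of significant
  genes belonging to any set of the collection. The universe must be
  supplied per run (the testable background differs between platforms); the
  pipeline uses all genes surviving the expression filter.
- **Trait correlation.** Spearman ρ with average ranks; for n ≤ 9 subjects
  the two-sided p comes from the exhaustive permutation distribution of the
  trait ranks (vectorized over genes), otherwise from the t approximation;
  BH across genes.
- **Peak assignment.** Each peak (midpoint) is assigned to the gene with
  the nearest TSS on its chromosome within 50 kb (default; strand-agnostic,
  both parameters exposed), ties to the lexicographically earlier gene id;
  a gene's representative peak is its highest-scoring assignment. The
  inverse reading (each gene claims its nearest peak) is available behind
  `mode="gene_to_peak"`.
- **Binary profile clustering.** With a handful of binary features,
  grouping genes by *exact* profile is deterministic and parameter-light;
  profiles below `min_cluster_size` (default 5) collapse into an
  "unclustered" residual label 0, clusters are numbered by descending size
  with lexicographic tie-break.
- **Set overlaps** report the one-sided Fisher p (identical to the ORA p on
  the same 2×2, asserted in tests), BH across a batch, and the Jaccard
  index.
- **TF enrichment.** Per TF, a one-sided Fisher test of its target set
  against each group's rhythmic set over the expression universe; TFs with
  zero rhythmic targets are excluded before testing, BH within each group.
  Self-edges are retained but flagged. Identifier conversion is delegated
  to user-supplied two-column mappings (one-to-many expanded, unmapped and
  multi-mapped ids counted).

## Synthetic cohorts

The generator emulates the study design: two donor groups (7 and 5
subjects), two treatment arms, eight 6-hourly harvests from 12 to 54 h
after synchronization, signals on the log2 scale. Gene `g` in subject `s`
follows `mesor_g + slope_g·t + A_g·att·cos(2π(t − φ_g)/T) + offset_s + ε`,
with uniform mesor in [3, 10] (log2 CPM-like), phase uniform on `[0, T)`,
amplitudes uniform in [0.5, 1.0] for the rhythmic fraction (default 50%),
trend slope SD 0.01 log2/h, subject offset SD 0.5, residual SD 0.3. The
second group's (and challenge arm's) amplitudes are multiplied by 0.5,
reproducing the direction of dampened oscillations under disease and under
a high glucose/insulin milieu. Dispersions are not estimated from any
cohort — they are chosen once to make a realistic, well-powered testbed. A
count-scale variant exponentiates the log2 signal into transcript
proportions and draws Poisson counts at a fixed 20-million-read library, a
convenience for exercising the count pipeline rather than a claim about
RNA-seq noise.

What the generator does **not** emulate: gene–gene correlation,
count-overdispersion beyond Poisson, gene-specific subject effects,
waveform asymmetry (planted signals are cosines, although the detector
accepts asymmetric shapes), missing samples, or amplitude–expression
coupling. Passing tests therefore demonstrate correctness and calibration
of the statistics under the declared model, not performance on any real
cohort.

## Problem sizes and determinism

The acceptance checks run 2000-gene cohorts for calibration/power, 500–1000
genes for the differential tests, a 1500-gene two-group cohort for the
end-to-end directional findings, 10⁵ draws for the meta-p Monte-Carlo, and
1000 genes for peak assignment — sizes at which every measured rate is
stable to a few tenths of a percent while the full suite stays fast. All
randomness flows from explicit seeds; the pipeline writes a manifest with a
config hash and reruns byte-identically.

## Known limitations

- The rhythm test's exact path requires ≤ 8 observations per subject;
  denser designs fall back to the normal approximation.
- Permutation-calibrated p-values cannot go below `1/(B+1)`; raise
  `n_null` when extremely small p-values matter.
- The differential test compares cosinor coefficients at a fixed period; a
  pure period change with matched amplitude appears as a phase/shape
  difference and is only partially captured.
- Exact-profile clustering is intentionally rigid: features must be binary
  and noiseless; noisy features should be thresholded upstream.
- Ties in expression values are handled exactly in the envelope null but
  the permutation family-calibration assumes continuous data; with heavily
  discretized input prefer `correction="bonferroni"`.
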