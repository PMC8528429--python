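# cycleomics

Circadian rhythmicity analysis for grouped time-course expression data.

Primary cell cultures keep a cell-autonomous circadian clock: after a serum
shock synchronizes the population, transcript levels oscillate with a
roughly 24-hour period. Comparing these oscillations between clinical
groups — for example myotube cultures from donors with normal glucose
tolerance (NGT) versus type 2 diabetes (T2D) — requires statistics that
respect the repeated-measures design (each donor contributes a full time
course), detect non-sinusoidal waveforms, and quantify amplitude on a scale
comparable across conditions. `cycleomics` provides that toolchain for
bioinformaticians analyzing bulk RNA-seq (or microarray/OCR) time courses:

- **Rhythm detection** — an umbrella rank test for longitudinal designs.
  Sampling times are folded to phases modulo the period; each candidate
  *envelope* (a peak phase plus rise/fall lengths) orders the phases into an
  increasing then decreasing sequence, and the statistic counts
  within-subject time-point pairs consistent with that ordering (ties count
  ½). The exact null is the convolution over subjects of exhaustively
  enumerated per-subject permutation distributions; the minimum envelope p
  is calibrated against its exact joint permutation null (or
  Bonferroni-corrected on request). Being rank-based, the test is invariant
  to monotone transforms and sensitive to asymmetric waveforms.
- **Differential rhythmicity** — genes are pre-filtered on a beta
  order-statistic meta p-value, `1 − (1 − p_min)²`, combining the two
  per-group rhythm p-values (BH < 0.10), then tested by a Wald comparison of
  robustly estimated harmonic coefficients (Huber M-estimation, c = 1.345,
  with linear trend).
- **Amplitude algebra** — per gene and group, least squares fits

  `E(t) = a·cos(2πt/T) + b·sin(2πt/T) + c + d·t`

  give the log2-scale amplitude `A_log = √(a² + b²)`, the fold-change
  amplitude `A_fc = 2^(2·A_log)` (peak/trough ratio on the natural scale),
  and the dimensionless relative amplitude

  `A_rel = (A_fc − 1)/(A_fc + 1)`,

  compared across groups by per-gene log2 ratios, a two-sided KS test and a
  paired Wilcoxon test; detrending (`E′ = E − (α + β·t)`) prepares heatmap
  displays, and peak phases cluster hierarchically under the circular
  (geodesic) metric.
- **Preprocessing** — low-expression filtering, log2 CPM with frozen library
  sizes, OLS removal of the per-participant batch effect with the
  group × treatment × time design protected, and per-group centering/z-scoring.
- **Enrichment and integration** — hypergeometric over-representation
  analysis ranked by gene ratio, Spearman correlation of basal expression
  with a clinical trait (exact permutation p for small cohorts), ChIP
  peak→nearest-TSS gene assignment, binary feature matrices clustered by
  exact profile, Fisher/Jaccard set overlaps, and per-TF enrichment of
  rhythmic genes in a TF→target network.
- **Synthetic cohorts** — a seeded generator reproducing the study design
  (donor groups, treatment arms, 6-hourly sampling 12–54 h, cosinor signal
  with trend, subject offsets, group-wise amplitude attenuation) with full
  ground truth, so every stage is testable without any download.

## Worked example

```python
import cycleomics as co

cfg = co.SimConfig(n_genes=500, frac_rhythmic=0.5, treatments=("control",), seed=1)
tc, truth = co.simulate_timecourse(cfg)   # 12 donors x 8 time points, log2 scale
tc = co.remove_batch(tc)                  # remove per-participant offsets
res = co.rhythm_analysis(tc, period=24.0, fdr_threshold=0.10)
print(res[res["rhythmic"]].groupby("group").size())
```

Running `python examples/rhythm_detection.py` (this cohort) prints:

```
NGT: 301 rhythmic genes at FDR < 0.10 (of 500)
T2D: 261 rhythmic genes at FDR < 0.10 (of 500)
...
fraction of truly rhythmic genes detected (both groups pooled): 0.97
```

Half of the 500 genes were planted as rhythmic; nearly all are recovered in
the NGT-like group, while the T2D-like group — whose planted amplitudes are
halved — yields fewer detections, the qualitative signature of dampened
circadian output in disease. The other scripts in `examples/` walk through
amplitude comparison, differential rhythmicity, enrichment/trait
correlation, integrative overlap and the end-to-end pipeline
(`cycleomics all --outdir run --seed 7` from the shell).

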