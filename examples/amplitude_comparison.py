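"""Compare oscillation amplitudes between two groups.

Fits a cosinor with linear trend per gene and group, converts the log2
amplitude A_log into the dimensionless relative amplitude
A_rel = (2^(2 A_log) - 1)/(2^(2 A_log) + 1), and contrasts the groups by
per-gene log2 A_rel ratios, a KS test (rhythmic vs non-rhythmic genes) and
a paired Wilcoxon test.
"""

import warnings

warnings.filterwarnings("ignore")

import cycleomics as co

cfg = co.SimConfig(n_genes=800, treatments=("control",), seed=2)
tc, truth = co.simulate_timecourse(cfg)
tc = co.remove_batch(tc)

res = co.rhythm_analysis(tc, period=24.0)
circadian = set(res.loc[res["rhythmic"], "gene_id"])

fits = co.harmonic_fits(tc, period=24.0)
fa = fits[fits["group"] == "NGT"]
fb = fits[fits["group"] == "T2D"]
comp = co.amplitude_ratio(fa, fb, circadian)

print(f"mean log2(A_rel T2D / A_rel NGT), circadian genes: {comp.mean_ratio_circadian:+.3f}")
print(f"mean ratio, non-circadian genes:                   {comp.mean_ratio_noncircadian:+.3f}")
print(f"KS test circadian vs non-circadian ratios: D={comp.ks_statistic:.3f}, p={comp.ks_p:.2e}")
print(f"paired Wilcoxon A_rel NGT vs T2D:          p={comp.wilcoxon_p:.2e}")
print()
print("A negative circadian mean ratio says oscillations are flatter in the")
print("second group; the generator planted a 2-fold amplitude attenuation, so")
print("circadian ratios center near -1.  Non-circadian genes carry only noise")
print("amplitudes, which are upward-biased in the smaller (5-donor) group —")
print("hence their slightly positive mean — and the KS test separates the two")
print("distributions cleanly.")
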