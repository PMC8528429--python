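"""Test genes for changed rhythmicity between two groups.

Genes are pre-filtered on the BH-adjusted beta meta p-value of the two
per-group rhythm p-values, then tested by a Wald comparison of robustly
estimated harmonic coefficients (Huber M-estimation with linear trend).
"""

import warnings

warnings.filterwarnings("ignore")

import cycleomics as co

cfg = co.SimConfig(
    n_genes=300, frac_rhythmic=1.0, noise_sd=0.25,
    amplitude_range=(0.9, 0.9), amplitude_attenuation=1 / 3,
    treatments=("control",), seed=3,
)
tc, _ = co.simulate_timecourse(cfg)
tc = co.remove_batch(tc)
a = tc.subset_samples(tc.condition_mask("NGT"))
b = tc.subset_samples(tc.condition_mask("T2D"))

res = co.differential_rhythmicity(a, b, period=24.0)
tested = res[res["tested"]]
n_hit = int((tested["diff_fdr"] < 0.10).sum())
print(f"genes passing the meta-p subsetting: {len(tested)} of {len(res)}")
print(f"differentially rhythmic at FDR < 0.10: {n_hit}")
print(f"detection fraction: {n_hit / len(tested):.2f}")
print()
print("Every gene here oscillates with log2 amplitude 0.9 in the first group")
print("but 0.3 in the second; the Wald test on the cos/sin coefficient")
print("difference flags that threefold attenuation in nearly all genes.")
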