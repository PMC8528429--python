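"""Detect rhythmic genes in a synthetic two-group cohort.

Simulates the default study design (7 NGT-like and 5 T2D-like donors,
samples every 6 h from 12 to 54 h after synchronization), removes the
participant batch effect, and runs the umbrella rank rhythm test at a
24-hour period in each group.
"""

import warnings

warnings.filterwarnings("ignore")

import cycleomics as co

cfg = co.SimConfig(n_genes=500, frac_rhythmic=0.5, treatments=("control",), seed=1)
tc, truth = co.simulate_timecourse(cfg)
tc = co.remove_batch(tc)

res = co.rhythm_analysis(tc, period=24.0, fdr_threshold=0.10)
for (group, _), sub in res.groupby(["group", "treatment"]):
    n = int(sub["rhythmic"].sum())
    print(f"{group}: {n} rhythmic genes at FDR < 0.10 (of {len(sub)})")

hits = res[res["rhythmic"]].nsmallest(3, "p_value")
print("\nstrongest rhythms (gene, group, p, peak hour):")
for r in hits.itertuples(index=False):
    print(f"  {r.gene_id}  {r.group}  p={r.p_value:.2e}  peak={r.peak_label:g} h")

sens = res.set_index("gene_id").loc[truth.rhythmic_ids, "rhythmic"].mean()
print(f"\nfraction of truly rhythmic genes detected (both groups pooled): {sens:.2f}")
print("The attenuated (T2D-like) group recovers fewer genes: its planted")
print("amplitudes are halved, so weak oscillators fall below detectability.")
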