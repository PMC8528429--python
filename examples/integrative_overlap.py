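"""Integrate rhythmicity with ChIP binding and cluster binary profiles.

Assigns simulated ChIP peaks to the gene with the nearest TSS, builds a
binary gene × feature matrix (rhythmicity, binding), clusters genes by
exact profile, and scores the rhythmic/bound overlap with Fisher's exact
test and the Jaccard index.  A TF→target table is tested for enrichment of
rhythmic genes per TF.
"""

import warnings

warnings.filterwarnings("ignore")

import numpy as np

import cycleomics as co

rng = np.random.default_rng(5)
universe = [f"gene{i:05d}" for i in range(1000)]
rhythmic = set(rng.choice(universe, size=150, replace=False))

peaks, tss, bound_truth = co.simulate_peaks_and_tss(1000, 0.3, seed=5)
assigned = co.assign_peaks_to_genes(peaks, tss, max_distance=50_000)
bound = set(assigned.index[assigned["bound"]])
print(f"peaks assigned: {int(assigned['bound'].sum())} bound genes "
      f"(truth {len(bound_truth)}, recovered exactly: {bound == bound_truth})")

bm = co.build_binary_matrix({"rhythmic": rhythmic, "bound": bound}, universe)
clusters = co.cluster_binary(bm, min_cluster_size=5)
print(f"binary profiles -> {clusters[clusters > 0].nunique()} clusters "
      f"(sizes: {clusters.value_counts().sort_index().tolist()})")

ov = co.overlap_test(rhythmic, bound, universe)
print(f"rhythmic vs bound overlap: {ov.n_overlap} genes, "
      f"OR={ov.odds_ratio:.2f}, p={ov.p_value:.3f}, Jaccard={ov.jaccard:.3f}")

edges = co.simulate_tf_edges(universe, sorted(rhythmic), seed=5)
tfres = co.tf_enrichment(edges, {"NGT": rhythmic}, universe)
best = tfres.nsmallest(1, "p_value").iloc[0]
print(f"top TF: {best['tf_id']} (overlap {best['overlap']}, fdr={best['fdr']:.2e})")
print("\nIndependent random sets give OR near 1; the planted TF whose targets")
print("are mostly rhythmic stands out with a tiny FDR.")
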