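"""Gene-set over-representation and trait correlation.

ORA asks whether rhythmic genes are over-represented in a curated set via
the hypergeometric test, ranking enriched sets by gene ratio; trait
correlation relates per-subject basal expression to a clinical measure
(an insulin-sensitivity-like value here) by Spearman rank correlation.
"""

import warnings

warnings.filterwarnings("ignore")

import numpy as np
import pandas as pd

import cycleomics as co

rng = np.random.default_rng(4)
universe = [f"gene{i:05d}" for i in range(2000)]
rhythmic = list(rng.choice(universe, size=200, replace=False))

sets = co.simulate_gene_sets(universe, rhythmic, n_decoy_sets=20, seed=4)
coll = co.GeneSetCollection(sets, universe)
res = co.enrich_collection(rhythmic, coll, fdr_threshold=0.10, top_k=5)
print("enriched sets (ranked by gene ratio):")
for r in res.itertuples(index=False):
    print(f"  {r.set_name}: overlap={r.overlap}/{r.set_size}, "
          f"gene_ratio={r.gene_ratio:.3f}, OR={r.odds_ratio:.1f}, fdr={r.fdr:.2e}")

# basal expression for 12 subjects; 30 genes track the trait
trait = pd.Series(rng.normal(6, 2, size=12), index=[f"s{i}" for i in range(12)])
expr = pd.DataFrame(
    rng.normal(size=(300, 12)), index=universe[:300], columns=trait.index
)
expr.iloc[:30] += 0.8 * trait.to_numpy()
cor = co.correlate_with_trait(expr, trait)
n_sig = int((cor["fdr"] < 0.10).sum())
print(f"\ngenes correlated with the trait at FDR < 0.10: {n_sig}")
print(f"median |rho| among the 30 planted trait-tracking genes: "
      f"{cor['rho'].iloc[:30].abs().median():.2f}")
print("\nThe planted set (80% rhythmic members) dominates the decoys, and the")
print("trait-tracking genes surface with high rank correlations.")
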