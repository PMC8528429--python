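"""Integrative overlap of rhythmicity, trait correlation and TF binding.

Connects the transcriptomic results to orthogonal evidence: ChIP peaks are
assigned to the gene with the nearest transcription start site, homologs are
mapped across species via a two-column table, and the per-gene evidence is
assembled into a binary feature matrix (rhythmic per condition, trait-
correlated, bound per protein).  Genes sharing an identical binary profile
form a cluster; overlaps between gene sets are scored by Fisher's exact
test and the Jaccard index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError, InvalidInputError
from .rhythm import adjust_bh

logger = logging.getLogger(__name__)


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    max_distance: int = 50_000,
    mode: str = "peak_to_gene",
) -> pd.DataFrame:
    """Flag genes bound by a peak near their TSS.

    Default ``mode="peak_to_gene"``: each peak (by its midpoint) is assigned
    to the gene with the nearest TSS on the same chromosome, provided the
    distance is within ``max_distance``; equidistant ties go to the
    lexicographically earlier gene identifier.  A gene's representative peak
    is its assigned peak of maximum score.  ``mode="gene_to_peak"`` instead
    gives each gene its nearest in-range peak.  Peaks on chromosomes absent
    from the TSS table are skipped with a logged warning.

    ``peaks`` needs columns chrom/start/end/score (0-based half-open);
    ``tss`` is indexed by gene_id with columns chrom/tss_position.
    """
    if max_distance <= 0:
        raise InvalidConfigError("max_distance must be positive")
    if mode not in ("peak_to_gene", "gene_to_peak"):
        raise InvalidConfigError(f"unknown mode {mode!r}")
    if (peaks["start"] >= peaks["end"]).any():
        raise InvalidInputError("peak intervals must satisfy start < end")

    out = pd.DataFrame(
        {
            "bound": False,
            "best_peak_score": np.nan,
            "best_peak_mid": pd.NA,
            "distance": np.nan,
        },
        index=tss.index,
    )
    missing = set(peaks["chrom"]) - set(tss["chrom"])
    if missing:
        logger.warning(
            "skipping %d peak(s) on chromosomes absent from the TSS table: %s",
            int(peaks["chrom"].isin(missing).sum()),
            sorted(missing),
        )

    for chrom, ptab in peaks.groupby("chrom"):
        ttab = tss[tss["chrom"] == chrom]
        if ttab.empty:
            continue
        # sort TSS by (position, gene_id) so equidistant ties resolve to the
        # lexicographically earlier gene deterministically
        ttab = ttab.sort_values(["tss_position"], kind="mergesort")
        pos = ttab["tss_position"].to_numpy(dtype=np.int64)
        gene_ids = ttab.index.to_numpy()
        mids = ((ptab["start"] + ptab["end"]) // 2).to_numpy(dtype=np.int64)
        scores = ptab["score"].to_numpy(dtype=float)

        if mode == "peak_to_gene":
            right = np.searchsorted(pos, mids)
            for mid, score, r in zip(mids, scores, right):
                cands = []
                if r < len(pos):
                    cands.append((abs(int(pos[r]) - int(mid)), r))
                if r > 0:
                    cands.append((abs(int(pos[r - 1]) - int(mid)), r - 1))
                dist, idx = min(cands)
                if dist > max_distance:
                    continue
                # equidistant neighbours: pick the lexicographically earlier id
                tied = [i for dd, i in cands if dd == dist]
                idx = min(tied, key=lambda i: str(gene_ids[i]))
                g = gene_ids[idx]
                prev = out.at[g, "best_peak_score"]
                if not out.at[g, "bound"] or score > prev:
                    out.at[g, "bound"] = True
                    out.at[g, "best_peak_score"] = score
                    out.at[g, "best_peak_mid"] = int(mid)
                    out.at[g, "distance"] = float(dist)
        else:  # gene_to_peak
            for g, tpos in zip(gene_ids, pos):
                dists = np.abs(mids - tpos)
                in_range = dists <= max_distance
                if not in_range.any():
                    continue
                dmin = dists[in_range].min()
                best = np.flatnonzero(in_range & (dists == dmin))
                # among equally near peaks prefer the higher score, then lower mid
                best = sorted(best, key=lambda i: (-scores[i], mids[i]))[0]
                out.at[g, "bound"] = True
                out.at[g, "best_peak_score"] = scores[best]
                out.at[g, "best_peak_mid"] = int(mids[best])
                out.at[g, "distance"] = float(dmin)
    return out


def map_homologs(gene_ids, homology: pd.DataFrame) -> tuple[set, dict]:
    """Map identifiers through a (source_id, target_id) homology table.

    One-to-many mappings are expanded; the report counts unmapped and
    multi-mapped source identifiers.
    """
    cols = list(homology.columns[:2])
    lut = homology.groupby(cols[0])[cols[1]].apply(list).to_dict()
    mapped = set()
    unmapped = 0
    multi = 0
    for g in gene_ids:
        targets = lut.get(g)
        if not targets:
            unmapped += 1
            continue
        if len(set(targets)) > 1:
            multi += 1
        mapped.update(targets)
    report = {"n_input": len(list(gene_ids)), "n_unmapped": unmapped,
              "n_multi_mapped": multi, "n_output": len(mapped)}
    return mapped, report


def build_binary_matrix(feature_sets, universe) -> pd.DataFrame:
    """Gene × feature 0/1 matrix: entry is 1 iff the gene is in the feature set.

    ``feature_sets`` is a mapping name → members, or an iterable of
    (name, members) pairs; duplicate feature names are rejected.
    """
    universe = list(dict.fromkeys(universe))
    pairs = (
        list(feature_sets.items())
        if hasattr(feature_sets, "items")
        else list(feature_sets)
    )
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise InvalidConfigError("duplicate feature names")
    uni_set = set(universe)
    data = {}
    for name, members in pairs:
        members = set(members)
        if not members <= uni_set:
            raise InvalidInputError(
                f"feature {name!r} contains genes outside the universe"
            )
        data[name] = np.fromiter((g in members for g in universe), dtype=int,
                                 count=len(universe))
    return pd.DataFrame(data, index=pd.Index(universe, name="gene_id"))


def cluster_binary(matrix: pd.DataFrame, min_cluster_size: int = 5) -> pd.Series:
    """Group genes by exact binary profile.

    Profiles observed in at least ``min_cluster_size`` genes become clusters
    numbered 1..C by descending size (ties by lexicographic profile order);
    the remainder is collected under label 0 ("unclustered").  Deterministic
    for any row order.
    """
    if matrix.empty:
        raise InvalidInputError("empty binary matrix")
    profiles = [tuple(int(v) for v in row) for row in matrix.to_numpy()]
    counts: dict = {}
    for p in profiles:
        counts[p] = counts.get(p, 0) + 1
    keep = [p for p, c in counts.items() if c >= min_cluster_size]
    keep.sort(key=lambda p: (-counts[p], p))
    label_of = {p: i + 1 for i, p in enumerate(keep)}
    labels = [label_of.get(p, 0) for p in profiles]
    return pd.Series(labels, index=matrix.index, name="cluster")


@dataclass
class OverlapResult:
    """Fisher/Jaccard overlap between two gene sets over a universe."""

    n_a: int
    n_b: int
    n_overlap: int
    n_union: int
    universe_size: int
    odds_ratio: float
    p_value: float
    jaccard: float
    fdr: float = np.nan


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """Fisher's exact test (greater) plus Jaccard index for two gene sets."""
    universe = set(universe)
    if not universe:
        raise InvalidInputError("empty universe")
    a = set(set_a)
    b = set(set_b)
    if not (a <= universe and b <= universe):
        raise InvalidInputError("sets must be subsets of the universe")
    inter = len(a & b)
    union = len(a | b)
    table = np.array(
        [
            [inter, len(a) - inter],
            [len(b) - inter, len(universe) - union],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="greater")
    jac = inter / union if union else 0.0
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_overlap=inter,
        n_union=union,
        universe_size=len(universe),
        odds_ratio=float(odds),
        p_value=float(p),
        jaccard=jac,
    )


def overlap_tests(pairs: dict, universe) -> pd.DataFrame:
    """Batch of overlap tests with BH adjustment across the batch.

    ``pairs`` maps a comparison name to a (set_a, set_b) tuple.
    """
    rows = {}
    for name, (a, b) in pairs.items():
        rows[name] = overlap_test(a, b, universe)
    df = pd.DataFrame(
        {
            "comparison": list(rows),
            "n_a": [r.n_a for r in rows.values()],
            "n_b": [r.n_b for r in rows.values()],
            "n_overlap": [r.n_overlap for r in rows.values()],
            "odds_ratio": [r.odds_ratio for r in rows.values()],
            "p_value": [r.p_value for r in rows.values()],
            "jaccard": [r.jaccard for r in rows.values()],
        }
    )
    df["fdr"] = adjust_bh(df["p_value"].to_numpy()) if len(df) else []
    return df
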