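"""Transcription-factor target enrichment among rhythmic genes.

Given a TF→target edge table (interaction sign deliberately dropped), each
TF's target set is tested for over-representation of rhythmic genes by a
one-sided Fisher test over the expression universe, separately per
condition group; TFs with zero rhythmic targets are excluded before
testing, and BH adjustment is applied within each group's table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .enrichment import ora_fisher
from .errors import InvalidInputError
from .rhythm import adjust_bh

logger = logging.getLogger(__name__)


def dedupe_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate (tf, target) pairs; flag (not drop) self-edges."""
    cols = list(edges.columns[:2])
    out = edges[cols].drop_duplicates().reset_index(drop=True)
    out.columns = ["tf_id", "target_id"]
    n_self = int((out["tf_id"] == out["target_id"]).sum())
    if n_self:
        logger.warning("edge table contains %d self-edge(s); retained", n_self)
    return out


def tf_enrichment(
    edges: pd.DataFrame,
    rhythmic_by_group: dict,
    universe,
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-TF Fisher enrichment of rhythmic genes among its targets.

    ``rhythmic_by_group`` maps a group label to its rhythmic gene set; BH is
    applied within each group independently.  Edges with targets outside
    the universe are ignored; TFs without any rhythmic target are excluded.
    """
    universe = list(dict.fromkeys(universe))
    uni_set = set(universe)
    if edges.empty:
        return pd.DataFrame(
            columns=["group", "tf_id", "overlap", "n_targets",
                     "odds_ratio", "p_value", "fdr", "significant"]
        )
    edges = dedupe_edges(edges)
    edges = edges[edges["target_id"].isin(uni_set)]
    targets_of = edges.groupby("tf_id")["target_id"].apply(set).to_dict()

    frames = []
    for group, rhythmic in rhythmic_by_group.items():
        rhythmic = set(rhythmic)
        if not rhythmic <= uni_set:
            raise InvalidInputError(
                f"rhythmic set for group {group!r} not contained in the universe"
            )
        rows = []
        for tf, targets in sorted(targets_of.items()):
            overlap = targets & rhythmic
            if not overlap:  # zero-overlap TFs excluded before testing
                continue
            r = ora_fisher(rhythmic, targets, universe, alternative="greater")
            rows.append(
                {
                    "group": group,
                    "tf_id": tf,
                    "overlap": r["overlap"],
                    "n_targets": r["set_size"],
                    "odds_ratio": r["odds_ratio"],
                    "p_value": r["p_value"],
                }
            )
        df = pd.DataFrame(rows)
        if len(df):
            df["fdr"] = adjust_bh(df["p_value"].to_numpy())
            df["significant"] = df["fdr"] < fdr_threshold
        frames.append(df)
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(
            columns=["group", "tf_id", "overlap", "n_targets",
                     "odds_ratio", "p_value", "fdr", "significant"]
        )
    return pd.concat(frames, ignore_index=True)


def build_tf_gene_graph(
    enriched: pd.DataFrame,
    edges: pd.DataFrame,
    rhythmic_by_group: dict,
) -> pd.DataFrame:
    """Edge list (tf, gene, group) from enriched TFs to their rhythmic targets.

    A target rhythmic in several groups yields one annotated edge per group
    in which its TF is enriched; node degrees therefore equal the per-group
    overlap counts of :func:`tf_enrichment`.
    """
    if enriched.empty:
        return pd.DataFrame(columns=["tf_id", "gene_id", "group"])
    edges = dedupe_edges(edges)
    targets_of = edges.groupby("tf_id")["target_id"].apply(set).to_dict()
    known_tfs = set(targets_of)
    bad = set(enriched["tf_id"]) - known_tfs
    if bad:
        raise InvalidInputError(f"enriched TFs absent from the edge table: {sorted(bad)}")
    rows = []
    for r in enriched.itertuples(index=False):
        rhythmic = set(rhythmic_by_group.get(r.group, ()))
        for gene in sorted(targets_of[r.tf_id] & rhythmic):
            rows.append((r.tf_id, gene, r.group))
    return pd.DataFrame(rows, columns=["tf_id", "gene_id", "group"])
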