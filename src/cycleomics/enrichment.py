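"""Over-representation analysis and trait correlation.

ORA tests whether a significant gene list overlaps a curated gene set more
than expected under hypergeometric sampling from a declared background
universe.  Collections are ranked by *gene ratio* — the fraction of
significant genes in a set relative to all significant genes belonging to
any set of the collection — after BH adjustment across the collection.

Trait correlation computes per-gene Spearman rank correlations between
basal expression and a per-subject clinical trait (e.g. the M value from a
hyperinsulinemic-euglycemic clamp), with exact permutation p-values for
small cohorts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTraitError, InvalidInputError
from .rhythm import adjust_bh


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit background universe.

    Sets are intersected with the universe at construction; sets that become
    empty are dropped.  Duplicate identifiers inside a set are removed (the
    count is recorded in ``n_duplicates_removed``).
    """

    sets: dict
    universe: list
    n_duplicates_removed: int = field(default=0)

    def __post_init__(self):
        uni = list(dict.fromkeys(self.universe))
        if len(uni) != len(self.universe):
            raise InvalidInputError("universe contains duplicate gene identifiers")
        uni_set = set(uni)
        cleaned = {}
        dups = 0
        for name, members in self.sets.items():
            members = list(members)
            dedup = list(dict.fromkeys(members))
            dups += len(members) - len(dedup)
            kept = [g for g in dedup if g in uni_set]
            if kept:
                cleaned[name] = kept
        self.sets = cleaned
        self.universe = uni
        self.n_duplicates_removed = dups


def ora_fisher(
    significant,
    gene_set,
    universe,
    alternative: str = "greater",
) -> dict:
    """Fisher/hypergeometric over-representation test for one gene set.

    The 2×2 table is a = |set ∩ sig|, b = |set \\ sig|, c = |sig \\ set|,
    d = remainder of the universe.  Returns a dict with the counts, the
    hypergeometric p-value (upper tail for ``greater``; probability-mass
    two-sided otherwise) and the sample odds ratio a·d/(b·c) (infinite when
    b·c = 0 and a·d > 0).
    """
    universe = set(universe)
    significant = set(significant)
    if not significant <= universe:
        offenders = sorted(significant - universe)[:10]
        raise InvalidInputError(
            f"significant genes outside the universe, e.g. {offenders}"
        )
    gene_set = set(gene_set) & universe
    if alternative not in ("greater", "two-sided"):
        raise InvalidInputError(f"unknown alternative {alternative!r}")

    a = len(gene_set & significant)
    b = len(gene_set) - a
    c = len(significant) - a
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    p = float(stats.fisher_exact(table, alternative=alternative)[1])
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = a * d / (b * c)
    return {
        "overlap": a,
        "set_size": a + b,
        "list_size": a + c,
        "universe_size": len(universe),
        "p_value": p,
        "odds_ratio": odds,
        "members": sorted(gene_set & significant),
    }


def enrich_collection(
    significant,
    collection: GeneSetCollection,
    fdr_threshold: float = 0.10,
    top_k: int | None = 10,
    alternative: str = "greater",
) -> pd.DataFrame:
    """ORA across a collection, BH-adjusted, ranked by gene ratio.

    Rows with fdr < ``fdr_threshold`` are sorted by gene ratio descending
    (ties by p ascending, then set name) and truncated to ``top_k``.
    """
    if not collection.sets:
        return pd.DataFrame(
            columns=[
                "set_name", "overlap", "set_size", "list_size",
                "universe_size", "gene_ratio", "p_value", "fdr",
                "odds_ratio", "members",
            ]
        )
    significant = set(significant)
    in_any_set = significant & set().union(*collection.sets.values())
    denom = max(len(in_any_set), 1)
    rows = []
    for name, members in collection.sets.items():
        r = ora_fisher(significant, members, collection.universe, alternative)
        r["set_name"] = name
        r["gene_ratio"] = r["overlap"] / denom
        rows.append(r)
    df = pd.DataFrame(rows)
    df["fdr"] = adjust_bh(df["p_value"].to_numpy())
    df = df[df["fdr"] < fdr_threshold]
    df = df.sort_values(
        by=["gene_ratio", "p_value", "set_name"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    cols = [
        "set_name", "overlap", "set_size", "list_size", "universe_size",
        "gene_ratio", "p_value", "fdr", "odds_ratio", "members",
    ]
    return df[cols]


# ---------------------------------------------------------------------------
# Spearman correlation with a clinical trait


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=-1)


def _pearson_rows(R: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of R (G×n) against a vector (n,)."""
    Rc = R - R.mean(axis=-1, keepdims=True)
    sc = s - s.mean()
    denom = np.sqrt((Rc**2).sum(axis=-1) * (sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Rc @ sc) / denom


def correlate_with_trait(
    basal_expression: pd.DataFrame,
    trait: pd.Series,
    exact_max_n: int = 9,
) -> pd.DataFrame:
    """Per-gene Spearman correlation of expression with a per-subject trait.

    Ties receive average ranks.  For n <= ``exact_max_n`` subjects the
    p-value is computed from the exhaustive permutation distribution of the
    trait ranks (two-sided); larger cohorts use the t approximation.  BH is
    applied across genes.
    """
    subjects = basal_expression.columns
    trait = trait.reindex(subjects)
    if trait.isna().any() or not np.all(np.isfinite(trait.to_numpy(float))):
        raise InvalidInputError("trait missing or non-finite for some subjects")
    n = len(subjects)
    if n < 4:
        raise InvalidInputError("need >= 4 subjects")
    tvec = trait.to_numpy(dtype=float)
    if np.all(tvec == tvec[0]):
        raise DegenerateTraitError("trait is constant across subjects")

    X = basal_expression.to_numpy(dtype=float)
    Rg = _rank(X)
    rt = _rank(tvec)
    rho = _pearson_rows(Rg, rt)

    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        rt_perm = rt[perms]  # (n!, n)
        # correlation of each gene's ranks against every permuted trait ranking
        Rc = Rg - Rg.mean(axis=1, keepdims=True)
        Pc = rt_perm - rt_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt((Rc**2).sum(axis=1)[:, None] * (Pc**2).sum(axis=1)[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_perm = (Rc @ Pc.T) / denom
        eps = 1e-12
        p = (np.abs(rho_perm) >= np.abs(rho)[:, None] - eps).mean(axis=1)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        p = np.where(np.isnan(p), 1.0, np.minimum(p, 1.0))

    rho = np.where(np.isnan(rho), 0.0, rho)
    return pd.DataFrame(
        {
            "gene_id": basal_expression.index,
            "rho": rho,
            "p_value": p,
            "fdr": adjust_bh(p),
        }
    )
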