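"""Expression matrix preparation: filtering, log-CPM, batch removal, centering.

The rhythm statistics downstream assume log2 CPM values with the participant
batch effect removed; these operations reproduce that preparation.  Library
sizes are computed on the unfiltered count matrix and frozen on the container
so that gene filtering never changes CPM denominators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import SCALE_COUNTS, SCALE_LOGCPM, TimecourseMatrix
from .errors import (
    ConfoundingError,
    InvalidInputError,
    WrongScaleError,
    ZeroVarianceError,
)


def _require_scale(tc: TimecourseMatrix, scale: str, op: str):
    if tc.scale != scale:
        raise WrongScaleError(f"{op} requires a matrix on the {scale} scale, got {tc.scale}")


def filter_low_expression(
    counts: TimecourseMatrix,
    min_count: int = 10,
    min_samples: int | None = None,
    min_total: int = 15,
) -> TimecourseMatrix:
    """Drop lowly expressed genes from a count matrix.

    A gene is retained when it has raw count >= ``min_count`` in at least
    ``min_samples`` samples *and* a total count >= ``min_total``.
    ``min_samples`` defaults to the size of the smallest (group, treatment)
    cell, so a gene expressed in one full condition always survives.
    Library sizes are frozen from the unfiltered matrix.
    """
    _require_scale(counts, SCALE_COUNTS, "filter_low_expression")
    if min_count < 0 or min_total < 0 or (min_samples is not None and min_samples < 0):
        raise InvalidInputError("filter thresholds must be >= 0")
    if min_samples is None:
        cell_sizes = counts.samples.groupby(["group", "treatment"], observed=True).size()
        min_samples = int(cell_sizes.min())
    vals = counts.values.to_numpy()
    keep = ((vals >= min_count).sum(axis=1) >= min_samples) & (
        vals.sum(axis=1) >= min_total
    )
    lib = counts.lib_sizes
    if lib is None:
        lib = counts.values.sum(axis=0)
    return TimecourseMatrix(
        values=counts.values.loc[keep],
        samples=counts.samples,
        scale=SCALE_COUNTS,
        lib_sizes=lib,
    )


def log_cpm(counts: TimecourseMatrix, prior_count: float = 0.5) -> TimecourseMatrix:
    """log2 counts-per-million with a prior count.

    value = log2((count + prior) / (lib_size + 2*prior) * 1e6).  Library
    sizes frozen on the container (pre-filtering) are used when present.
    """
    _require_scale(counts, SCALE_COUNTS, "log_cpm")
    vals = counts.values.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise InvalidInputError("negative counts")
    lib = counts.lib_sizes
    if lib is None:
        lib = counts.values.sum(axis=0)
    lib_arr = lib.to_numpy(dtype=float)
    if np.any(lib_arr <= 0):
        raise InvalidInputError("non-positive library sizes")
    out = np.log2((vals + prior_count) / (lib_arr + 2.0 * prior_count) * 1e6)
    return TimecourseMatrix(
        values=pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns),
        samples=counts.samples,
        scale=SCALE_LOGCPM,
        lib_sizes=lib,
    )


def _protected_design(samples: pd.DataFrame, protected) -> tuple[np.ndarray, list, pd.Series]:
    """Full-rank protected design matrix plus the protection-cell labels.

    The default design is the group × treatment interaction crossed with
    time as a categorical factor — it spans every condition-time mean the
    rhythm tests rely on.
    """
    if protected is None:
        cells = pd.Series("all", index=samples.index)
        cols = np.ones((len(samples), 1))
        names = ["intercept"]
        return cols, names, cells
    cells = samples["group"].astype(str) + ":" + samples["treatment"].astype(str)
    cell_d = pd.get_dummies(cells, dtype=float)
    time_d = pd.get_dummies(samples["time"].astype(float), drop_first=True, dtype=float, prefix="time")
    design = pd.concat([cell_d, time_d], axis=1)
    return design.to_numpy(), list(design.columns), cells


def remove_batch(
    logcpm: TimecourseMatrix,
    batch: pd.Series | None = None,
    protected: str | None = "design",
) -> TimecourseMatrix:
    """Subtract per-batch (participant) offsets estimated by OLS.

    Per gene, expression is regressed on the protected design covariates
    plus sum-to-zero batch contrasts and the fitted batch component is
    subtracted.  When batches are nested inside the protection cells (the
    usual case: subjects nested in group × treatment), the contrasts are
    built within each cell, which keeps every protected cell mean exactly
    unchanged on balanced designs.  Genuine collinearity between batch and
    protected covariates raises :class:`ConfoundingError`.
    """
    _require_scale(logcpm, SCALE_LOGCPM, "remove_batch")
    if batch is None:
        batch = logcpm.samples["subject"]
    batch = batch.reindex(logcpm.samples.index)
    if batch.isna().any():
        raise InvalidInputError("missing batch label for some samples")

    P, p_names, cells = _protected_design(logcpm.samples, protected)

    # one batch level overall -> nothing to remove
    if batch.nunique() <= 1:
        return TimecourseMatrix(
            values=logcpm.values.copy(),
            samples=logcpm.samples,
            scale=SCALE_LOGCPM,
            lib_sizes=logcpm.lib_sizes,
        )

    # find the finest protection level in which batches are nested: the
    # group × treatment cells, the clinical group alone, or nothing.  In the
    # study design subjects belong to one group but cross treatment arms.
    candidates = [cells]
    if protected is not None:
        candidates.append(logcpm.samples["group"].astype(str))
    candidates.append(pd.Series("all", index=logcpm.samples.index))
    nest = None
    for cand in candidates:
        if (pd.crosstab(batch, cand) > 0).sum(axis=1).eq(1).all():
            nest = cand
            break

    b_cols = []
    b_names = []
    for nest_label in sorted(nest.unique()):
        in_nest = (nest == nest_label).to_numpy()
        levels = sorted(batch[in_nest].unique())
        for lev in levels[:-1]:
            col = np.where(batch == lev, 1.0, 0.0) - np.where(
                batch == levels[-1], 1.0, 0.0
            )
            col[~in_nest] = 0.0
            b_cols.append(col)
            b_names.append(f"batch[{lev}-{levels[-1]}]")

    if not b_cols:
        return TimecourseMatrix(
            values=logcpm.values.copy(),
            samples=logcpm.samples,
            scale=SCALE_LOGCPM,
            lib_sizes=logcpm.lib_sizes,
        )

    B = np.column_stack(b_cols)
    D = np.column_stack([P, B])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify collinear columns by incremental rank growth
        bad = []
        r = 0
        for j in range(D.shape[1]):
            new_r = np.linalg.matrix_rank(D[:, : j + 1])
            if new_r == r:
                bad.append((p_names + b_names)[j])
            r = new_r
        raise ConfoundingError(
            f"batch is confounded with protected covariates: {bad}", columns=bad
        )

    Y = logcpm.values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(D, Y.T, rcond=None)
    batch_coef = coef[P.shape[1]:, :]
    corrected = Y - (B @ batch_coef).T
    return TimecourseMatrix(
        values=pd.DataFrame(
            corrected, index=logcpm.values.index, columns=logcpm.values.columns
        ),
        samples=logcpm.samples,
        scale=SCALE_LOGCPM,
        lib_sizes=logcpm.lib_sizes,
    )


def center_by_group(
    matrix: TimecourseMatrix,
    mode: str = "mean",
    group_cols: tuple = ("group", "treatment"),
) -> TimecourseMatrix:
    """Mean-center (or z-score) each gene within each condition group.

    ``mode`` is ``"mean"`` or ``"zscore"``.  z-scoring a gene that is
    constant within some group raises :class:`ZeroVarianceError` naming the
    offending genes.
    """
    _require_scale(matrix, SCALE_LOGCPM, "center_by_group")
    if mode not in ("mean", "zscore"):
        raise InvalidInputError(f"unknown centering mode {mode!r}")
    vals = matrix.values.to_numpy(dtype=float).copy()
    labels = matrix.samples[list(group_cols)].apply(tuple, axis=1)
    bad_genes: set = set()
    for _, idx in labels.groupby(labels).groups.items():
        cols = matrix.values.columns.get_indexer(idx)
        block = vals[:, cols]
        block = block - block.mean(axis=1, keepdims=True)
        if mode == "zscore":
            sd = block.std(axis=1, ddof=1, keepdims=True)
            zero = sd[:, 0] == 0
            if zero.any():
                bad_genes.update(matrix.values.index[zero])
                sd[zero] = 1.0
            block = block / sd
        vals[:, cols] = block
    if bad_genes and mode == "zscore":
        raise ZeroVarianceError(
            f"{len(bad_genes)} gene(s) constant within a group", genes=sorted(bad_genes)
        )
    return TimecourseMatrix(
        values=pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns),
        samples=matrix.samples,
        scale=SCALE_LOGCPM,
        lib_sizes=matrix.lib_sizes,
    )
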