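"""Core in-memory containers for grouped circadian time-course data.

The central object is :class:`TimecourseMatrix`: a gene × sample expression
matrix together with per-sample metadata (subject, clinical group, treatment
arm, hours after synchronization).  Matrices carry a ``scale`` flag so that
operations that only make sense on raw counts (library-size normalisation)
or on log2 counts-per-million (rhythm statistics) can refuse the wrong input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

SCALE_COUNTS = "counts"
SCALE_LOGCPM = "logcpm"

#: required columns of the sample metadata table
SAMPLE_COLUMNS = ("subject", "group", "treatment", "time")


@dataclass
class TimecourseMatrix:
    """Gene × sample expression with time-course metadata.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_samples); index are gene identifiers,
        columns are sample identifiers matching ``samples.index``.
    samples
        DataFrame indexed by sample identifier with columns
        ``subject``, ``group``, ``treatment`` and ``time`` (hours).
    scale
        ``"counts"`` for raw counts, ``"logcpm"`` for log2 CPM values.
    lib_sizes
        Optional per-sample library sizes.  Frozen at construction so that
        gene filtering does not change CPM denominators downstream.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = SCALE_COUNTS
    lib_sizes: pd.Series | None = field(default=None)

    def __post_init__(self):
        if self.scale not in (SCALE_COUNTS, SCALE_LOGCPM):
            raise InvalidInputError(f"unknown scale {self.scale!r}")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise InvalidInputError(f"sample metadata missing columns: {missing}")
        if list(self.values.columns) != list(self.samples.index):
            raise InvalidInputError("values columns do not match sample metadata index")
        if self.values.index.has_duplicates:
            raise InvalidInputError("duplicate gene identifiers")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("non-finite expression values")
        key = self.samples[["subject", "treatment", "time"]].apply(tuple, axis=1)
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise InvalidInputError(
                f"duplicate (subject, treatment, time) triple: {dup}"
            )
        if self.lib_sizes is not None:
            self.lib_sizes = self.lib_sizes.reindex(self.values.columns)
            if self.lib_sizes.isna().any():
                raise InvalidInputError("lib_sizes missing for some samples")

    # -- convenience accessors -------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def condition_mask(self, group=None, treatment=None) -> np.ndarray:
        """Boolean sample mask for a clinical group and/or treatment arm."""
        mask = np.ones(self.n_samples, dtype=bool)
        if group is not None:
            mask &= (self.samples["group"] == group).to_numpy()
        if treatment is not None:
            mask &= (self.samples["treatment"] == treatment).to_numpy()
        return mask

    def subset_samples(self, mask) -> "TimecourseMatrix":
        """Return a new matrix restricted to the samples selected by ``mask``."""
        cols = self.values.columns[np.asarray(mask)]
        return TimecourseMatrix(
            values=self.values[cols],
            samples=self.samples.loc[cols],
            scale=self.scale,
            lib_sizes=None if self.lib_sizes is None else self.lib_sizes[cols],
        )

    def subset_genes(self, genes) -> "TimecourseMatrix":
        return TimecourseMatrix(
            values=self.values.loc[genes],
            samples=self.samples,
            scale=self.scale,
            lib_sizes=self.lib_sizes,
        )

    def conditions(self):
        """Iterate over observed (group, treatment) pairs in sorted order."""
        pairs = (
            self.samples[["group", "treatment"]]
            .drop_duplicates()
            .sort_values(["group", "treatment"])
        )
        return [tuple(r) for r in pairs.itertuples(index=False)]
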