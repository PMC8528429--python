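"""Harmonic regression with trend and the amplitude algebra.

A gene's log2-scale series is fit by least squares to

    y(t) = a*cos(2*pi*t/T) + b*sin(2*pi*t/T) + c + d*t,

giving the absolute log2 amplitude A_log = sqrt(a^2 + b^2) and the peak
phase.  Because the data are on the log2 scale, the natural-scale
fold-change amplitude (peak/trough ratio) is A_fc = 2^(2*A_log), and the
dimensionless relative amplitude — (peak − trough)/(peak + trough), the
quantity comparable across conditions and experiments — follows as

    A_rel = (A_fc − 1)/(A_fc + 1) = (2^(2*A_log) − 1)/(2^(2*A_log) + 1).

Group comparisons use per-gene log2 ratios of relative amplitudes, a
Kolmogorov-Smirnov test of the ratio distribution (rhythmic vs
non-rhythmic genes) and a paired Wilcoxon test of relative amplitudes
across groups.  Detrending subtracts the OLS straight line through the
fitted curve, for heatmap display of oscillatory patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import TimecourseMatrix
from .errors import InsufficientDesignError, InvalidConfigError, InvalidInputError


def arel_from_alog(a_log):
    """Relative amplitude from the absolute log2 amplitude."""
    a_log = np.asarray(a_log, dtype=float)
    if np.any(a_log < 0):
        raise InvalidInputError("A_log must be >= 0")
    x = np.exp2(2.0 * a_log)
    out = (x - 1.0) / (x + 1.0)
    return out if out.ndim else float(out)


def afc_from_alog(a_log):
    """Fold-change (peak/trough) amplitude from the log2 amplitude."""
    a_log = np.asarray(a_log, dtype=float)
    out = np.exp2(2.0 * a_log)
    return out if out.ndim else float(out)


def alog_from_arel(a_rel):
    """Inverse of :func:`arel_from_alog`."""
    a_rel = np.asarray(a_rel, dtype=float)
    if np.any(a_rel < 0) or np.any(a_rel >= 1):
        raise InvalidInputError("A_rel must lie in [0, 1)")
    out = 0.5 * np.log2((1.0 + a_rel) / (1.0 - a_rel))
    return out if out.ndim else float(out)


@dataclass
class HarmonicFit:
    """Cosinor-with-trend coefficients and derived amplitudes for one series."""

    a: float
    b: float
    c: float
    d: float
    period: float

    @property
    def a_log(self) -> float:
        return float(np.hypot(self.a, self.b))

    @property
    def a_fc(self) -> float:
        return afc_from_alog(self.a_log)

    @property
    def a_rel(self) -> float:
        return arel_from_alog(self.a_log)

    @property
    def phase(self) -> float:
        ph = float(np.mod(self.period / (2 * np.pi) * np.arctan2(self.b, self.a), self.period))
        return 0.0 if ph >= self.period else ph  # mod of -eps can round to T

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        w = 2.0 * np.pi * t / self.period
        return self.a * np.cos(w) + self.b * np.sin(w) + self.c + self.d * t


def fit_harmonic(values, times, period: float = 24.0, trend_degree: int = 1) -> HarmonicFit:
    """Least-squares cosinor fit with optional linear trend (one series)."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if period <= 0:
        raise InvalidInputError("period must be positive")
    if trend_degree not in (0, 1):
        raise InvalidInputError("trend_degree must be 0 or 1")
    if len(np.unique(t)) < (4 if trend_degree else 3):
        raise InsufficientDesignError("need >= 4 distinct times for a trended fit")
    w = 2.0 * np.pi * t / period
    cols = [np.cos(w), np.sin(w), np.ones_like(t)]
    if trend_degree == 1:
        cols.append(t)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InsufficientDesignError("rank-deficient harmonic design")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c = coef[0], coef[1], coef[2]
    d = coef[3] if trend_degree == 1 else 0.0
    return HarmonicFit(a=float(a), b=float(b), c=float(c), d=float(d), period=period)


def fit_harmonic_matrix(
    X, times, period: float = 24.0, trend_degree: int = 1
) -> pd.DataFrame:
    """Row-wise cosinor fits; returns a DataFrame of coefficients and amplitudes."""
    Xm = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(times, dtype=float)
    w = 2.0 * np.pi * t / period
    cols = [np.cos(w), np.sin(w), np.ones_like(t)]
    if trend_degree == 1:
        cols.append(t)
    D = np.column_stack(cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise InsufficientDesignError("rank-deficient harmonic design")
    coef, *_ = np.linalg.lstsq(D, Xm.T, rcond=None)
    a, b, c = coef[0], coef[1], coef[2]
    d = coef[3] if trend_degree == 1 else np.zeros_like(a)
    a_log = np.hypot(a, b)
    phase = np.mod(period / (2 * np.pi) * np.arctan2(b, a), period)
    phase[phase >= period] = 0.0  # mod of -eps can round to the period
    return pd.DataFrame(
        {
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "a_log": a_log,
            "a_fc": afc_from_alog(a_log),
            "a_rel": arel_from_alog(a_log),
            "phase": phase,
            "period": period,
        }
    )


def harmonic_fits(
    tc: TimecourseMatrix, period: float = 24.0, trend_degree: int = 1
) -> pd.DataFrame:
    """Per-gene cosinor fits for every (group, treatment) condition."""
    frames = []
    for (group, treatment) in tc.conditions():
        sub = tc.subset_samples(tc.condition_mask(group, treatment))
        fit = fit_harmonic_matrix(
            sub.values.to_numpy(), sub.samples["time"].to_numpy(), period, trend_degree
        )
        fit.insert(0, "gene_id", sub.gene_ids.to_numpy())
        fit.insert(1, "group", group)
        fit.insert(2, "treatment", treatment)
        frames.append(fit)
    return pd.concat(frames, ignore_index=True)


def detrend_fit(fit: HarmonicFit, times) -> np.ndarray:
    """Fitted values with the OLS straight line through them removed.

    E'(t) = E(t) − (alpha + beta*t), so the post-detrend OLS slope is zero.
    """
    t = np.asarray(times, dtype=float)
    e = fit.predict(t)
    A = np.column_stack([np.ones_like(t), t])
    ab, *_ = np.linalg.lstsq(A, e, rcond=None)
    return e - (A @ ab)


def detrended_matrix(fits: pd.DataFrame, times) -> np.ndarray:
    """Detrended fitted curves for a table of fits (rows) at given times."""
    t = np.asarray(times, dtype=float)
    out = np.empty((len(fits), len(t)))
    for i, row in enumerate(fits.itertuples(index=False)):
        hf = HarmonicFit(a=row.a, b=row.b, c=row.c, d=row.d, period=row.period)
        out[i] = detrend_fit(hf, t)
    return out


@dataclass
class AmplitudeComparison:
    """Cohort-level amplitude contrasts between two groups."""

    per_gene: pd.DataFrame  # gene_id, a_rel per group, log2_arel_ratio, circadian flag
    ks_statistic: float
    ks_p: float
    wilcoxon_statistic: float
    wilcoxon_p: float
    mean_ratio_circadian: float
    mean_ratio_noncircadian: float
    n_excluded_zero_amplitude: int


def _paired_wilcoxon(x, y, exact_max: int = 25):
    """Paired Wilcoxon signed-rank test; exact for n <= 25 without ties/zeros."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    use_exact = d.size <= exact_max and len(np.unique(np.abs(d))) == d.size
    res = stats.wilcoxon(
        x, y, zero_method="wilcox",
        method="exact" if use_exact else "approx",
        correction=not use_exact,
    )
    return float(res.statistic), float(res.pvalue)


def amplitude_ratio(
    fits_ref: pd.DataFrame,
    fits_alt: pd.DataFrame,
    circadian_genes,
    min_arel: float = 0.0,
) -> AmplitudeComparison:
    """Per-gene log2 relative-amplitude ratios alt/ref and cohort tests.

    ``fits_ref``/``fits_alt`` are per-gene fit tables (same gene order) for
    the reference (e.g. NGT) and alternate (e.g. T2D) groups.  Genes with a
    zero amplitude in either group are excluded from the ratio (counted, not
    fatal).  The KS test contrasts the ratio distribution of circadian vs
    non-circadian genes; the paired Wilcoxon compares A_rel across groups on
    the circadian set.
    """
    ref = fits_ref.set_index("gene_id")
    alt = fits_alt.set_index("gene_id")
    genes = ref.index.intersection(alt.index)
    ar = ref.loc[genes, "a_rel"].to_numpy()
    aa = alt.loc[genes, "a_rel"].to_numpy()
    ok = (ar > min_arel) & (aa > min_arel)
    n_excluded = int((~ok).sum())
    ratio = np.full(len(genes), np.nan)
    ratio[ok] = np.log2(aa[ok] / ar[ok])
    circ = genes.isin(set(circadian_genes))

    per_gene = pd.DataFrame(
        {
            "gene_id": genes,
            "a_rel_ref": ar,
            "a_rel_alt": aa,
            "log2_arel_ratio": ratio,
            "circadian": circ,
        }
    )

    rc = ratio[circ & ok]
    rn = ratio[~circ & ok]
    if rc.size and rn.size:
        ks = stats.ks_2samp(rc, rn, alternative="two-sided")
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = np.nan, np.nan
    keep = circ & ok
    if keep.sum() >= 2 and np.any(ar[keep] != aa[keep]):
        w_stat, w_p = _paired_wilcoxon(aa[keep], ar[keep])
    elif keep.sum() >= 1:
        w_stat, w_p = 0.0, 1.0
    else:
        w_stat, w_p = np.nan, np.nan
    return AmplitudeComparison(
        per_gene=per_gene,
        ks_statistic=ks_stat,
        ks_p=ks_p,
        wilcoxon_statistic=w_stat,
        wilcoxon_p=w_p,
        mean_ratio_circadian=float(np.mean(rc)) if rc.size else np.nan,
        mean_ratio_noncircadian=float(np.mean(rn)) if rn.size else np.nan,
        n_excluded_zero_amplitude=n_excluded,
    )


def circular_phase_distance(phases, period: float = 24.0) -> np.ndarray:
    """Pairwise geodesic (shorter-arc) distance matrix between peak phases."""
    p = np.asarray(phases, dtype=float)
    diff = np.abs(p[:, None] - p[None, :])
    return np.minimum(diff, period - diff)


def cluster_by_phase(phases, period: float = 24.0, k: int = 2) -> np.ndarray:
    """Ward-linkage hierarchical clustering on the circular phase metric.

    Returns integer labels 1..k; deterministic for a given input order.
    """
    p = np.asarray(phases, dtype=float)
    if k < 1 or k > len(p):
        raise InvalidConfigError("k must satisfy 1 <= k <= n")
    if len(p) == 1 or k == len(p):
        return np.arange(1, len(p) + 1) if k == len(p) else np.ones(1, dtype=int)
    D = circular_phase_distance(p, period)
    Z = linkage(squareform(D, checks=False), method="ward")
    return fcluster(Z, t=k, criterion="maxclust")
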