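"""Synthetic cohorts with known circadian ground truth.

The generator emulates a serum-shock time-course study in primary myotube
cultures: two clinical groups of donors (7 NGT-like, 5 T2D-like), two
treatment arms (control and a high glucose/insulin challenge), harvests every
6 hours from 12 to 54 hours after synchronization, and expression measured on
the log2 scale.  A configurable fraction of genes oscillates with a 24-hour
cosinor signal superimposed on a per-gene linear trend, per-subject additive
offsets (the participant "batch" effect) and i.i.d. Gaussian noise.  The
second group's amplitudes are attenuated multiplicatively, reproducing the
direction of reduced oscillation size in the disease-like group; the
challenge arm is attenuated likewise.

Every generator is fully determined by its seed, and each simulation returns
a :class:`SimTruth` table recording the planted rhythmicity flag, amplitudes,
phase, mesor and trend slope per gene — the oracle against which detection
and estimation are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import SCALE_COUNTS, SCALE_LOGCPM, TimecourseMatrix
from .errors import InvalidConfigError

DEFAULT_TIMEPOINTS = (12.0, 18.0, 24.0, 30.0, 36.0, 42.0, 48.0, 54.0)

#: library size used by the raw-count variant (reads per sample)
DEFAULT_LIB_SIZE = 20_000_000


@dataclass
class SimConfig:
    """Parameters of the time-course generator.

    Dispersions are in log2 units; times in hours.  ``amplitude_attenuation``
    multiplies the amplitudes of every group after the first (and of every
    treatment after the first when several arms are simulated).
    """

    n_genes: int = 2000
    frac_rhythmic: float = 0.5
    n_subjects_per_group: dict = field(
        default_factory=lambda: {"NGT": 7, "T2D": 5}
    )
    treatments: tuple = ("control", "HGI")
    timepoints: tuple = DEFAULT_TIMEPOINTS
    period: float = 24.0
    amplitude_range: tuple = (0.5, 1.0)
    amplitude_attenuation: float = 0.5
    treatment_attenuation: float = 0.5
    trend_slope_sd: float = 0.01
    subject_effect_sd: float = 0.5
    noise_sd: float = 0.3
    mesor_range: tuple = (3.0, 10.0)
    output_scale: str = SCALE_LOGCPM
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise InvalidConfigError("n_genes must be positive")
        if not 0.0 <= self.frac_rhythmic <= 1.0:
            raise InvalidConfigError("frac_rhythmic must lie in [0, 1]")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size < 2 or np.any(np.diff(tp) <= 0):
            raise InvalidConfigError("timepoints must be strictly increasing")
        for name in ("trend_slope_sd", "subject_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.amplitude_attenuation < 0 or self.treatment_attenuation < 0:
            raise InvalidConfigError("attenuation factors must be >= 0")
        if self.period <= 0:
            raise InvalidConfigError("period must be positive")
        lo, hi = self.amplitude_range
        if lo < 0 or hi < lo:
            raise InvalidConfigError("amplitude_range must be 0 <= lo <= hi")
        if not all(n > 0 for n in self.n_subjects_per_group.values()):
            raise InvalidConfigError("subject counts must be positive")
        if self.output_scale not in (SCALE_COUNTS, SCALE_LOGCPM):
            raise InvalidConfigError("output_scale must be counts or logcpm")


@dataclass
class SimTruth:
    """Planted ground truth, one row per gene.

    Columns: ``is_rhythmic``, ``phase`` (peak hour in [0, period)), ``mesor``,
    ``slope``, and one ``alog_<group>`` column per clinical group holding the
    planted log2-scale amplitude (0 for non-rhythmic genes).
    """

    genes: pd.DataFrame
    period: float

    def alog(self, group: str) -> pd.Series:
        return self.genes[f"alog_{group}"]

    @property
    def rhythmic_ids(self) -> pd.Index:
        return self.genes.index[self.genes["is_rhythmic"]]


def simulate_timecourse(config: SimConfig) -> tuple[TimecourseMatrix, SimTruth]:
    """Draw a cohort from the generating model.

    The signal for gene *g*, subject *s* (group G, treatment R) at time *t* is

        mesor_g + slope_g * t + A_g * att_G * att_R
            * cos(2*pi*(t - phase_g)/period) + offset_s + noise,

    all on the log2 scale.  When ``output_scale == "counts"`` the log2 signal
    is exponentiated into per-sample transcript proportions and counts are
    drawn Poisson at a fixed library size of 20 million reads.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    genes = pd.Index([f"gene{i:05d}" for i in range(g)], name="gene_id")

    n_rhythmic = int(round(config.frac_rhythmic * g))
    is_rhythmic = np.zeros(g, dtype=bool)
    rhythmic_idx = rng.choice(g, size=n_rhythmic, replace=False)
    is_rhythmic[rhythmic_idx] = True

    lo, hi = config.amplitude_range
    base_amp = np.where(is_rhythmic, rng.uniform(lo, hi, size=g), 0.0)
    phase = rng.uniform(0.0, config.period, size=g)
    mesor = rng.uniform(*config.mesor_range, size=g)
    slope = rng.normal(0.0, config.trend_slope_sd, size=g)

    groups = list(config.n_subjects_per_group)
    sample_rows = []
    for gi, group in enumerate(groups):
        for si in range(config.n_subjects_per_group[group]):
            subject = f"{group}_s{si + 1}"
            for treatment in config.treatments:
                for t in config.timepoints:
                    sample_rows.append((subject, group, treatment, float(t)))
    samples = pd.DataFrame(
        sample_rows, columns=["subject", "group", "treatment", "time"]
    )
    samples.index = pd.Index(
        [
            f"{r.subject}_{r.treatment}_t{r.time:g}"
            for r in samples.itertuples()
        ],
        name="sample_id",
    )

    subjects = samples["subject"].unique()
    offsets = dict(
        zip(subjects, rng.normal(0.0, config.subject_effect_sd, size=len(subjects)))
    )

    t = samples["time"].to_numpy()
    group_att = samples["group"].map(
        {grp: config.amplitude_attenuation**i for i, grp in enumerate(groups)}
    ).to_numpy()
    treat_att = samples["treatment"].map(
        {tr: config.treatment_attenuation**i for i, tr in enumerate(config.treatments)}
    ).to_numpy()
    subj_off = samples["subject"].map(offsets).to_numpy()

    cosine = np.cos(
        2.0 * np.pi * (t[None, :] - phase[:, None]) / config.period
    )
    signal = (
        mesor[:, None]
        + slope[:, None] * t[None, :]
        + base_amp[:, None] * (group_att * treat_att)[None, :] * cosine
        + subj_off[None, :]
    )
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)

    truth_cols = {
        "is_rhythmic": is_rhythmic,
        "phase": np.where(is_rhythmic, phase, np.nan),
        "mesor": mesor,
        "slope": slope,
    }
    for i, group in enumerate(groups):
        truth_cols[f"alog_{group}"] = base_amp * config.amplitude_attenuation**i
    truth = SimTruth(pd.DataFrame(truth_cols, index=genes), config.period)

    if config.output_scale == SCALE_COUNTS:
        linear = np.exp2(signal)
        props = linear / linear.sum(axis=0, keepdims=True)
        counts = rng.poisson(props * DEFAULT_LIB_SIZE).astype(np.int64)
        values = pd.DataFrame(counts, index=genes, columns=samples.index)
        tc = TimecourseMatrix(values=values, samples=samples, scale=SCALE_COUNTS)
    else:
        values = pd.DataFrame(signal, index=genes, columns=samples.index)
        tc = TimecourseMatrix(values=values, samples=samples, scale=SCALE_LOGCPM)
    return tc, truth


def simulate_binary_annotations(
    n_genes: int,
    profiles: list,
    counts_per_profile: list,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Plant binary feature profiles across genes in randomized order.

    Returns the gene × feature 0/1 matrix and a Series mapping each gene to
    the index of its planted profile.
    """
    profiles = [np.asarray(p, dtype=int) for p in profiles]
    if len(profiles) != len(counts_per_profile):
        raise InvalidConfigError("profiles and counts_per_profile differ in length")
    if not profiles:
        raise InvalidConfigError("at least one profile required")
    width = len(profiles[0])
    if any(len(p) != width for p in profiles):
        raise InvalidConfigError("all profiles must have the same length")
    if any(np.any((p != 0) & (p != 1)) for p in profiles):
        raise InvalidConfigError("profiles must be 0/1 vectors")
    if sum(counts_per_profile) != n_genes:
        raise InvalidConfigError("counts_per_profile must sum to n_genes")

    rng = np.random.default_rng(seed)
    assignment = np.repeat(np.arange(len(profiles)), counts_per_profile)
    rng.shuffle(assignment)
    genes = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id")
    matrix = pd.DataFrame(
        np.stack([profiles[a] for a in assignment]) if n_genes else
        np.empty((0, width), dtype=int),
        index=genes,
        columns=[f"feature{j + 1}" for j in range(width)],
    )
    labels = pd.Series(assignment, index=genes, name="profile")
    return matrix, labels


def simulate_peaks_and_tss(
    n_genes: int,
    bound_fraction: float,
    seed: int = 0,
    n_chroms: int = 4,
    spacing: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame, set]:
    """Lay out TSS positions and plant binding peaks near a random subset.

    TSS are spaced ``spacing`` bp apart (with jitter of at most spacing/8),
    so a peak placed within spacing/4 of its own TSS is guaranteed nearer to
    that TSS than to any other — the planted bound set is exactly recoverable
    by nearest-TSS assignment.
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise InvalidConfigError("bound_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    chroms = [f"chr{(i % n_chroms) + 1}" for i in range(n_genes)]
    pos_index = np.arange(n_genes) // n_chroms
    jitter = rng.integers(-spacing // 8, spacing // 8 + 1, size=n_genes)
    tss_pos = spacing + pos_index * spacing + jitter
    tss = pd.DataFrame(
        {
            "gene_id": genes,
            "chrom": chroms,
            "tss_position": tss_pos,
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    ).set_index("gene_id")

    n_bound = int(round(bound_fraction * n_genes))
    bound_idx = rng.choice(n_genes, size=n_bound, replace=False)
    rows = []
    for gi in sorted(bound_idx):
        n_peaks = int(rng.integers(1, 4))
        for pi in range(n_peaks):
            offset = int(rng.integers(-spacing // 4, spacing // 4 + 1))
            mid = int(tss_pos[gi]) + offset
            half = int(rng.integers(50, 300))
            rows.append(
                (
                    chroms[gi],
                    max(0, mid - half),
                    mid + half,
                    f"peak_{genes[gi]}_{pi}",
                    float(rng.uniform(1, 100)),
                )
            )
    peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score"]
    )
    bound = {genes[i] for i in bound_idx}
    return peaks, tss, bound


def simulate_gene_sets(
    universe,
    rhythmic,
    n_decoy_sets: int = 20,
    set_size: int = 50,
    seed: int = 0,
) -> dict:
    """Build a GMT-style collection with one set enriched for rhythmic genes.

    The planted set draws 80% of its members from ``rhythmic``; decoys draw
    uniformly from the universe.  Used by the pipeline demo and tests.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    rhythmic = [g for g in rhythmic if g in set(universe)]
    sets = {}
    n_hit = min(int(0.8 * set_size), len(rhythmic))
    hits = list(rng.choice(rhythmic, size=n_hit, replace=False))
    rest = list(
        rng.choice(universe, size=set_size - n_hit, replace=False)
    )
    sets["planted_rhythmic_set"] = sorted(set(hits + rest))
    for i in range(n_decoy_sets):
        sets[f"decoy_set_{i + 1:02d}"] = sorted(
            rng.choice(universe, size=set_size, replace=False)
        )
    return sets


def simulate_tf_edges(
    universe,
    rhythmic,
    n_decoy_tfs: int = 20,
    targets_per_tf: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """TF→target edge table with one TF whose targets are mostly rhythmic."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    rhythmic = [g for g in rhythmic if g in set(universe)]
    rows = []
    n_hit = min(int(0.8 * targets_per_tf), len(rhythmic))
    for tgt in rng.choice(rhythmic, size=n_hit, replace=False):
        rows.append(("TF_planted", tgt))
    for tgt in rng.choice(universe, size=targets_per_tf - n_hit, replace=False):
        rows.append(("TF_planted", tgt))
    for i in range(n_decoy_tfs):
        for tgt in rng.choice(universe, size=targets_per_tf, replace=False):
            rows.append((f"TF_decoy_{i + 1:02d}", tgt))
    edges = pd.DataFrame(rows, columns=["tf_id", "target_id"]).drop_duplicates()
    return edges.reset_index(drop=True)
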