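"""End-to-end orchestration: simulate/ingest → preprocess → statistics → outputs.

``run_pipeline`` executes the stages in dependency order, writes every
result as TSV into a run directory and records a machine-readable manifest
(config hash, seed, row counts per output).  All randomness flows from the
single configured seed, so a rerun with an identical configuration
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .amplitude import amplitude_ratio, harmonic_fits
from .datatypes import SCALE_COUNTS, TimecourseMatrix
from .enrichment import GeneSetCollection, correlate_with_trait, enrich_collection
from .errors import CycleomicsError, InvalidConfigError
from .integrate import (
    assign_peaks_to_genes,
    build_binary_matrix,
    cluster_binary,
    overlap_tests,
)
from .preprocess import filter_low_expression, log_cpm, remove_batch
from .rhythm import differential_rhythmicity, rhythm_analysis, tabulate_peak_times
from .simulate import (
    SimConfig,
    simulate_gene_sets,
    simulate_peaks_and_tss,
    simulate_tf_edges,
    simulate_timecourse,
)
from .tf_network import build_tf_gene_graph, tf_enrichment

logger = logging.getLogger(__name__)


class PipelineStageError(CycleomicsError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage, original):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Run-level parameters; stage defaults mirror the module defaults."""

    outdir: str = "cycleomics_run"
    seed: int = 0
    # either simulate ...
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    # ... or ingest existing files
    expr_path: str | None = None
    samples_path: str | None = None

    period: float = 24.0
    rhythm_fdr: float = 0.10
    enrich_fdr: float = 0.10
    overlap_fdr: float = 0.05
    min_count: int = 10
    min_samples: int | None = None
    min_total: int = 15
    prior_count: float = 0.5
    rhythm_method: str = "auto"
    bound_fraction: float = 0.3
    max_peak_distance: int = 50_000
    min_cluster_size: int = 5

    def __post_init__(self):
        for name in ("rhythm_fdr", "enrich_fdr", "overlap_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidConfigError(f"{name} must lie in (0, 1]")
        if not self.simulate and (self.expr_path is None or self.samples_path is None):
            raise InvalidConfigError("ingest mode needs expr_path and samples_path")
        if self.expr_path is not None and self.expr_path == self.samples_path:
            raise InvalidConfigError("declared paths must be distinct")

    def config_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("outdir", None)  # hash the analysis, not its destination
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {},
    }
    meta = {"config": config.config_hash(), "seed": config.seed}

    def record(name, df, path):
        cio.write_tsv(df, path, meta=meta)
        manifest["outputs"][name] = {"path": str(path), "rows": int(len(df))}

    # -- stage: simulate / ingest ------------------------------------------
    @_stage("simulate")
    def stage_simulate():
        sim_cfg = SimConfig(seed=config.seed, **config.sim_overrides)
        tc, truth = simulate_timecourse(sim_cfg)
        cio.write_timecourse(
            tc, outdir / "expression.tsv", outdir / "samples.tsv", meta=meta
        )
        truth_df = truth.genes.reset_index()
        record("truth", truth_df, outdir / "truth.tsv")
        return tc, truth, sim_cfg

    @_stage("ingest")
    def stage_ingest():
        tc = cio.read_timecourse(config.expr_path, config.samples_path)
        return tc, None, None

    if config.simulate:
        tc, truth, sim_cfg = stage_simulate()
    else:
        tc, truth, sim_cfg = stage_ingest()

    # -- stage: preprocess --------------------------------------------------
    @_stage("preprocess")
    def stage_preprocess(tc):
        n_in = tc.n_genes
        if tc.scale == SCALE_COUNTS:
            tc = filter_low_expression(
                tc, config.min_count, config.min_samples, config.min_total
            )
            logger.info("filter: %d genes in, %d retained", n_in, tc.n_genes)
            tc = log_cpm(tc, config.prior_count)
        tc = remove_batch(tc)
        return tc

    tc = stage_preprocess(tc)
    manifest["n_genes_analyzed"] = int(tc.n_genes)
    universe = list(tc.gene_ids)
    groups = list(pd.unique(tc.samples["group"]))
    treatments = list(pd.unique(tc.samples["treatment"]))

    # -- stage: rhythm -------------------------------------------------------
    @_stage("rhythm")
    def stage_rhythm(tc):
        res = rhythm_analysis(
            tc, period=config.period, fdr_threshold=config.rhythm_fdr,
            method=config.rhythm_method,
        )
        record("rhythm", res, outdir / "rhythm.tsv")
        peaks = tabulate_peak_times(res)
        record("peak_times", peaks, outdir / "peak_times.tsv")
        return res

    rhythm = stage_rhythm(tc)

    def rhythmic_set(group, treatment):
        sel = rhythm[
            (rhythm["group"] == group)
            & (rhythm["treatment"] == treatment)
            & rhythm["rhythmic"]
        ]
        return set(sel["gene_id"])

    # -- stage: differential rhythmicity ------------------------------------
    @_stage("dodr")
    def stage_dodr(tc):
        frames = []
        if len(groups) >= 2:
            ga, gb = groups[0], groups[1]
            for treatment in treatments:
                sub_a = tc.subset_samples(tc.condition_mask(ga, treatment))
                sub_b = tc.subset_samples(tc.condition_mask(gb, treatment))
                pa = rhythm.set_index("gene_id").loc[
                    lambda d: (d["group"] == ga) & (d["treatment"] == treatment),
                    "p_value",
                ]
                pb = rhythm.set_index("gene_id").loc[
                    lambda d: (d["group"] == gb) & (d["treatment"] == treatment),
                    "p_value",
                ]
                res = differential_rhythmicity(
                    sub_a, sub_b, period=config.period,
                    rhythm_p_a=pa.reindex(sub_a.gene_ids).to_numpy(),
                    rhythm_p_b=pb.reindex(sub_b.gene_ids).to_numpy(),
                    meta_fdr_threshold=config.rhythm_fdr,
                )
                res.insert(1, "treatment", treatment)
                frames.append(res)
        out = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["gene_id", "treatment", "meta_p", "meta_fdr",
                                       "tested", "diff_p", "diff_fdr"])
        )
        record("dodr", out, outdir / "dodr.tsv")
        return out

    stage_dodr(tc)

    # -- stage: amplitude ----------------------------------------------------
    @_stage("amplitude")
    def stage_amplitude(tc):
        fits = harmonic_fits(tc, period=config.period)
        record("harmonic_fits", fits, outdir / "harmonic_fits.tsv")
        rows = []
        if len(groups) >= 2:
            ga, gb = groups[0], groups[1]
            for treatment in treatments:
                fa = fits[(fits["group"] == ga) & (fits["treatment"] == treatment)]
                fb = fits[(fits["group"] == gb) & (fits["treatment"] == treatment)]
                circadian = rhythmic_set(ga, treatment) | rhythmic_set(gb, treatment)
                comp = amplitude_ratio(fa, fb, circadian)
                rows.append(
                    {
                        "treatment": treatment,
                        "ks_statistic": comp.ks_statistic,
                        "ks_p": comp.ks_p,
                        "wilcoxon_statistic": comp.wilcoxon_statistic,
                        "wilcoxon_p": comp.wilcoxon_p,
                        "mean_ratio_circadian": comp.mean_ratio_circadian,
                        "mean_ratio_noncircadian": comp.mean_ratio_noncircadian,
                        "n_excluded": comp.n_excluded_zero_amplitude,
                    }
                )
        record("amplitude_comparison", pd.DataFrame(rows),
               outdir / "amplitude_comparison.tsv")
        return fits

    stage_amplitude(tc)

    # the annotation stages below need ground truth to fabricate inputs;
    # in ingest mode users run them directly on their own files
    if truth is None:
        _write_manifest(manifest, outdir)
        return manifest

    rhythmic_ref = rhythmic_set(groups[0], treatments[0])

    # -- stage: enrichment ---------------------------------------------------
    @_stage("enrich")
    def stage_enrich():
        sets = simulate_gene_sets(universe, sorted(rhythmic_ref),
                                  seed=config.seed + 101)
        cio.write_gmt(sets, outdir / "gene_sets.gmt")
        coll = GeneSetCollection(sets, universe)
        res = enrich_collection(rhythmic_ref, coll, fdr_threshold=config.enrich_fdr)
        res = res.assign(members=res["members"].map(lambda m: ",".join(m)))
        record("enrichment", res, outdir / "enrichment.tsv")

    stage_enrich()

    # -- stage: trait correlation -------------------------------------------
    @_stage("trait_cor")
    def stage_trait():
        # basal expression: per-subject mean of the reference arm
        sub = tc.subset_samples(tc.condition_mask(treatment=treatments[0]))
        basal = sub.values.T.groupby(sub.samples["subject"]).mean().T
        rng = np.random.default_rng(config.seed + 202)
        subj_groups = sub.samples.drop_duplicates("subject").set_index("subject")["group"]
        subj_groups = subj_groups.reindex(basal.columns)
        # M-value-like trait: lower in the disease-like group, plus noise
        trait = pd.Series(
            np.where(subj_groups == groups[0], 8.0, 4.0)
            + rng.normal(0, 1.5, size=len(basal.columns)),
            index=basal.columns,
            name="m_value",
        )
        cio.write_tsv(trait.rename_axis("subject").reset_index(), outdir / "trait.tsv")
        res = correlate_with_trait(basal, trait)
        record("trait_correlation", res, outdir / "trait_correlation.tsv")
        return res

    trait_cor = stage_trait()
    trait_sig = set(trait_cor.loc[trait_cor["fdr"] < config.enrich_fdr, "gene_id"])

    # -- stage: integrate ----------------------------------------------------
    @_stage("integrate")
    def stage_integrate():
        peaks, tss, bound_truth = simulate_peaks_and_tss(
            len(universe), config.bound_fraction, seed=config.seed + 303
        )
        # re-key the generic simulated gene ids onto the analysis universe
        key = dict(zip([f"gene{i:05d}" for i in range(len(universe))], universe))
        tss.index = [key[g] for g in tss.index]
        tss.index.name = "gene_id"
        cio.write_bed6(peaks, outdir / "peaks.bed")
        cio.write_tss(tss, outdir / "tss.tsv")
        assigned = assign_peaks_to_genes(peaks, tss, config.max_peak_distance)
        bound = set(assigned.index[assigned["bound"]])
        features = {
            f"rhythmic_{g}_{t}": rhythmic_set(g, t)
            for g in groups
            for t in treatments
        }
        features["trait_correlated"] = trait_sig
        features["bound"] = bound
        bm = build_binary_matrix(features, universe)
        record("binary_matrix", bm.reset_index(), outdir / "binary_matrix.tsv")
        labels = cluster_binary(bm, config.min_cluster_size)
        record("clusters", labels.rename_axis("gene_id").reset_index(),
               outdir / "clusters.tsv")
        pairs = {
            f"rhythmic_{g}_{t}_vs_bound": (rhythmic_set(g, t), bound)
            for g in groups
            for t in treatments
        }
        ov = overlap_tests(pairs, universe)
        ov["significant"] = ov["fdr"] < config.overlap_fdr
        record("overlaps", ov, outdir / "overlaps.tsv")

    stage_integrate()

    # -- stage: TF network ---------------------------------------------------
    @_stage("tfnet")
    def stage_tfnet():
        edges = simulate_tf_edges(universe, sorted(rhythmic_ref),
                                  seed=config.seed + 404)
        cio.write_tsv(edges, outdir / "tf_edges.tsv")
        by_group = {
            g: rhythmic_set(g, treatments[0]) for g in groups
        }
        res = tf_enrichment(edges, by_group, universe,
                            fdr_threshold=config.enrich_fdr)
        record("tf_enrichment", res, outdir / "tf_enrichment.tsv")
        graph = build_tf_gene_graph(res[res["significant"]], edges, by_group)
        record("tf_graph", graph, outdir / "tf_graph.tsv")

    stage_tfnet()

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path):
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
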