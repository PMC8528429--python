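import numpy as np
import pandas as pd
import pytest

import cycleomics as co
from cycleomics.datatypes import TimecourseMatrix
from cycleomics.errors import (
    ConfoundingError,
    InvalidInputError,
    WrongScaleError,
    ZeroVarianceError,
)


def make_counts(counts_rows, times=(0, 6, 12, 18), subjects=None, groups=None):
    """Small count container; one subject per sample column by default."""
    arr = np.asarray(counts_rows)
    n = arr.shape[1]
    times = list(times) * (n // len(times)) if n != len(times) else list(times)
    subjects = subjects or [f"s{i}" for i in range(n)]
    groups = groups or ["A"] * n
    samples = pd.DataFrame(
        {
            "subject": subjects,
            "group": groups,
            "treatment": "control",
            "time": [float(t) for t in times[:n]],
        },
        index=pd.Index([f"smp{i}" for i in range(n)], name="sample_id"),
    )
    values = pd.DataFrame(
        arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=samples.index
    )
    return TimecourseMatrix(values=values, samples=samples, scale="counts")


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        tc = make_counts([[0, 0, 0, 0], [20, 20, 20, 20]])
        out = co.filter_low_expression(tc, min_count=1, min_samples=1, min_total=1)
        assert list(out.gene_ids) == ["g1"]

    def test_uniform_high_gene_retained_with_defaults(self):
        tc = make_counts([[20, 20, 20, 20]])
        out = co.filter_low_expression(tc)
        assert list(out.gene_ids) == ["g0"]

    def test_single_spike_removed(self):
        tc = make_counts([[12, 0, 0, 0]])
        out = co.filter_low_expression(tc, min_count=10, min_samples=2, min_total=0)
        assert len(out.gene_ids) == 0

    def test_requires_counts_scale(self):
        tc = make_counts([[1, 2, 3, 4]])
        lc = co.log_cpm(tc)
        with pytest.raises(WrongScaleError):
            co.filter_low_expression(lc)


class TestLogCpm:
    def test_known_values(self):
        tc = make_counts([[1000], [0]], times=(0,))
        tc.values.iloc[:, 0] = [1000, 0]
        lib = pd.Series([10**6], index=tc.values.columns)
        tc.lib_sizes = lib
        out = co.log_cpm(tc, prior_count=0.5)
        expected_hi = np.log2(1000.5 / 1_000_001 * 1e6)
        expected_lo = np.log2(0.5 / 1_000_001 * 1e6)
        assert out.values.iloc[0, 0] == pytest.approx(expected_hi, abs=1e-9)
        assert out.values.iloc[0, 0] == pytest.approx(9.9666, abs=1e-4)
        assert out.values.iloc[1, 0] == pytest.approx(expected_lo, abs=1e-9)

    def test_symmetry_equal_counts_equal_outputs(self):
        tc = make_counts([[5, 5, 5, 5], [5, 5, 5, 5]])
        out = co.log_cpm(tc)
        vals = out.values.to_numpy()
        assert np.allclose(vals, vals[0, 0])

    def test_negative_counts_rejected(self):
        tc = make_counts([[1, 2, 3, 4]])
        tc.values.iloc[0, 0] = -1
        with pytest.raises(InvalidInputError):
            co.log_cpm(tc)

    def test_filter_then_logcpm_commutes(self):
        """Library sizes are frozen pre-filtering, so filtering first and
        transforming matches transforming then subsetting genes."""
        rng = np.random.default_rng(0)
        tc = make_counts(rng.integers(0, 100, size=(30, 4)))
        filtered = co.filter_low_expression(tc, min_count=10, min_samples=2, min_total=50)
        a = co.log_cpm(filtered).values
        b = co.log_cpm(
            co.filter_low_expression(tc, min_count=0, min_samples=0, min_total=0)
        ).values.loc[filtered.gene_ids]
        pd.testing.assert_frame_equal(a, b)


class TestRemoveBatch:
    def test_single_batch_identity(self):
        tc = make_counts([[1, 2, 3, 4]], subjects=["s"] * 4)
        lc = co.log_cpm(tc)
        out = co.remove_batch(lc, protected=None)
        pd.testing.assert_frame_equal(out.values, lc.values)

    def test_constant_offset_between_batches_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 8))
        vals = base.copy()
        vals[:, 4:] += 3.0  # batch B offset by delta
        samples = pd.DataFrame(
            {
                "subject": ["a"] * 4 + ["b"] * 4,
                "group": "A",
                "treatment": "control",
                "time": [0.0, 6.0, 12.0, 18.0] * 2,
            },
            index=pd.Index([f"smp{i}" for i in range(8)], name="sample_id"),
        )
        tc = TimecourseMatrix(
            values=pd.DataFrame(vals, columns=samples.index),
            samples=samples,
            scale="logcpm",
        )
        out = co.remove_batch(tc, protected=None)
        v = out.values.to_numpy()
        diff = v[:, :4].mean(axis=1) - v[:, 4:].mean(axis=1)
        assert np.abs(diff).max() <= 1e-10

    def test_idempotent_and_means_protected(self):
        cfg = co.SimConfig(n_genes=60, seed=2)
        tc, _ = co.simulate_timecourse(cfg)
        rb = co.remove_batch(tc)
        rb2 = co.remove_batch(rb)
        assert np.abs(rb.values.to_numpy() - rb2.values.to_numpy()).max() <= 1e-9
        cells = tc.samples["group"].astype(str) + ":" + tc.samples["treatment"].astype(str)
        for cell in cells.unique():
            m = (cells == cell).to_numpy()
            shift = (
                tc.values.to_numpy()[:, m].mean(axis=1)
                - rb.values.to_numpy()[:, m].mean(axis=1)
            )
            assert np.abs(shift).max() <= 1e-9

    def test_subject_variance_shrinks_on_noiseless_signal(self):
        cfg = co.SimConfig(
            n_genes=40, noise_sd=0.0, subject_effect_sd=1.0,
            treatments=("control",), seed=3,
        )
        tc, _ = co.simulate_timecourse(cfg)
        rb = co.remove_batch(tc)

        def within_group_subject_var(t):
            # variance of subject means around their group mean — the
            # component batch removal targets (between-group is protected)
            sm = t.values.T.groupby(t.samples["subject"]).mean().T
            gmap = t.samples.drop_duplicates("subject").set_index("subject")["group"]
            centered = sm - sm.T.groupby(gmap).transform("mean").T
            return float((centered**2).mean().mean())

        assert within_group_subject_var(rb) <= 0.1 * within_group_subject_var(tc)

    def test_confounded_batch_raises(self):
        # explicit batch labels identical to a time split -> collinear with
        # the protected time factor
        rng = np.random.default_rng(4)
        samples = pd.DataFrame(
            {
                "subject": ["a"] * 4 + ["b"] * 4,
                "group": ["A"] * 4 + ["B"] * 4,
                "treatment": "control",
                "time": [0.0, 6.0, 12.0, 18.0] * 2,
            },
            index=pd.Index([f"smp{i}" for i in range(8)], name="sample_id"),
        )
        tc = TimecourseMatrix(
            values=pd.DataFrame(rng.normal(size=(5, 8)), columns=samples.index),
            samples=samples,
            scale="logcpm",
        )
        batch = pd.Series(
            np.where(samples["time"] < 12, "early", "late"), index=samples.index
        )
        with pytest.raises(ConfoundingError) as exc:
            co.remove_batch(tc, batch=batch)
        assert exc.value.columns  # names the collinear columns


class TestCenterByGroup:
    def test_constant_gene_mean_center_zeros(self):
        tc = make_counts([[7, 7, 7, 7]])
        lc = co.log_cpm(tc)
        out = co.center_by_group(lc, mode="mean")
        assert np.allclose(out.values.to_numpy(), 0.0, atol=1e-10)

    def test_already_centered_unchanged(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(6, 4))
        vals -= vals.mean(axis=1, keepdims=True)
        tc = make_counts(np.ones((6, 4)))
        lc = co.log_cpm(tc)
        lc.values.iloc[:, :] = vals
        out = co.center_by_group(lc, mode="mean")
        assert np.allclose(out.values.to_numpy(), vals, atol=1e-12)

    def test_zscore_moments(self, small_cohort):
        tc, _, _ = small_cohort
        out = co.center_by_group(tc, mode="zscore")
        labels = out.samples[["group", "treatment"]].apply(tuple, axis=1)
        for _, idx in labels.groupby(labels).groups.items():
            block = out.values[list(idx)].to_numpy()
            assert np.abs(block.mean(axis=1)).max() < 1e-10
            assert np.abs(block.std(axis=1, ddof=1) - 1).max() < 1e-10

    def test_zscore_constant_gene_raises(self):
        tc = make_counts([[7, 7, 7, 7]])
        lc = co.log_cpm(tc)
        with pytest.raises(ZeroVarianceError) as exc:
            co.center_by_group(lc, mode="zscore")
        assert "g0" in exc.value.genes
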