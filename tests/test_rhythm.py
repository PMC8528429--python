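import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cycleomics as co
from cycleomics.errors import InsufficientDesignError, InvalidInputError
from cycleomics.rhythm import _UmbrellaDesign


def brute_force_umbrella_p(values, times, period):
    """Independent oracle: exhaustive single-subject permutation p-value.

    Enumerates every ordering of the observed values over the time slots for
    each envelope, takes the best envelope p and applies the same Bonferroni
    factor.  Shares no code with the tested statistic beyond the envelope
    pair definitions.
    """
    values = np.asarray(values, float)
    design = _UmbrellaDesign(times, np.zeros(len(values)), period)
    perms = np.array(list(itertools.permutations(range(len(values)))))
    vp = values[perms]
    best = np.inf
    for e in range(design.n_envelopes):
        lo, hi = design._env_lo[e], design._env_hi[e]
        s_obs = (2 * (values[lo] < values[hi]) + (values[lo] == values[hi])).sum()
        s_null = (2 * (vp[:, lo] < vp[:, hi]) + (vp[:, lo] == vp[:, hi])).sum(axis=1)
        best = min(best, (s_null >= s_obs).mean())
    return min(1.0, best * design.n_envelopes)


class TestUmbrellaRhythmTest:
    def test_constant_series_p_one(self):
        t = np.arange(8) * 6.0
        p, _ = co.umbrella_rhythm_test(np.ones(8), t, period=48,
                                       correction="bonferroni")
        assert p == 1.0

    def test_matches_exhaustive_permutation_oracle(self):
        t = np.arange(8) * 6.0
        for vals in ([0, 1, 2, 3, 3, 2, 1, 0], [0, 1, 2, 3, 4, 3, 2, 1],
                     [5, 1, 4, 2, 2, 4, 1, 5]):
            p_impl, _ = co.umbrella_rhythm_test(vals, t, period=48,
                                                correction="bonferroni")
            p_oracle = brute_force_umbrella_p(vals, t, period=48)
            assert p_impl == pytest.approx(p_oracle, abs=1e-12)

    def test_peak_time_matches_planted_phase(self):
        # strong noiseless cosine peaking at 12 h on the folded 4-phase grid
        t = np.tile(np.arange(12, 55, 6.0), 3)
        subj = np.repeat(["a", "b", "c"], 8)
        y = np.cos(2 * np.pi * (t - 12.0) / 24.0)
        p, peak = co.umbrella_rhythm_test(y, t, subjects=subj, period=24.0)
        assert p < 0.01
        assert peak == 12.0

    def test_monotone_transform_invariance(self, eight_phase_design):
        times, subjects, period = eight_phase_design
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(times))
        kw = dict(correction="bonferroni")
        p1, k1 = co.umbrella_rhythm_test(y, times, subjects, period, **kw)
        p2, k2 = co.umbrella_rhythm_test(np.exp(y), times, subjects, period, **kw)
        p3, k3 = co.umbrella_rhythm_test(3 * y - 7, times, subjects, period, **kw)
        assert p1 == p2 == p3 and k1 == k2 == k3

    def test_time_reversal_invariance_of_min_p(self):
        # the envelope set is mirror-complete, so reversing time preserves p
        t = np.arange(8) * 6.0
        rng = np.random.default_rng(1)
        y = rng.normal(size=8)
        p_fwd, _ = co.umbrella_rhythm_test(y, t, period=48, correction="bonferroni")
        p_rev, _ = co.umbrella_rhythm_test(y[::-1], t, period=48, correction="bonferroni")
        assert p_fwd == pytest.approx(p_rev, abs=1e-12)

    def test_normal_approximation_close_to_exact(self, eight_phase_design):
        times, subjects, period = eight_phase_design
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, len(times)))
        X[:25] += np.cos(2 * np.pi * np.asarray(times) / period) * 1.5
        pe, _, _ = co.umbrella_rhythm_matrix(X, times, subjects, period, method="exact")
        pn, _, _ = co.umbrella_rhythm_matrix(X, times, subjects, period, method="normal")
        # same rejections at 0.05 for clearly-signal and clearly-null genes
        agree = ((pe < 0.05) == (pn < 0.05)).mean()
        assert agree > 0.9

    def test_too_few_phases_raises(self):
        with pytest.raises(InsufficientDesignError):
            co.umbrella_rhythm_test([1, 2, 3], [0, 6, 12], period=24)

    def test_single_phase_subject_raises(self):
        times = [0, 6, 12, 18, 0]
        subjects = ["a", "a", "a", "a", "b"]
        with pytest.raises(InsufficientDesignError):
            co.umbrella_rhythm_test([1, 2, 3, 4, 5], times, subjects, period=24)

    def test_null_calibration_small(self, eight_phase_design):
        times, subjects, period = eight_phase_design
        rng = np.random.default_rng(3)
        X = rng.normal(size=(500, len(times)))
        p, _, _ = co.umbrella_rhythm_matrix(X, times, subjects, period)
        assert 0.02 <= (p < 0.05).mean() <= 0.08


class TestAdjustBH:
    def test_step_up_closed_form(self):
        out = co.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert co.adjust_bh([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(co.adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(co.adjust_bh(p)[perm], co.adjust_bh(p[perm]))

    def test_dominates_raw_p_and_capped(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=30)
        out = co.adjust_bh(p)
        assert np.all(out >= p) and np.all(out <= 1)

    def test_range_check(self):
        with pytest.raises(InvalidInputError):
            co.adjust_bh([0.5, 1.5])


class TestMetaPBeta:
    def test_known_values(self):
        assert co.meta_p_beta(0.5, 0.5) == pytest.approx(0.75)
        assert co.meta_p_beta(0.0, 0.9) == 0.0
        assert co.meta_p_beta(1.0, 1.0) == 1.0

    @given(st.floats(min_value=0, max_value=1))
    @settings(deadline=None, max_examples=50)
    def test_order_statistic_bounds(self, p):
        m = co.meta_p_beta(p, p)
        assert p - 1e-12 <= m <= min(1.0, 2 * p) + 1e-12

    def test_range_check(self):
        with pytest.raises(InvalidInputError):
            co.meta_p_beta(-0.1, 0.5)


class TestDifferentialRhythmicity:
    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(6)
        cfg = co.SimConfig(
            n_genes=10, frac_rhythmic=1.0, noise_sd=0.2,
            n_subjects_per_group={"NGT": 4}, treatments=("control",), seed=7,
        )
        tc, _ = co.simulate_timecourse(cfg)
        res = co.differential_rhythmicity(tc, tc, period=24.0)
        tested = res[res["tested"]]
        assert len(tested) > 0
        assert np.allclose(tested["diff_p"], 1.0)

    def test_amplitude_difference_detected(self):
        cfg = co.SimConfig(
            n_genes=100, frac_rhythmic=1.0, noise_sd=0.25,
            amplitude_range=(0.9, 0.9), amplitude_attenuation=1 / 3,
            treatments=("control",), seed=8,
        )
        tc, _ = co.simulate_timecourse(cfg)
        tc = co.remove_batch(tc)
        a = tc.subset_samples(tc.condition_mask("NGT"))
        b = tc.subset_samples(tc.condition_mask("T2D"))
        res = co.differential_rhythmicity(a, b, period=24.0)
        tested = res[res["tested"]]
        assert (tested["diff_fdr"] < 0.10).mean() >= 0.8

    def test_untested_genes_have_nan_p(self):
        cfg = co.SimConfig(
            n_genes=60, frac_rhythmic=0.3, noise_sd=0.4,
            treatments=("control",), seed=9,
        )
        tc, _ = co.simulate_timecourse(cfg)
        tc = co.remove_batch(tc)
        a = tc.subset_samples(tc.condition_mask("NGT"))
        b = tc.subset_samples(tc.condition_mask("T2D"))
        res = co.differential_rhythmicity(a, b, period=24.0)
        assert res.loc[~res["tested"], "diff_p"].isna().all()
        assert (res["meta_fdr"] >= res["meta_p"] - 1e-12).all()


class TestTabulatePeakTimes:
    def test_counts_and_percentages(self, small_cohort):
        tc, _, _ = small_cohort
        res = co.rhythm_analysis(co.remove_batch(tc), period=24.0)
        tab = co.tabulate_peak_times(res)
        for (_, _), grp in tab.groupby(["group", "treatment"]):
            assert grp["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        assert tab["count"].sum() == int(res["rhythmic"].sum())

    def test_no_rhythmic_genes_empty_table(self):
        import pandas as pd

        empty = pd.DataFrame(
            {
                "gene_id": ["g1"], "group": ["A"], "treatment": ["c"],
                "peak_label": [24.0], "rhythmic": [False],
            }
        )
        tab = co.tabulate_peak_times(empty)
        assert tab.empty
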