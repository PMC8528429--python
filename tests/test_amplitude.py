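import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cycleomics as co
from cycleomics.errors import InsufficientDesignError, InvalidInputError


class TestAmplitudeAlgebra:
    @pytest.mark.parametrize(
        "alog,arel",
        [(0.0, 0.0), (0.5, 1 / 3), (1.0, 0.6)],
    )
    def test_known_relative_amplitudes(self, alog, arel):
        assert co.arel_from_alog(alog) == pytest.approx(arel, abs=1e-12)

    def test_round_trip_identity(self):
        grid = np.linspace(0, 3, 301)
        back = co.alog_from_arel(co.arel_from_alog(grid))
        assert np.abs(back - grid).max() <= 1e-10

    def test_fold_change_consistency(self):
        grid = np.linspace(0, 3, 50)
        afc = co.afc_from_alog(grid)
        assert np.all(afc >= 1)
        assert np.allclose(2 * grid, np.log2(afc), atol=1e-12)
        assert np.allclose(co.arel_from_alog(grid), (afc - 1) / (afc + 1))

    @given(st.floats(min_value=0, max_value=3), st.floats(min_value=0, max_value=3))
    @settings(deadline=None, max_examples=50)
    def test_arel_strictly_increasing(self, x, y):
        if x + 1e-9 < y:  # strictness is not meaningful below float resolution
            assert co.arel_from_alog(x) < co.arel_from_alog(y)
        elif x == y:
            assert co.arel_from_alog(x) == co.arel_from_alog(y)

    def test_negative_input_rejected(self):
        with pytest.raises(InvalidInputError):
            co.arel_from_alog(-0.1)


class TestFitHarmonic:
    def test_noiseless_recovery(self):
        t = np.arange(12, 55, 6.0)
        y = 0.8 * np.cos(2 * np.pi * t / 24) + 5 + 0.1 * t
        fit = co.fit_harmonic(y, t, period=24.0)
        assert fit.a == pytest.approx(0.8, abs=1e-8)
        assert fit.b == pytest.approx(0.0, abs=1e-8)
        assert fit.c == pytest.approx(5.0, abs=1e-8)
        assert fit.d == pytest.approx(0.1, abs=1e-8)
        assert fit.a_log == pytest.approx(0.8, abs=1e-8)

    def test_constant_series(self):
        t = np.arange(12, 55, 6.0)
        fit = co.fit_harmonic(np.full_like(t, 3.0), t, period=24.0)
        assert fit.a_log == pytest.approx(0.0, abs=1e-10)
        assert fit.a_rel == pytest.approx(0.0, abs=1e-10)
        assert fit.d == pytest.approx(0.0, abs=1e-10)

    def test_phase_invariance_under_period_shift(self):
        t = np.arange(12, 55, 6.0)
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(t))
        f1 = co.fit_harmonic(y, t, period=24.0)
        f2 = co.fit_harmonic(y, t + 24.0, period=24.0)
        assert f1.a == pytest.approx(f2.a, abs=1e-9)
        assert f1.b == pytest.approx(f2.b, abs=1e-9)
        assert f1.phase == pytest.approx(f2.phase, abs=1e-9)

    def test_phase_matches_planted_peak(self):
        t = np.arange(0, 48, 3.0)
        for peak in (0.0, 5.0, 13.5, 23.0):
            y = np.cos(2 * np.pi * (t - peak) / 24)
            fit = co.fit_harmonic(y, t, period=24.0)
            assert fit.phase == pytest.approx(peak, abs=1e-8)

    def test_insufficient_design_raises(self):
        with pytest.raises(InsufficientDesignError):
            co.fit_harmonic([1, 2, 3], [0, 8, 16], period=24.0)

    def test_amplitude_estimate_unbiased_under_generator(self):
        """Replicated noisy cosinor fits recover the planted log2 amplitude
        with negligible bias (matrix fit, 500 replicates)."""
        rng = np.random.default_rng(1)
        t = np.tile(np.arange(12, 55, 6.0), 7)
        alog = 0.8
        y = alog * np.cos(2 * np.pi * t / 24) + 6.0 + 0.01 * t
        Y = y[None, :] + rng.normal(0, 0.3, size=(500, len(t)))
        fits = co.fit_harmonic_matrix(Y, t, period=24.0)
        assert abs(fits["a_log"].mean() - alog) < 0.03


class TestDetrend:
    def test_pure_linear_input_zeroed(self):
        t = np.arange(12, 55, 6.0)
        fit = co.fit_harmonic(2.0 + 0.5 * t, t, period=24.0)
        out = co.detrend_fit(fit, t)
        assert np.abs(out).max() <= 1e-9

    def test_pure_harmonic_whole_periods_mean_removed(self):
        # grid symmetric about t = 24, so the discrete OLS slope of the
        # cosine vanishes exactly and detrending reduces to mean removal
        t = np.arange(0, 49, 6.0)
        y = 1.2 * np.cos(2 * np.pi * t / 24) + 4.0
        fit = co.fit_harmonic(y, t, period=24.0)
        out = co.detrend_fit(fit, t)
        e = fit.predict(t)
        assert np.allclose(out, e - e.mean(), atol=1e-9)

    def test_post_detrend_slope_zero_on_random_fits(self):
        rng = np.random.default_rng(2)
        t = np.arange(12, 55, 6.0)
        worst = 0.0
        for _ in range(100):
            fit = co.HarmonicFit(*rng.normal(size=4), period=24.0)
            out = co.detrend_fit(fit, t)
            A = np.column_stack([np.ones_like(t), t])
            slope = np.linalg.lstsq(A, out, rcond=None)[0][1]
            worst = max(worst, abs(slope))
        assert worst < 1e-9


class TestAmplitudeRatio:
    def _fits(self, arels, period=24.0):
        import pandas as pd

        alog = co.alog_from_arel(np.asarray(arels))
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(arels))],
                "a": alog, "b": 0.0, "c": 0.0, "d": 0.0,
                "a_log": alog, "a_fc": co.afc_from_alog(alog),
                "a_rel": arels, "phase": 0.0, "period": period,
            }
        )

    def test_equal_amplitudes_ratio_zero_wilcoxon_one(self):
        fa = self._fits([0.2, 0.3, 0.4])
        comp = co.amplitude_ratio(fa, fa.copy(), circadian_genes=["g0", "g1", "g2"])
        assert np.allclose(comp.per_gene["log2_arel_ratio"], 0.0)
        assert comp.wilcoxon_p == 1.0

    def test_halved_amplitude_ratio_minus_one(self):
        fa = self._fits([0.5])
        fb = self._fits([0.25])
        comp = co.amplitude_ratio(fa, fb, circadian_genes=["g0"])
        assert comp.per_gene["log2_arel_ratio"].iloc[0] == pytest.approx(-1.0)

    def test_zero_amplitude_excluded_not_fatal(self):
        fa = self._fits([0.0, 0.4])
        fb = self._fits([0.3, 0.2])
        comp = co.amplitude_ratio(fa, fb, circadian_genes=["g0", "g1"])
        assert comp.n_excluded_zero_amplitude == 1
        assert np.isnan(comp.per_gene["log2_arel_ratio"].iloc[0])

    def test_antisymmetry_under_group_swap(self):
        fa = self._fits([0.2, 0.5, 0.7])
        fb = self._fits([0.4, 0.3, 0.6])
        c1 = co.amplitude_ratio(fa, fb, circadian_genes=["g0", "g1", "g2"])
        c2 = co.amplitude_ratio(fb, fa, circadian_genes=["g0", "g1", "g2"])
        assert np.allclose(
            c1.per_gene["log2_arel_ratio"], -c2.per_gene["log2_arel_ratio"]
        )

    def test_ks_matches_brute_force_oracle(self):
        """KS statistic/p for two 10-element samples versus exhaustive
        computation: statistic over all thresholds, p by enumerating all
        C(20,10) label assignments."""
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        y = rng.normal(0.5, 1, size=10)

        def ks_stat(a, b):
            pooled = np.sort(np.concatenate([a, b]))
            fa = np.searchsorted(np.sort(a), pooled, side="right") / len(a)
            fb = np.searchsorted(np.sort(b), pooled, side="right") / len(b)
            return np.abs(fa - fb).max()

        d_obs = ks_stat(x, y)
        order = np.argsort(np.concatenate([x, y]))
        # enumerate all C(20,10) label assignments over the sorted pooled
        # sample; D = max |cumsum(in_A)/10 - cumsum(in_B)/10|
        combos = np.array(list(itertools.combinations(range(20), 10)))
        masks = np.zeros((len(combos), 20), dtype=np.int8)
        np.put_along_axis(masks, combos, 1, axis=1)
        masks = masks[:, order]
        ca = np.cumsum(masks, axis=1) / 10.0
        cb = np.cumsum(1 - masks, axis=1) / 10.0
        d_all = np.abs(ca - cb).max(axis=1)
        p_oracle = (d_all >= d_obs - 1e-12).mean()
        res = ks_2samp(x, y, alternative="two-sided", method="exact")
        assert res.statistic == pytest.approx(d_obs, abs=1e-12)
        assert res.pvalue == pytest.approx(p_oracle, abs=1e-9)


class TestClusterByPhase:
    def test_separated_groups_recovered(self):
        labels = co.cluster_by_phase([0.0, 0.5, 12.0, 12.5], period=24.0, k=2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_circular_metric_wraps(self):
        D = co.amplitude.circular_phase_distance([23.5, 0.5], period=24.0)
        assert D[0, 1] == pytest.approx(1.0)

    def test_identical_phases_single_cluster(self):
        labels = co.cluster_by_phase([6.0, 6.0, 6.0], period=24.0, k=1)
        assert set(labels) == {1}

    def test_k_too_large_rejected(self):
        from cycleomics.errors import InvalidConfigError

        with pytest.raises(InvalidConfigError):
            co.cluster_by_phase([1.0, 2.0], period=24.0, k=3)
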