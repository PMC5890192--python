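"""The core statistic: z-scoring, pattern correlation, Fisher Z, top-N mean,
and the variance-decomposition N_top selector."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from preplay import (
    NtopSelector,
    ReactivationScorer,
    RestingSeries,
    aggregate_ntop,
    estimate_ntop,
    fisher_z,
    intensity_table,
    inverse_fisher,
    pattern_correlation_timecourse,
    topn_mean,
    zscore_voxels,
)
from preplay.representation import RepresentationMap
from preplay.synthetic import SyntheticSpec, make_representations, make_resting_series


class TestZscore:
    def test_closed_form(self):
        series = RestingSeries(data=np.array([[1.0], [2.0], [3.0]]))
        z = zscore_voxels(series)
        expected = np.array([-1.0, 0.0, 1.0]) * np.sqrt(1.5)  # ddof 0
        np.testing.assert_allclose(z.data[:, 0], expected, atol=1e-12)
        assert z.zscored

    def test_idempotent(self, rng):
        series = zscore_voxels(RestingSeries(data=rng.normal(size=(50, 8))))
        again = zscore_voxels(series)
        np.testing.assert_allclose(series.data, again.data, atol=1e-8)

    def test_constant_voxel_flagged_not_raised(self, rng):
        data = rng.normal(size=(20, 4))
        data[:, 2] = 7.0
        z = zscore_voxels(RestingSeries(data=data))
        assert z.degenerate.tolist() == [False, False, True, False]
        np.testing.assert_array_equal(z.data[:, 2], 0.0)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_voxels(RestingSeries(data=np.ones((10, 3))))


class TestPatternCorrelation:
    def _series(self, data):
        return RestingSeries(data=np.asarray(data, float), zscored=True)

    def test_exact_match_and_flip(self, rng):
        p = rng.normal(size=20)
        series = self._series([p, -p, rng.normal(size=20)])
        r = pattern_correlation_timecourse(series, p)
        assert r[0] == pytest.approx(1.0, abs=1e-12)
        assert r[1] == pytest.approx(-1.0, abs=1e-12)
        assert -1 <= r[2] <= 1

    def test_orthogonalized_frame_is_zero(self, rng):
        p = rng.normal(size=50)
        f = rng.normal(size=50)
        pc = p - p.mean()
        fc = f - f.mean()
        f_orth = fc - (fc @ pc) / (pc @ pc) * pc  # Gram-Schmidt against p
        r = pattern_correlation_timecourse(self._series([f_orth]), p)
        assert abs(r[0]) < 1e-10

    def test_zero_variance_frame_is_missing(self, rng):
        p = rng.normal(size=10)
        series = self._series([np.full(10, 3.3), rng.normal(size=10)])
        r = pattern_correlation_timecourse(series, p)
        assert np.isnan(r[0]) and np.isfinite(r[1])

    def test_too_few_shared_voxels(self, rng):
        series = RestingSeries(
            data=rng.normal(size=(5, 4)),
            zscored=True,
            degenerate=np.array([False, False, True, True]),
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            pattern_correlation_timecourse(series, rng.normal(size=4))


class TestFisher:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert float(fisher_z(np.tanh(0.5))) == pytest.approx(0.5, abs=1e-12)

    @given(st.floats(-0.999, 0.999))
    def test_odd_and_invertible(self, r):
        assert float(fisher_z(-r)) == pytest.approx(-float(fisher_z(r)), abs=1e-12)
        assert float(inverse_fisher(fisher_z(r))) == pytest.approx(r, abs=1e-12)

    def test_clamped_at_unity(self):
        assert np.isfinite(fisher_z(1.0)) and np.isfinite(fisher_z(-1.0))
        assert float(fisher_z(1.0)) > 13.0  # arctanh(1 - 1e-12)

    def test_nan_propagates(self):
        assert np.isnan(fisher_z(np.nan))


class TestTopnMean:
    def test_worked_examples(self):
        z = [0.5, 0.4, 0.3, 0.2]
        assert topn_mean(z, 2) == pytest.approx(0.45)
        assert topn_mean(z, 4) == pytest.approx(np.mean(z))

    def test_matches_sort_oracle(self, rng):
        for _ in range(200):
            z = rng.normal(size=rng.integers(5, 60))
            n = int(rng.integers(1, z.size + 1))
            oracle = float(np.sort(z)[::-1][:n].mean())
            assert topn_mean(z, n) == oracle

    def test_excess_n_errors_not_truncates(self):
        with pytest.raises(ValueError, match="exceeds"):
            topn_mean([0.1, 0.2], 3)
        with pytest.raises(ValueError):
            topn_mean([np.nan, 0.2, 0.3], 3)  # NaN does not count as available

    @given(st.lists(st.floats(-3, 3), min_size=4, max_size=30))
    def test_monotone_nonincreasing_in_n(self, z):
        vals = [topn_mean(z, n) for n in range(1, len(z) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_frame_order_invariance(self, rng):
        z = rng.normal(size=40)
        assert topn_mean(z, 7) == topn_mean(rng.permutation(z), 7)


class TestIntensity:
    def test_record_count_and_composition(self, rng):
        reps = [RepresentationMap(i, rng.normal(size=30)) for i in range(20)]
        series = RestingSeries(data=rng.normal(size=(50, 30)), session="day2pre")
        tab = intensity_table(series, reps, n_top=10)
        assert len(tab) == 20
        assert set(tab["session"]) == {"day2pre"}
        # composition check: manual chain for one sentence
        z = fisher_z(
            pattern_correlation_timecourse(zscore_voxels(series), reps[3])
        )
        assert tab["intensity"].iloc[3] == pytest.approx(topn_mean(z, 10), abs=1e-12)

    def test_amplitude_recovery(self, roi_mask, rng):
        """Planted increasing amplitudes must rank-order the intensities."""
        from scipy.stats import spearmanr

        spec = SyntheticSpec()
        reps = make_representations(20, roi_mask, seed=5)
        amps = np.linspace(3, 14, 20)
        series, _ = make_resting_series(reps, spec, amps, seed=6)
        tab = intensity_table(series, reps, n_top=9)
        assert spearmanr(tab["intensity"], amps).statistic > 0.8

    def test_affine_invariance(self, rng):
        """Positive affine rescaling of data and template leaves intensity."""
        reps = [RepresentationMap(0, rng.normal(size=25))]
        data = rng.normal(size=(40, 25))
        t1 = intensity_table(RestingSeries(data=data), reps, n_top=5)
        reps2 = [RepresentationMap(0, 3.0 * reps[0].values + 11.0)]
        t2 = intensity_table(RestingSeries(data=0.5 * data - 2.0), reps2, n_top=5)
        assert t1["intensity"].iloc[0] == pytest.approx(
            t2["intensity"].iloc[0], abs=1e-9
        )

    def test_scorer_sklearn_interface(self, rng):
        scorer = ReactivationScorer(n_top=4)
        assert scorer.get_params() == {"n_top": 4}
        T = rng.normal(size=(3, 20))
        out = scorer.fit(T).transform(rng.normal(size=(30, 20)))
        assert out.shape == (3,)


class TestNtopSelection:
    def test_pure_noise_curve_returns_smallest(self):
        grid = np.arange(10, 81, 5)
        curve = 0.7 / grid + 0.01  # exactly a/N + c: residuals vanish
        sel = NtopSelector(grid=grid).fit_variance_curve(grid, curve)
        assert sel.n_top_ == 10

    def test_bump_is_found(self):
        grid = np.arange(10, 81, 5)
        curve = 0.7 / grid + 0.01
        curve[grid == 15] += 0.05
        sel = NtopSelector(grid=grid).fit_variance_curve(grid, curve)
        assert sel.n_top_ == 15

    def test_embedded_frames_set_the_scale(self, roi_mask):
        """With 15 planted frames per sentence the selector lands near 15."""
        spec = SyntheticSpec(
            n_posterior=10, n_associated=5, reactivation_events_per_sentence=15
        )
        chosen = []
        for s in range(5):
            rng = np.random.default_rng(300 + s)
            reps = make_representations(10, roi_mask, seed=rng)
            amps = rng.normal(spec.amplitude_mean, spec.amplitude_sd, 10).clip(0)
            series, _ = make_resting_series(reps, spec, amps, seed=rng)
            chosen.append(estimate_ntop(series, reps, grid=range(10, 81, 5)).chosen)
        assert np.mean([c in (10, 15, 20) for c in chosen]) >= 0.8

    def test_group_aggregation_rounds_to_grid(self):
        grid = range(10, 81, 5)
        assert aggregate_ntop([15, 15, 15, 14], grid) == 15  # mean 14.75 -> 15
        assert aggregate_ntop([10, 15], grid) == 15  # midpoint 12.5 rounds up
        assert aggregate_ntop([45], grid) == 45

    def test_single_sentence_errors(self, rng):
        series = RestingSeries(data=rng.normal(size=(100, 20)))
        with pytest.raises(ValueError, match="2 sentences"):
            estimate_ntop(series, [RepresentationMap(0, rng.normal(size=20))],
                          grid=[10, 15, 20])

    def test_grid_beyond_frames_errors(self, rng):
        series = RestingSeries(data=rng.normal(size=(30, 20)))
        reps = [RepresentationMap(i, rng.normal(size=20)) for i in range(3)]
        with pytest.raises(ValueError, match="exceeds"):
            estimate_ntop(series, reps, grid=[10, 20, 40])
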