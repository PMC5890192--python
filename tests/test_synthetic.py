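"""Generator behavior: planted structure, determinism, on-disk cohort."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from preplay import (
    AssociationTable,
    SyntheticSpec,
    make_dataset,
    make_induced_sessions,
    make_ratings,
    make_representations,
    make_resting_series,
    pattern_correlation_timecourse,
    zscore_voxels,
)
from preplay.synthetic import ellipsoid_mask, make_associations


class TestSpecValidation:
    def test_defaults_are_valid(self):
        spec = SyntheticSpec()
        assert spec.n_subjects == 16
        assert spec.n_prior == 10 and spec.n_posterior == 20
        assert spec.n_rest_frames == 197 and spec.tr_seconds == 3.0
        # induced session geometry: 2 rest + 6 block + 1 response per trial,
        # 3 edge scans at each end
        assert spec.session_scans == {"prior": 96, "posterior": 186}

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_associated": 25},  # exceeds n_posterior
            {"rating_coupling_rho": 1.0},
            {"n_subjects": 0},
            {"noise_sd": -1.0},
            {"reactivation_events_per_sentence": 20},  # 20*20 > 197 frames
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticSpec(**kwargs)

    def test_spec_dict_roundtrip(self):
        spec = SyntheticSpec(seed=42, rating_coupling_rho=0.25)
        assert SyntheticSpec.from_dict(spec.to_dict()) == spec


class TestRepresentations:
    def test_unit_norm_and_count(self, roi_mask):
        reps = make_representations(2, roi_mask, seed=1)
        assert len(reps) == 2
        for r in reps:
            assert r.n_voxels == int(roi_mask.sum())
            assert np.linalg.norm(r.values) == pytest.approx(1.0, abs=1e-12)

    def test_same_seed_identical(self, roi_mask):
        a = make_representations(3, roi_mask, seed=7)
        b = make_representations(3, roi_mask, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_pairwise_correlations_near_zero(self):
        # expected value for 20 smooth patterns on ~300 voxels: |r| ~ 1/sqrt(V_eff)
        mask = np.ones((7, 7, 7), dtype=bool)  # 343 voxels
        reps = make_representations(20, mask, smooth_fwhm=1.0, seed=3)
        C = np.corrcoef(np.vstack([r.values for r in reps]))
        off = C[np.triu_indices(20, 1)]
        assert np.abs(off).mean() < 0.15

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            make_representations(2, np.zeros((4, 4, 4), dtype=bool), seed=0)


class TestRestingSeries:
    def test_embed_counts_match_budget(self, roi_mask):
        spec = SyntheticSpec(
            n_posterior=10, n_associated=5, reactivation_events_per_sentence=15
        )
        reps = make_representations(10, roi_mask, seed=2)
        series, log = make_resting_series(reps, spec, np.ones(10), seed=4)
        assert series.n_frames == 197
        assert len(log) == 150  # 15 events x 10 sentences
        assert log["frame"].nunique() == 150  # disjoint frames, 47 baseline
        assert log.groupby("sentence_id").size().eq(15).all()

    def test_zero_amplitude_is_pure_noise(self, roi_mask):
        spec = SyntheticSpec()
        reps = make_representations(5, roi_mask, seed=2)
        series, log = make_resting_series(reps, spec, np.zeros(5), seed=4)
        noise_only, _ = make_resting_series(reps, spec, np.zeros(5), seed=4)
        np.testing.assert_array_equal(series.data, noise_only.data)
        assert len(log) == 5 * spec.reactivation_events_per_sentence

    def test_strong_amplitude_gives_high_frame_correlation(self, roi_mask):
        spec = SyntheticSpec(noise_sd=1.0)
        reps = make_representations(3, roi_mask, seed=2)
        amp = 100.0  # far above noise_sd * sqrt(V)
        series, log = make_resting_series(reps, spec, [amp] * 3, seed=4)
        zs = zscore_voxels(series)
        for rep in reps:
            r = pattern_correlation_timecourse(zs, rep)
            frames = log.loc[log["sentence_id"] == rep.sentence_id, "frame"]
            assert (r[frames.to_numpy()] > 0.9).all()

    def test_frame_budget_enforced(self, roi_mask):
        # 9 events x 25 sentences = 225 > 197 frames
        spec = SyntheticSpec(n_rest_frames=197)
        reps25 = make_representations(25, roi_mask, seed=2)
        with pytest.raises(ValueError, match="exceed"):
            make_resting_series(reps25, spec, np.ones(25), seed=0)


class TestInducedSessions:
    def test_design_table_row_count(self, roi_mask):
        spec = SyntheticSpec(n_induced_sessions=5)
        reps = make_representations(10, roi_mask, seed=2)
        volumes, events = make_induced_sessions(reps, spec, seed=3)
        assert len(volumes) == 5
        assert len(events) == 50  # 10 sentences x 5 sessions
        assert volumes[0].shape == spec.roi_shape + (96,)

    def test_noiseless_blocks_proportional_to_regressor(self, roi_mask):
        spec = SyntheticSpec(noise_sd=0.0, n_induced_sessions=1)
        reps = make_representations(2, roi_mask, seed=2)
        volumes, events = make_induced_sessions(reps, spec, seed=3, hrf="none")
        data = volumes[0][roi_mask].T  # frames x voxels
        # with the identity kernel the signal is the boxcar itself: during
        # sentence blocks the frame equals amplitude * pattern exactly
        for _, ev in events.iterrows():
            rep = reps[int(ev["sentence_id"])]
            start = int(ev["onset"] / spec.tr_seconds)
            frame = data[start]
            np.testing.assert_allclose(
                frame, spec.induced_amplitude * rep.values, atol=1e-10
            )


class TestAssociationsAndRatings:
    def test_association_table_valid(self, rng):
        spec = SyntheticSpec()
        assoc = make_associations(spec, rng)
        assert len(assoc.table) == spec.n_posterior
        assert 1 <= assoc.n_associated <= spec.n_posterior

    def test_duplicate_posterior_rejected(self):
        df = pd.DataFrame({"posterior_id": [0, 0], "prior_id": [1, 2]})
        with pytest.raises(ValueError, match="exactly once"):
            AssociationTable(df)

    def _all_associated(self, n):
        return AssociationTable(
            pd.DataFrame(
                {
                    "posterior_id": np.arange(n),
                    "prior_id": pd.array([0] * n, dtype="Int64"),
                }
            )
        )

    def test_ratings_bounded(self, rng):
        assoc = self._all_associated(50)
        ratings = make_ratings(rng.normal(size=50) * 100, assoc, 0.5, seed=rng)
        assert ratings["rating"].between(0, 100).all()

    def test_high_rho_gives_high_sample_correlation(self, rng):
        n = 1000
        assoc = self._all_associated(n)
        amps = rng.normal(size=n)
        ratings = make_ratings(amps, assoc, 0.99, seed=rng)
        assert np.corrcoef(amps, ratings["rating"])[0, 1] > 0.9

    def test_zero_rho_uncoupled(self, rng):
        n = 2000
        assoc = self._all_associated(n)
        amps = rng.normal(size=n)
        ratings = make_ratings(amps, assoc, 0.0, seed=rng)
        assert abs(np.corrcoef(amps, ratings["rating"])[0, 1]) < 0.08

    def test_non_associated_independent_of_amplitude(self, rng):
        n = 2000
        assoc = AssociationTable(
            pd.DataFrame(
                {
                    "posterior_id": np.arange(n),
                    "prior_id": pd.array([pd.NA] * n, dtype="Int64"),
                }
            )
        )
        amps = rng.normal(size=n)
        ratings = make_ratings(amps, assoc, 0.9, seed=rng)
        assert abs(np.corrcoef(amps, ratings["rating"])[0, 1]) < 0.08


def _tree_checksums(root: Path) -> dict:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


class TestDataset:
    def test_cohort_layout_and_manifest(self, tiny_spec, tmp_path):
        manifest = make_dataset(tiny_spec, tmp_path / "ds")
        assert len(manifest["subjects"]) == tiny_spec.n_subjects
        for sub in manifest["subjects"]:
            d = tmp_path / "ds" / sub
            assert (d / "rest_day1.nii").exists()
            assert (d / "rest_day2pre.nii").exists()
            assert (d / "rest_day2post.nii").exists()
            assert (d / "ratings.tsv").exists()
            truth = json.loads((d / "truth.json").read_text())
            assert len(truth["amplitudes_posterior"]) == tiny_spec.n_posterior
        spec2 = SyntheticSpec.from_dict(manifest["spec"])
        assert spec2 == tiny_spec

    def test_regeneration_is_byte_identical(self, tiny_spec, tmp_path):
        make_dataset(tiny_spec, tmp_path / "a")
        make_dataset(tiny_spec, tmp_path / "b")
        assert _tree_checksums(tmp_path / "a") == _tree_checksums(tmp_path / "b")

    def test_different_seed_differs(self, tiny_spec, tmp_path):
        from dataclasses import replace

        make_dataset(tiny_spec, tmp_path / "a")
        make_dataset(replace(tiny_spec, seed=99), tmp_path / "b")
        assert _tree_checksums(tmp_path / "a") != _tree_checksums(tmp_path / "b")
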