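"""Synthetic multi-subject cohorts with planted reactivation structure.

Emulates the structure of a two-day sentence-comprehension study: each
subject has 10 "prior" and 20 "posterior" sentences, a subject-specific
association map (on average ~11 posterior sentences linked to a prior
sentence), three resting sessions (Day 1, Day 2 pre, Day 2 post) of 197
retained frames at TR 3 s, and block-design induced sessions from which
sentence representations are estimated.  Reactivation is modelled as
additive injection of a sentence's unit-norm pattern into single resting
frames; understanding ratings are coupled to the planted reactivation
amplitude only for associated sentences.

Everything is driven by a :class:`SyntheticSpec` and a seed; a fixed seed
reproduces the on-disk dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .representation import RepresentationMap, hrf_kernel
from .rsa import RestingSeries

__all__ = [
    "SyntheticSpec",
    "AssociationTable",
    "make_associations",
    "make_representations",
    "make_resting_series",
    "make_induced_sessions",
    "make_ratings",
    "make_rating_cohort",
    "make_searchlight_cohort",
    "make_dataset",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a simulated cohort.

    Counts and session geometry follow the emulated study (16 subjects,
    10 prior / 20 posterior sentences, ~11 associated per subject, 197
    retained resting frames at TR 3 s, five induced sessions per sentence
    set with 2 rest / 6 sentence / 1 response scans per trial and 3 edge
    scans).  Amplitudes are in arbitrary BOLD signal units relative to a
    unit-norm spatial pattern and ``noise_sd``.
    """

    n_subjects: int = 16
    n_prior: int = 10
    n_posterior: int = 20
    n_associated: int = 11
    n_associated_sd: float = 1.5
    roi_shape: tuple[int, int, int] = (8, 8, 8)
    n_rest_frames: int = 197
    n_discard_frames: int = 3
    tr_seconds: float = 3.0
    n_induced_sessions: int = 5
    block_scans: int = 6
    rest_scans: int = 2
    response_scans: int = 1
    edge_scans: int = 3
    reactivation_events_per_sentence: int = 9
    amplitude_mean: float = 8.0
    amplitude_sd: float = 2.5
    induced_amplitude: float = 15.0
    noise_sd: float = 1.0
    rating_coupling_rho: float = 0.4
    rating_scale: tuple[float, float] = (0.0, 100.0)
    day2post_gain: float = 1.5
    smooth_fwhm: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_prior": self.n_prior,
            "n_posterior": self.n_posterior,
            "n_associated": self.n_associated,
            "n_rest_frames": self.n_rest_frames,
            "n_induced_sessions": self.n_induced_sessions,
            "block_scans": self.block_scans,
            "reactivation_events_per_sentence": self.reactivation_events_per_sentence,
        }
        for name, v in counts.items():
            if int(v) <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_associated > self.n_posterior:
            raise ValueError("n_associated cannot exceed n_posterior")
        if not abs(self.rating_coupling_rho) < 1:
            raise ValueError("|rating_coupling_rho| must be < 1")
        if self.noise_sd < 0 or self.amplitude_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        k = self.reactivation_events_per_sentence
        if k * max(self.n_prior, self.n_posterior) > self.n_rest_frames:
            raise ValueError(
                "reactivation events per sentence x sentences exceeds the "
                "resting frame budget"
            )

    @property
    def session_scans(self) -> dict[str, int]:
        """Scans per induced session for each sentence set."""
        per_trial = self.rest_scans + self.block_scans + self.response_scans
        return {
            "prior": 2 * self.edge_scans + self.n_prior * per_trial,
            "posterior": 2 * self.edge_scans + self.n_posterior * per_trial,
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roi_shape"] = list(self.roi_shape)
        d["rating_scale"] = list(self.rating_scale)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticSpec":
        d = dict(d)
        d["roi_shape"] = tuple(d["roi_shape"])
        d["rating_scale"] = tuple(d["rating_scale"])
        return cls(**d)


@dataclass
class AssociationTable:
    """Per-subject map from posterior sentences to prior sentences (or N/A).

    Each posterior id appears exactly once; prior ids may repeat (several
    posterior sentences can share one prior answer).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        cols = {"posterior_id", "prior_id"}
        if not cols <= set(self.table.columns):
            raise ValueError("association table needs posterior_id and prior_id")
        if self.table["posterior_id"].duplicated().any():
            raise ValueError("each posterior id must appear exactly once")
        self.table = self.table.reset_index(drop=True)

    @property
    def associated_mask(self) -> np.ndarray:
        return self.table["prior_id"].notna().to_numpy()

    @property
    def posterior_ids(self) -> np.ndarray:
        return self.table["posterior_id"].to_numpy()

    @property
    def n_associated(self) -> int:
        return int(self.associated_mask.sum())


def make_associations(spec: SyntheticSpec, rng: np.random.Generator) -> AssociationTable:
    """Draw one subject's association map.

    The number of associated posterior sentences is a rounded normal draw
    around ``spec.n_associated`` (sd ``n_associated_sd``), clipped to
    [1, n_posterior]; each associated sentence is linked to a uniformly
    drawn prior sentence, repeats allowed.
    """
    n_assoc = int(np.clip(round(rng.normal(spec.n_associated, spec.n_associated_sd)),
                          1, spec.n_posterior))
    chosen = np.sort(rng.choice(spec.n_posterior, size=n_assoc, replace=False))
    prior = pd.array([pd.NA] * spec.n_posterior, dtype="Int64")
    prior[chosen] = rng.integers(0, spec.n_prior, size=n_assoc)
    return AssociationTable(
        pd.DataFrame({"posterior_id": np.arange(spec.n_posterior), "prior_id": prior})
    )


def ellipsoid_mask(shape: Sequence[int]) -> np.ndarray:
    """Inscribed-ellipsoid ROI mask for a voxel grid."""
    shape = tuple(int(s) for s in shape)
    grids = np.indices(shape).astype(float)
    centers = [(s - 1) / 2.0 for s in shape]
    semi = [max(s / 2.0, 0.5) for s in shape]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centers, semi))
    return d2 <= 1.0


def make_representations(
    n_sentences: int,
    roi_mask: np.ndarray,
    smooth_fwhm: float = 1.5,
    seed: int | np.random.Generator = 0,
) -> list[RepresentationMap]:
    """Random smooth unit-norm voxel patterns, one per sentence.

    Patterns are spatially smoothed Gaussian fields, centered and scaled
    to unit norm over the masked voxels; with enough voxels their pairwise
    correlations concentrate near zero (roughly 1/sqrt(V) scaling), which
    is what the similarity statistic assumes of distinct sentences.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty ROI mask")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = smooth_fwhm * _FWHM_TO_SIGMA
    reps = []
    for sid in range(int(n_sentences)):
        vol = rng.normal(size=mask.shape)
        if sigma > 0:
            vol = gaussian_filter(vol, sigma=sigma)
        v = vol[mask]
        v = v - v.mean()
        norm = np.linalg.norm(v)
        if norm == 0:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("degenerate zero pattern")
        reps.append(RepresentationMap(sentence_id=sid, values=v / norm, mask=mask))
    return reps


def make_resting_series(
    reps: Sequence[RepresentationMap],
    spec: SyntheticSpec,
    amplitudes: Sequence[float],
    seed: int | np.random.Generator = 0,
    session: str = "",
) -> tuple[RestingSeries, pd.DataFrame]:
    """Resting frames with sentence patterns injected at random frames.

    Baseline frames are i.i.d. Gaussian noise; for every sentence, exactly
    ``spec.reactivation_events_per_sentence`` distinct frames (disjoint
    across sentences) receive an additive ``amplitude * pattern`` term on
    top of the noise.  Returns the series and an embed log listing which
    frame carries which sentence.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size != len(reps):
        raise ValueError("one amplitude per representation required")
    k = spec.reactivation_events_per_sentence
    n_frames = spec.n_rest_frames
    if k * len(reps) > n_frames:
        raise ValueError(
            f"{k} events x {len(reps)} sentences exceed {n_frames} frames"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V = reps[0].n_voxels
    data = rng.normal(0.0, spec.noise_sd, size=(n_frames, V))
    slots = rng.permutation(n_frames)[: k * len(reps)]
    log_rows = []
    for i, rep in enumerate(reps):
        frames = np.sort(slots[i * k : (i + 1) * k])
        data[frames] += amplitudes[i] * rep.values
        for f in frames:
            log_rows.append({"sentence_id": rep.sentence_id, "frame": int(f)})
    series = RestingSeries(data=data, mask=reps[0].mask, session=session)
    return series, pd.DataFrame(log_rows)


def make_induced_sessions(
    reps: Sequence[RepresentationMap],
    spec: SyntheticSpec,
    seed: int | np.random.Generator = 0,
    hrf: str = "glover",
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Block-design task sessions and their event table.

    Every session presents each sentence in one block (order shuffled per
    session): per trial, ``rest_scans`` rest, ``block_scans`` of sentence
    presentation, ``response_scans`` response; ``edge_scans`` of rest pad
    each end.  The signal is the HRF-convolved block boxcar times
    ``induced_amplitude`` times the sentence pattern, plus Gaussian noise.
    Returns 4-D (x, y, z, t) volumes and a long event table with columns
    onset, duration, sentence_id, session.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = reps[0].mask
    if mask is None:
        raise ValueError("representations need a mask to build volumes")
    tr = spec.tr_seconds
    per_trial = spec.rest_scans + spec.block_scans + spec.response_scans
    n_frames = 2 * spec.edge_scans + len(reps) * per_trial
    kernel = hrf_kernel(tr, hrf)
    P = np.vstack([r.values for r in reps])  # sentences x voxels

    volumes, rows = [], []
    for ses in range(spec.n_induced_sessions):
        order = rng.permutation(len(reps))
        signal = np.zeros((n_frames, P.shape[1]))
        for trial, idx in enumerate(order):
            onset_scan = spec.edge_scans + trial * per_trial + spec.rest_scans
            box = np.zeros(n_frames)
            box[onset_scan : onset_scan + spec.block_scans] = 1.0
            reg = np.convolve(box, kernel)[:n_frames]
            signal += np.outer(reg, spec.induced_amplitude * P[idx])
            rows.append(
                {
                    "onset": onset_scan * tr,
                    "duration": spec.block_scans * tr,
                    "sentence_id": reps[idx].sentence_id,
                    "session": ses,
                }
            )
        vol = rng.normal(0.0, spec.noise_sd, size=mask.shape + (n_frames,))
        vol[mask] += signal.T
        volumes.append(vol)
    events = pd.DataFrame(rows).sort_values(["session", "onset"]).reset_index(drop=True)
    return volumes, events


def _latent_to_rating(latent: np.ndarray, scale: tuple[float, float]) -> np.ndarray:
    lo, hi = scale
    center = 0.5 * (lo + hi)
    spread = 0.15 * (hi - lo)
    return np.clip(center + spread * latent, lo, hi)


def make_ratings(
    amplitudes: Sequence[float],
    association: AssociationTable,
    rho: float,
    scale: tuple[float, float] = (0.0, 100.0),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Understanding ratings coupled to amplitude only where associated.

    For associated posterior sentences the latent rating is
    ``rho * standardized(amplitude) + sqrt(1 - rho^2) * noise``; for
    non-associated sentences it is independent noise.  Latents are mapped
    affinely onto the rating scale and clamped to its bounds.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    amplitudes = np.asarray(amplitudes, dtype=float)
    n = len(association.table)
    if amplitudes.size != n:
        raise ValueError("one amplitude per posterior sentence required")
    assoc = association.associated_mask
    latent = rng.normal(size=n)
    if assoc.sum() >= 2 and amplitudes[assoc].std() > 0:
        z = (amplitudes[assoc] - amplitudes[assoc].mean()) / amplitudes[assoc].std()
        latent[assoc] = rho * z + np.sqrt(1.0 - rho**2) * latent[assoc]
    return pd.DataFrame(
        {
            "sentence_id": association.posterior_ids,
            "rating": _latent_to_rating(latent, scale),
            "associated": assoc,
        }
    )


def make_rating_cohort(
    n_subjects: int,
    n_sentences: int,
    rho: float,
    seed: int | np.random.Generator = 0,
    scale: tuple[float, float] = (0.0, 100.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort of (intensity, rating) tables at the statistics level.

    Per subject, standard-normal "intensities" stand in for measured
    reactivation and ratings are generated with the coupling model used by
    :func:`make_ratings` (every sentence associated).  Useful for studying
    the calibration and power of the merged-correlation machinery without
    simulating any imaging.  Returns (intensity table, ratings table) with
    a ``subject`` column each.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    assoc = AssociationTable(
        pd.DataFrame(
            {
                "posterior_id": np.arange(n_sentences),
                "prior_id": pd.array([0] * n_sentences, dtype="Int64"),
            }
        )
    )
    intens_rows, rating_frames = [], []
    for sub in range(n_subjects):
        amps = rng.normal(size=n_sentences)
        ratings = make_ratings(amps, assoc, rho, scale=scale, seed=rng)
        ratings.insert(0, "subject", sub)
        rating_frames.append(ratings)
        for sid, a in zip(assoc.posterior_ids, amps):
            intens_rows.append({"subject": sub, "sentence_id": sid, "intensity": a})
    return pd.DataFrame(intens_rows), pd.concat(rating_frames, ignore_index=True)


def make_searchlight_cohort(
    n_subjects: int,
    shape: tuple[int, int, int],
    region: np.ndarray,
    n_sentences: int = 20,
    n_associated: int = 10,
    rho: float = 0.9,
    amplitude_mean: float = 24.0,
    amplitude_sd: float = 7.5,
    n_frames: int = 80,
    events_per_sentence: int = 4,
    noise_sd: float = 1.0,
    template_noise_sd: float = 0.05,
    smooth_fwhm: float = 1.5,
    seed: int | np.random.Generator = 0,
) -> list[dict]:
    """Whole-volume subjects with reactivation confined to one region.

    For each subject, sentence patterns are restricted to ``region`` (a
    boolean volume), renormalized, and injected into resting frames; the
    sentence templates are the region-restricted patterns plus weak
    Gaussian noise everywhere (mimicking t-map noise outside the truly
    responsive region).  Ratings couple to amplitude (coefficient ``rho``)
    only for the first ``n_associated`` sentences.  Set ``rho = 0`` for a
    null cohort.  Returns one dict per subject with keys ``rest4d``,
    ``tmaps4d``, ``ratings``, ``associated``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    region = np.asarray(region, dtype=bool)
    if region.shape != tuple(shape):
        raise ValueError("region shape must match the volume shape")
    if not 0 < n_associated < n_sentences:
        raise ValueError("need sentences in both conditions")
    mask = np.ones(shape, dtype=bool)
    regflat = region[mask]
    subjects = []
    for _ in range(int(n_subjects)):
        reps = make_representations(n_sentences, mask, smooth_fwhm, rng)
        P = np.vstack([r.values for r in reps])
        restricted = P * regflat
        norms = np.linalg.norm(restricted, axis=1, keepdims=True)
        restricted = restricted / norms
        amps = np.clip(
            rng.normal(amplitude_mean, amplitude_sd, n_sentences), 0.0, None
        )
        data = rng.normal(0.0, noise_sd, size=(n_frames, int(mask.sum())))
        slots = rng.permutation(n_frames)[: events_per_sentence * n_sentences]
        for i in range(n_sentences):
            frames = slots[i * events_per_sentence : (i + 1) * events_per_sentence]
            data[frames] += amps[i] * restricted[i]
        rest4d = np.zeros(shape + (n_frames,))
        rest4d[mask] = data.T
        tmaps4d = np.zeros(shape + (n_sentences,))
        tmaps4d[mask] = restricted.T
        tmaps4d += rng.normal(0.0, template_noise_sd, tmaps4d.shape)
        associated = np.zeros(n_sentences, dtype=bool)
        associated[:n_associated] = True
        latent = rng.normal(size=n_sentences)
        if rho != 0:
            a = associated
            za = (amps[a] - amps[a].mean()) / amps[a].std()
            latent[a] = rho * za + np.sqrt(1 - rho**2) * latent[a]
        subjects.append(
            {
                "rest4d": rest4d,
                "tmaps4d": tmaps4d,
                "ratings": _latent_to_rating(latent, (0.0, 100.0)),
                "associated": associated,
            }
        )
    return subjects


def _save_nifti(path: Path, data: np.ndarray, voxel_mm: float = 3.0) -> None:
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="N/A")


def make_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write a full multi-subject cohort to disk and return the manifest.

    Per subject: ROI mask, three resting sessions (Day 1 with prior
    patterns embedded, Day 2 pre with posterior patterns, Day 2 post with
    gain-scaled posterior patterns; each with ``n_discard_frames`` pure
    lead-in frames prepended), induced sessions for both sentence sets
    with event tables, ratings, associations, and a ground-truth record
    (planted amplitudes and embed logs, frame indices counted after the
    lead-in).  Uncompressed NIfTI-1 is used throughout so a fixed seed
    gives byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(spec.seed)
    subject_seeds = root_ss.spawn(spec.n_subjects)
    mask = ellipsoid_mask(spec.roi_shape)
    subjects = []

    for si, sub_ss in enumerate(subject_seeds):
        sub = f"sub-{si + 1:02d}"
        sub_dir = out / sub
        sub_dir.mkdir(exist_ok=True)
        streams = {
            name: np.random.default_rng(child)
            for name, child in zip(
                ["assoc", "rep_prior", "rep_post", "amp", "rest", "induced",
                 "ratings", "leadin"],
                sub_ss.spawn(8),
            )
        }
        association = make_associations(spec, streams["assoc"])
        reps_prior = make_representations(
            spec.n_prior, mask, spec.smooth_fwhm, streams["rep_prior"]
        )
        reps_post = make_representations(
            spec.n_posterior, mask, spec.smooth_fwhm, streams["rep_post"]
        )
        amp_prior = streams["amp"].normal(
            spec.amplitude_mean, spec.amplitude_sd, spec.n_prior
        )
        amp_post = streams["amp"].normal(
            spec.amplitude_mean, spec.amplitude_sd, spec.n_posterior
        )
        amp_prior = np.clip(amp_prior, 0.0, None)
        amp_post = np.clip(amp_post, 0.0, None)

        sessions = {
            "day1": (reps_prior, amp_prior),
            "day2pre": (reps_post, amp_post),
            "day2post": (reps_post, spec.day2post_gain * amp_post),
        }
        embed_logs = {}
        for name, (reps, amps) in sessions.items():
            series, log = make_resting_series(
                reps, spec, amps, streams["rest"], session=name
            )
            leadin = streams["leadin"].normal(
                0.0, spec.noise_sd, size=(spec.n_discard_frames, series.n_voxels)
            )
            full = np.vstack([leadin, series.data])
            vol = np.zeros(mask.shape + (full.shape[0],), dtype=float)
            vol[mask] = full.T
            _save_nifti(sub_dir / f"rest_{name}.nii", vol)
            embed_logs[name] = log.to_dict(orient="records")

        for set_name, reps in (("prior", reps_prior), ("posterior", reps_post)):
            volumes, events = make_induced_sessions(reps, spec, streams["induced"])
            for ses, vol in enumerate(volumes):
                _save_nifti(sub_dir / f"induced_{set_name}_run-{ses + 1}.nii", vol)
            _write_tsv(sub_dir / f"events_{set_name}.tsv", events)

        post_ratings = make_ratings(
            amp_post,
            association,
            spec.rating_coupling_rho,
            spec.rating_scale,
            streams["ratings"],
        )
        prior_ratings = pd.DataFrame(
            {
                "sentence_id": np.arange(spec.n_prior),
                "rating": _latent_to_rating(
                    streams["ratings"].normal(size=spec.n_prior), spec.rating_scale
                ),
                "associated": False,
            }
        )
        ratings = pd.concat(
            [prior_ratings.assign(set="prior"), post_ratings.assign(set="posterior")],
            ignore_index=True,
        )[["set", "sentence_id", "rating", "associated"]]
        _write_tsv(sub_dir / "ratings.tsv", ratings)
        _write_tsv(sub_dir / "associations.tsv", association.table)
        _save_nifti(sub_dir / "mask.nii", mask.astype(np.float32))

        truth = {
            "subject": sub,
            "n_associated": association.n_associated,
            "amplitudes_prior": amp_prior.tolist(),
            "amplitudes_posterior": amp_post.tolist(),
            "day2post_gain": spec.day2post_gain,
            "embed_logs": embed_logs,
        }
        (sub_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        subjects.append(sub)

    manifest = {
        "spec": spec.to_dict(),
        "subjects": subjects,
        "rest_sessions": ["day1", "day2pre", "day2post"],
        "sentence_sets": {"prior": spec.n_prior, "posterior": spec.n_posterior},
        "n_discard_frames": spec.n_discard_frames,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
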