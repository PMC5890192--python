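"""Per-sentence neural representations from stimulus-induced sessions.

A sentence's neural representation is the t-statistic map of its
HRF-convolved block regressor in a first-level GLM fitted to the induced
(task) sessions, restricted to an ROI mask.  Sessions are combined by
concatenating frames, sharing one task regressor per sentence across
sessions and giving each session its own intercept.  A variance-based
filter then removes the least informative voxels (those whose t-values
barely change across sentences) before any similarity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from nilearn.glm.contrasts import compute_contrast
from nilearn.glm.first_level import run_glm
from nilearn.glm.first_level.hemodynamic_models import glover_hrf, spm_hrf
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RepresentationMap",
    "DesignMatrix",
    "hrf_kernel",
    "build_design_matrix",
    "concatenate_designs",
    "fit_glm_tmaps",
    "InformativeVoxelFilter",
    "select_informative_voxels",
]


@dataclass
class RepresentationMap:
    """t-statistic voxel pattern of one sentence over a masked ROI.

    ``values`` holds one value per in-mask voxel, in C order of the mask;
    ``mask`` is the 3-D boolean ROI (or None for abstract/flat use).
    """

    sentence_id: object
    values: np.ndarray
    mask: np.ndarray | None = None
    source: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in representation {self.sentence_id!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if int(self.mask.sum()) != self.values.size:
                raise ValueError("mask voxel count does not match values length")

    @property
    def n_voxels(self) -> int:
        return self.values.size

    def to_volume(self, fill: float = np.nan) -> np.ndarray:
        """Embed the masked values back into a 3-D volume."""
        if self.mask is None:
            raise ValueError("representation has no mask")
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = self.values
        return vol


@dataclass
class DesignMatrix:
    """First-level design: frames x regressors, labelled columns."""

    matrix: np.ndarray
    columns: list[str]
    task_columns: list[str]
    task_ids: list = field(default_factory=list)
    frame_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("column labels do not match matrix width")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


def hrf_kernel(tr: float, model: str = "glover", time_length: float = 32.0) -> np.ndarray:
    """Hemodynamic response kernel sampled at the TR.

    ``model`` is ``'glover'`` or ``'spm'`` (canonical double-gamma shapes)
    or ``'none'`` for an identity kernel (no convolution), which is useful
    for exact construction tests.
    """
    if model == "none":
        return np.array([1.0])
    if model == "glover":
        return glover_hrf(tr, oversampling=1, time_length=time_length)
    if model == "spm":
        return spm_hrf(tr, oversampling=1, time_length=time_length)
    raise ValueError(f"unknown HRF model {model!r}")


def _boxcar(onset: float, duration: float, n_frames: int, tr: float) -> np.ndarray:
    t = np.arange(n_frames) * tr
    return ((t >= onset - 1e-9) & (t < onset + duration - 1e-9)).astype(float)


def build_design_matrix(
    events: pd.DataFrame,
    n_frames: int,
    tr: float,
    hrf: str = "glover",
) -> DesignMatrix:
    """Build a single-session design with one convolved column per sentence.

    ``events`` needs columns ``onset`` and ``duration`` (seconds) and
    ``sentence_id``.  Each sentence's boxcar (possibly spanning several
    events) is convolved with the HRF kernel and truncated to the session
    length; an intercept column is appended.  Raises if any event extends
    past the session or if the result is rank deficient.
    """
    required = {"onset", "duration", "sentence_id"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    session_end = n_frames * tr
    late = events[events["onset"] + events["duration"] > session_end + 1e-9]
    if len(late):
        raise ValueError(
            f"{len(late)} event(s) extend past the session end ({session_end:g} s); "
            f"first offender: sentence {late.iloc[0]['sentence_id']!r} "
            f"onset {late.iloc[0]['onset']:g} s"
        )
    if (events["onset"] < -1e-9).any():
        raise ValueError("negative event onset")

    kernel = hrf_kernel(tr, hrf)
    sentence_ids = sorted(events["sentence_id"].unique())
    cols = []
    for sid in sentence_ids:
        box = np.zeros(n_frames)
        for _, ev in events[events["sentence_id"] == sid].iterrows():
            box += _boxcar(float(ev["onset"]), float(ev["duration"]), n_frames, tr)
        cols.append(np.convolve(box, kernel)[:n_frames])
    task_names = [f"sentence_{sid}" for sid in sentence_ids]
    matrix = np.column_stack(cols + [np.ones(n_frames)])
    design = DesignMatrix(
        matrix=matrix,
        columns=task_names + ["intercept"],
        task_columns=task_names,
        task_ids=list(sentence_ids),
        frame_times=np.arange(n_frames) * tr,
    )
    _check_rank(design)
    return design


def _check_rank(design: DesignMatrix) -> None:
    rank = np.linalg.matrix_rank(design.matrix)
    if rank < design.matrix.shape[1]:
        # name near-collinear column pairs to aid diagnosis
        X = design.matrix - design.matrix.mean(axis=0)
        norms = np.linalg.norm(X, axis=0)
        norms[norms == 0] = 1.0
        C = (X / norms).T @ (X / norms)
        bad = [
            (design.columns[i], design.columns[j])
            for i in range(C.shape[0])
            for j in range(i + 1, C.shape[1])
            if abs(C[i, j]) > 0.999
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def concatenate_designs(designs: Sequence[DesignMatrix]) -> DesignMatrix:
    """Stack session designs: shared task columns, per-session intercepts.

    Task columns with the same label are aligned into one shared regressor
    (zero in sessions where the sentence does not occur); every session
    contributes its own intercept column.
    """
    if not designs:
        raise ValueError("no designs to concatenate")
    task_names: list[str] = []
    task_ids: list = []
    for d in designs:
        ids = d.task_ids if d.task_ids else [None] * len(d.task_columns)
        for name, tid in zip(d.task_columns, ids):
            if name not in task_names:
                task_names.append(name)
                task_ids.append(tid)
    n_total = sum(d.n_frames for d in designs)
    matrix = np.zeros((n_total, len(task_names) + len(designs)))
    row = 0
    for s, d in enumerate(designs):
        for name in d.task_columns:
            matrix[row : row + d.n_frames, task_names.index(name)] = d.matrix[
                :, d.columns.index(name)
            ]
        matrix[row : row + d.n_frames, len(task_names) + s] = 1.0
        row += d.n_frames
    columns = task_names + [f"intercept_ses{s}" for s in range(len(designs))]
    out = DesignMatrix(
        matrix=matrix, columns=columns, task_columns=task_names, task_ids=task_ids
    )
    _check_rank(out)
    return out


def fit_glm_tmaps(
    series: np.ndarray | Sequence[np.ndarray],
    design: DesignMatrix | Sequence[DesignMatrix],
    sentence_ids: Sequence | None = None,
    mask: np.ndarray | None = None,
    stat: str = "t",
) -> list[RepresentationMap]:
    """OLS first-level fit; one t-map per sentence regressor.

    ``series`` is a frames x voxels matrix (or a 4-D x,y,z,t volume with
    ``mask``), or a list of per-session series matched with a list of
    session designs, in which case sessions are concatenated with shared
    task regressors and per-session intercepts.  The t statistic at each
    voxel is the contrast estimate of the sentence regressor divided by
    its standard error under residual degrees of freedom; ``stat='beta'``
    returns the raw contrast estimate instead (useful for exactness checks).
    """
    if stat not in ("t", "beta"):
        raise ValueError("stat must be 't' or 'beta'")
    if isinstance(design, DesignMatrix):
        designs = [design]
        series_list = [series]
    else:
        designs = list(design)
        series_list = list(series)
        if len(designs) != len(series_list):
            raise ValueError("number of sessions and designs differ")

    mats = []
    for s in series_list:
        arr = np.asarray(s, dtype=float)
        if arr.ndim == 4:
            if mask is None:
                raise ValueError("4-D series requires a mask")
            arr = arr[np.asarray(mask, dtype=bool)].T  # frames x voxels
        mats.append(arr)

    big = concatenate_designs(designs) if len(designs) > 1 else designs[0]
    for m, d in zip(mats, designs):
        if m.shape[0] != d.n_frames:
            raise ValueError(f"series has {m.shape[0]} frames, design {d.n_frames}")
    Y = np.vstack(mats)
    X = big.matrix
    dof = Y.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError(f"non-positive residual dof ({dof})")

    task_cols = big.task_columns
    if sentence_ids is None:
        if big.task_ids and all(t is not None for t in big.task_ids):
            sentence_ids = list(big.task_ids)
        else:
            sentence_ids = [name.removeprefix("sentence_") for name in task_cols]
    if len(sentence_ids) != len(task_cols):
        raise ValueError("sentence_ids length does not match task regressors")

    labels, results = run_glm(Y, X, noise_model="ols")
    maps = []
    for k, (name, sid) in enumerate(zip(task_cols, sentence_ids)):
        con = np.zeros(X.shape[1])
        con[big.columns.index(name)] = 1.0
        contrast = compute_contrast(labels, results, con, stat_type="t")
        tvals = contrast.stat() if stat == "t" else contrast.effect_size()
        maps.append(
            RepresentationMap(
                sentence_id=sid,
                values=np.asarray(tvals, dtype=float),
                mask=None if mask is None else np.asarray(mask, dtype=bool),
                source=tuple(range(len(designs))),
            )
        )
    return maps


class InformativeVoxelFilter(TransformerMixin, BaseEstimator):
    """Drop the voxels whose t-values vary least across sentences.

    Fit on a (n_sentences, n_voxels) matrix of t-values.  The per-voxel
    population variance across sentences is computed and voxels strictly
    below the ``drop_fraction`` quantile of that variance distribution are
    removed; ties at the cutoff are kept, so the filter never removes more
    than the nominal fraction.  The fitted ``support_mask_`` applies to all
    sentences identically and is invariant to sentence order.

    Parameters
    ----------
    drop_fraction : float, default 0.03
        Fraction of voxels to discard from the low-variance tail.
    """

    def __init__(self, drop_fraction: float = 0.03):
        self.drop_fraction = drop_fraction

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a (n_sentences >= 2, n_voxels) matrix")
        if not 0.0 <= self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must be in [0, 1)")
        self.variances_ = X.var(axis=0, ddof=0)
        cutoff = np.quantile(self.variances_, self.drop_fraction)
        self.cutoff_ = float(cutoff)
        self.support_mask_ = ~(self.variances_ < cutoff)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError("voxel count differs from fit")
        return X[..., self.support_mask_]


def select_informative_voxels(
    tmaps: Sequence[RepresentationMap], drop_fraction: float = 0.03
) -> np.ndarray:
    """Boolean keep-mask over masked voxels from the t-variance filter."""
    X = np.vstack([m.values for m in tmaps])
    filt = InformativeVoxelFilter(drop_fraction=drop_fraction).fit(X)
    n_dropped = int((~filt.support_mask_).sum())
    if n_dropped == 0 and drop_fraction > 0:
        warnings.warn("variance filter removed no voxels (ties at the cutoff)")
    return filt.support_mask_
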