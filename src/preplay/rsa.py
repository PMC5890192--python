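"""Reactivation intensity: top-N Fisher-Z pattern similarity in rest data.

The statistic: z-score every voxel's resting time course, correlate each
frame's voxel pattern with a sentence's representation (t-map), Fisher
transform the per-frame correlations, and summarize each sentence's time
course by the mean of its N_top largest Z values.  N_top itself can be
estimated by decomposing the across-sentence variance of the intensity
into a noise part proportional to 1/N and a signal part (the residual of
that fit); the chosen N maximizes the signal part.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .representation import RepresentationMap

__all__ = [
    "RestingSeries",
    "NtopEstimate",
    "zscore_voxels",
    "pattern_correlation_timecourse",
    "fisher_z",
    "inverse_fisher",
    "topn_mean",
    "ReactivationScorer",
    "intensity_table",
    "NtopSelector",
    "estimate_ntop",
    "aggregate_ntop",
]

_CLAMP = 1.0 - 1e-12


@dataclass
class RestingSeries:
    """Frames x masked-voxels matrix from one resting session.

    ``degenerate`` flags constant voxels (excluded from correlations);
    ``zscored`` records whether voxel time courses have been standardized.
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    zscored: bool = False
    degenerate: np.ndarray | None = None
    session: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.degenerate is None:
            self.degenerate = np.zeros(self.data.shape[1], dtype=bool)
        else:
            self.degenerate = np.asarray(self.degenerate, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class NtopEstimate:
    """Variance decomposition over a grid of candidate N_top values."""

    grid: np.ndarray
    variance_curve: np.ndarray
    signal_curve: np.ndarray
    chosen: int
    noise_fit: tuple[float, float] = (0.0, 0.0)  # (slope on 1/N, intercept)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        self.variance_curve = np.asarray(self.variance_curve, dtype=float)
        self.signal_curve = np.asarray(self.signal_curve, dtype=float)
        if not (len(self.grid) == len(self.variance_curve) == len(self.signal_curve)):
            raise ValueError("grid and curves must have equal length")
        if self.chosen not in self.grid:
            raise ValueError("chosen N_top not on the grid")


def zscore_voxels(series: RestingSeries) -> RestingSeries:
    """Standardize each voxel's time course to mean 0, sd 1 (ddof 0).

    Constant voxels cannot be standardized; they are flagged degenerate
    (zeroed, excluded from correlations) rather than raising, unless every
    voxel is constant.  Idempotent on already-standardized input.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to z-score")
    data = series.data
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=0)
    scale = np.maximum(np.abs(mu), np.nanmax(np.abs(data), axis=0, initial=1.0))
    degen = sd <= 1e-12 * np.maximum(scale, 1.0)
    if degen.all():
        raise ValueError("all voxels are constant; nothing to standardize")
    out = np.zeros_like(data)
    ok = ~degen
    out[:, ok] = (data[:, ok] - mu[ok]) / sd[ok]
    return replace(
        series,
        data=out,
        zscored=True,
        degenerate=series.degenerate | degen,
    )


def pattern_correlation_timecourse(
    series: RestingSeries, rep: RepresentationMap | np.ndarray
) -> np.ndarray:
    """Pearson correlation of each frame's voxel pattern with a template.

    Uses the non-degenerate voxels shared by the series and the template;
    needs at least 3.  Frames with zero spatial variance get NaN (missing,
    excluded downstream).  Returns one correlation per frame, in [-1, 1].
    """
    values = rep.values if isinstance(rep, RepresentationMap) else np.asarray(rep, float)
    values = values.ravel()
    if values.size != series.n_voxels:
        raise ValueError(
            f"template has {values.size} voxels, series has {series.n_voxels}"
        )
    use = ~series.degenerate & np.isfinite(values)
    if int(use.sum()) < 3:
        raise ValueError("fewer than 3 shared usable voxels")
    p = values[use]
    p_c = p - p.mean()
    p_norm = np.linalg.norm(p_c)
    if p_norm == 0:
        raise ValueError("template has zero spatial variance over shared voxels")
    F = series.data[:, use]
    F_c = F - F.mean(axis=1, keepdims=True)
    f_norm = np.linalg.norm(F_c, axis=1)
    r = np.full(series.n_frames, np.nan)
    ok = f_norm > 0
    r[ok] = (F_c[ok] @ p_c) / (f_norm[ok] * p_norm)
    return np.clip(r, -1.0, 1.0, out=r)


def fisher_z(r):
    """Variance-stabilizing transform Z = arctanh(r) = 0.5 ln((1+r)/(1-r)).

    Correlations with |r| >= 1 - 1e-12 are clamped just inside the open
    interval so that exact matches (noiseless constructions) stay finite.
    NaN inputs propagate.
    """
    r = np.clip(np.asarray(r, dtype=float), -_CLAMP, _CLAMP)
    return np.arctanh(r)


def inverse_fisher(z):
    """Inverse of :func:`fisher_z`: r = tanh(Z)."""
    return np.tanh(np.asarray(z, dtype=float))


def topn_mean(z_values: np.ndarray, n_top: int) -> float:
    """Mean of the ``n_top`` largest non-missing values.

    Order-independent; raises if fewer than ``n_top`` usable values are
    available (silent truncation would change the statistic's meaning).
    """
    z = np.asarray(z_values, dtype=float).ravel()
    z = z[np.isfinite(z)]
    n_top = int(n_top)
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > z.size:
        raise ValueError(f"n_top={n_top} exceeds {z.size} available values")
    if n_top < z.size:
        z = np.partition(z, z.size - n_top)[z.size - n_top :]
    # canonical (descending) order so the mean is order-independent exactly
    return float(np.sort(z)[::-1].mean())


class ReactivationScorer(TransformerMixin, BaseEstimator):
    """Score per-sentence reactivation intensity in resting frames.

    Fit on a (n_sentences, n_voxels) matrix of representation templates
    (t-maps over a common filtered mask).  ``transform`` takes a resting
    frames x voxels matrix (or :class:`RestingSeries`), z-scores voxel
    time courses if needed, and returns the (n_sentences,) vector of
    top-``n_top`` mean Fisher-Z intensities.

    Parameters
    ----------
    n_top : int, default 15
        Number of highest Fisher-Z frame correlations to average.
    """

    def __init__(self, n_top: int = 15):
        self.n_top = n_top

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("templates must be finite")
        self.templates_ = X
        self.n_features_in_ = X.shape[1]
        return self

    def _as_series(self, R) -> RestingSeries:
        if isinstance(R, RestingSeries):
            series = R
        else:
            series = RestingSeries(data=np.asarray(R, dtype=float))
        if series.n_voxels != self.n_features_in_:
            raise ValueError("voxel count differs from templates")
        if not series.zscored:
            series = zscore_voxels(series)
        return series

    def z_timecourses(self, R) -> np.ndarray:
        """(n_sentences, n_frames) Fisher-Z correlation time courses."""
        series = self._as_series(R)
        return np.vstack(
            [fisher_z(pattern_correlation_timecourse(series, t)) for t in self.templates_]
        )

    def transform(self, R) -> np.ndarray:
        Z = self.z_timecourses(R)
        return np.array([topn_mean(row, self.n_top) for row in Z])


def intensity_table(
    series: RestingSeries | Sequence[RestingSeries],
    reps: Sequence[RepresentationMap],
    n_top: int = 15,
) -> pd.DataFrame:
    """One intensity record per (sentence, session).

    Columns: ``sentence_id``, ``session``, ``n_top``, ``intensity``.
    Caller attaches subject and condition labels.
    """
    sessions = [series] if isinstance(series, RestingSeries) else list(series)
    scorer = ReactivationScorer(n_top=n_top).fit(np.vstack([r.values for r in reps]))
    rows = []
    for s in sessions:
        intensities = scorer.transform(s)
        for rep, val in zip(reps, intensities):
            rows.append(
                {
                    "sentence_id": rep.sentence_id,
                    "session": s.session,
                    "n_top": int(n_top),
                    "intensity": float(val),
                }
            )
    return pd.DataFrame(rows)


DEFAULT_NTOP_GRID = tuple(range(10, 81, 5))


class NtopSelector(BaseEstimator):
    """Choose N_top by maximizing the signal part of the variance curve.

    For each candidate N on the grid, the across-sentence variance of the
    top-N intensities is computed.  The noise contribution to that variance
    is modelled as proportional to 1/N; an ordinary least-squares fit of
    the variance curve on 1/N (with intercept) absorbs it, and the residual
    at each grid point is read as the signal component.  The chosen N_top
    maximizes the residual; exact ties (a pure a/N + c curve) resolve to
    the smallest grid value.

    Parameters
    ----------
    grid : sequence of int, default (10, 15, ..., 80)
        Candidate N_top values; at least 3, all within the frame count.
    """

    def __init__(self, grid: Sequence[int] = DEFAULT_NTOP_GRID):
        self.grid = grid

    def fit(self, R, templates=None):
        grid = np.asarray(sorted(set(int(g) for g in self.grid)), dtype=int)
        if grid.size < 3:
            raise ValueError("need at least 3 grid points")
        if (grid < 1).any():
            raise ValueError("grid values must be positive")
        if templates is None:
            raise ValueError("templates are required")
        T = np.atleast_2d(np.asarray(templates, dtype=float))
        if T.shape[0] < 2:
            raise ValueError("need at least 2 sentences to compute a variance")
        scorer = ReactivationScorer(n_top=int(grid[0])).fit(T)
        Z = scorer.z_timecourses(R)
        n_avail = np.isfinite(Z).sum(axis=1).min()
        if grid.max() > n_avail:
            raise ValueError(f"grid maximum {grid.max()} exceeds {n_avail} usable frames")
        var_curve = np.array(
            [np.var([topn_mean(row, n) for row in Z], ddof=1) for n in grid]
        )
        self._decompose(grid, var_curve)
        return self

    def fit_variance_curve(self, grid, variance_curve):
        """Run only the decomposition on a precomputed variance curve."""
        grid = np.asarray(grid, dtype=int)
        self._decompose(grid, np.asarray(variance_curve, dtype=float))
        return self

    def _decompose(self, grid: np.ndarray, var_curve: np.ndarray) -> None:
        X = np.column_stack([1.0 / grid, np.ones(grid.size)])
        coef, *_ = np.linalg.lstsq(X, var_curve, rcond=None)
        resid = var_curve - X @ coef
        # exact-tie tolerance: a pure a/N + c curve leaves only rounding noise
        tol = 1e-9 * max(np.max(np.abs(var_curve)), 1e-300)
        near_max = resid >= resid.max() - tol
        self.grid_ = grid
        self.variance_curve_ = var_curve
        self.signal_curve_ = resid
        self.noise_fit_ = (float(coef[0]), float(coef[1]))
        self.n_top_ = int(grid[np.flatnonzero(near_max)[0]])

    def estimate_(self) -> NtopEstimate:
        return NtopEstimate(
            grid=self.grid_,
            variance_curve=self.variance_curve_,
            signal_curve=self.signal_curve_,
            chosen=self.n_top_,
            noise_fit=self.noise_fit_,
        )


def estimate_ntop(
    series: RestingSeries | np.ndarray,
    reps: Sequence[RepresentationMap],
    grid: Sequence[int] = DEFAULT_NTOP_GRID,
) -> NtopEstimate:
    """Variance-decomposition estimate of N_top for one subject/session."""
    T = np.vstack([r.values for r in reps])
    return NtopSelector(grid=grid).fit(series, templates=T).estimate_()


def aggregate_ntop(chosen: Sequence[int], grid: Sequence[int] = DEFAULT_NTOP_GRID) -> int:
    """Group-level N_top: mean of per-subject choices, snapped to the grid.

    The mean is mapped to the nearest grid value; a midpoint tie rounds up
    (e.g. a mean of 14.81 on a step-5 grid becomes 15).
    """
    chosen = np.asarray(list(chosen), dtype=float)
    if chosen.size == 0:
        raise ValueError("no per-subject estimates to aggregate")
    grid = np.asarray(sorted(set(int(g) for g in grid)), dtype=int)
    mean = chosen.mean()
    dist = np.abs(grid - mean)
    best = dist.min()
    candidates = grid[dist <= best + 1e-12]
    return int(candidates.max())  # midpoint tie -> round up
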