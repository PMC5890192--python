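"""Voxelwise (searchlight) reactivation intensity and condition contrast.

The ROI intensity statistic is repeated inside a cube neighborhood (by
default 5 x 5 x 5 voxels, Chebyshev radius 2) centered on every in-mask
voxel: the cube's t-map pattern is correlated with each resting frame's
cube pattern, Fisher-transformed, and summarized by the top-N mean.
Cubes are truncated at volume edges rather than dropped.  The condition
contrast (associated vs non-associated sentences) is assessed with a
within-subject label permutation and max-statistic family-wise error
correction over the mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rsa import (
    RestingSeries,
    fisher_z,
    pattern_correlation_timecourse,
    topn_mean,
    zscore_voxels,
)

__all__ = [
    "SearchlightMap",
    "cube_indices",
    "searchlight_intensity",
    "condition_contrast_map",
]


@dataclass
class SearchlightMap:
    """Per-sentence intensity volumes from one subject's searchlight run."""

    values: np.ndarray  # (x, y, z, n_sentences), NaN outside mask
    mask: np.ndarray
    radius: int
    n_top: int

    @property
    def n_sentences(self) -> int:
        return self.values.shape[-1]

    def masked(self) -> np.ndarray:
        """(n_mask_voxels, n_sentences) view in C order of the mask."""
        return self.values[self.mask]


def cube_indices(
    center: Sequence[int],
    radius: int,
    shape: Sequence[int],
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """In-bounds, in-mask voxels within Chebyshev distance ``radius``.

    Returns an (k, 3) integer array in C (row-major) order.  The center
    must itself lie inside the mask.
    """
    center = tuple(int(c) for c in center)
    shape = tuple(int(s) for s in shape)
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if any(not 0 <= c < s for c, s in zip(center, shape)):
        raise ValueError(f"center {center} outside volume {shape}")
    if mask is not None and not mask[center]:
        raise ValueError(f"center {center} outside mask")
    ranges = [
        np.arange(max(0, c - radius), min(s, c + radius + 1))
        for c, s in zip(center, shape)
    ]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    if mask is not None:
        grid = grid[mask[grid[:, 0], grid[:, 1], grid[:, 2]]]
    return grid


def searchlight_intensity(
    rest4d: np.ndarray,
    tmaps4d: np.ndarray,
    mask: np.ndarray,
    n_top: int = 13,
    radius: int = 2,
) -> SearchlightMap:
    """Top-N Fisher-Z intensity of every sentence at every mask voxel.

    ``rest4d`` is (x, y, z, t); ``tmaps4d`` is (x, y, z, n_sentences).
    Voxel time courses are z-scored once (per voxel, so values match the
    ROI pipeline exactly when a cube coincides with an ROI mask); cubes
    with fewer than 3 usable voxels yield NaN at that center.
    """
    mask = np.asarray(mask, dtype=bool)
    rest4d = np.asarray(rest4d, dtype=float)
    tmaps4d = np.asarray(tmaps4d, dtype=float)
    if rest4d.shape[:3] != mask.shape or tmaps4d.shape[:3] != mask.shape:
        raise ValueError("volume shapes disagree with the mask")
    n_sent = tmaps4d.shape[-1]
    shape = mask.shape

    # global per-voxel z-scoring; identical to per-cube z-scoring
    flat = RestingSeries(data=rest4d.reshape(-1, rest4d.shape[-1]).T)
    flat = zscore_voxels(flat)
    zdata = flat.data  # frames x all voxels
    degen = flat.degenerate

    lin = np.arange(np.prod(shape)).reshape(shape)
    out = np.full(shape + (n_sent,), np.nan)
    for center in np.argwhere(mask):
        cube = cube_indices(center, radius, shape, mask)
        flat_idx = lin[cube[:, 0], cube[:, 1], cube[:, 2]]
        series = RestingSeries(
            data=zdata[:, flat_idx],
            zscored=True,
            degenerate=degen[flat_idx],
        )
        usable = ~series.degenerate
        if int(usable.sum()) < 3:
            continue
        for s in range(n_sent):
            template = tmaps4d[cube[:, 0], cube[:, 1], cube[:, 2], s]
            try:
                r = pattern_correlation_timecourse(series, template)
            except ValueError:
                continue
            out[center[0], center[1], center[2], s] = topn_mean(fisher_z(r), n_top)
    return SearchlightMap(values=out, mask=mask, radius=radius, n_top=n_top)


def _rating_correlations(maps: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each voxel's intensities and ratings y."""
    yc = y - y.mean()
    y_norm = np.linalg.norm(yc)
    Xc = maps - maps.mean(axis=1, keepdims=True)
    x_norm = np.linalg.norm(Xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (x_norm * y_norm)
    return r


def condition_contrast_map(
    maps: Sequence[np.ndarray],
    ratings: Sequence[np.ndarray],
    associated: Sequence[np.ndarray],
    n_permutations: int = 5000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise associated-vs-non-associated correlation contrast.

    Per subject and voxel, the intensity-rating Pearson correlation is
    computed separately over associated and non-associated sentences; the
    statistic is the across-subject mean of the Fisher-Z difference.  The
    null distribution permutes the association labels within each subject
    (preserving counts), and family-wise error is controlled by the
    permutation distribution of the maximum statistic over voxels.

    Parameters
    ----------
    maps : per subject, (n_voxels, n_sentences) intensity matrix
    ratings : per subject, (n_sentences,) rating vector
    associated : per subject, boolean (n_sentences,) association labels
    n_permutations : number of label permutations (must be >= 1)
    seed : RNG seed or generator

    Returns
    -------
    (stat, p) : both (n_voxels,); p is FWE-corrected by the max statistic.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects")
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    if not (len(maps) == len(ratings) == len(associated)):
        raise ValueError("maps, ratings, associated must align per subject")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    maps = [np.asarray(m, dtype=float) for m in maps]
    ratings = [np.asarray(y, dtype=float).ravel() for y in ratings]
    associated = [np.asarray(a, dtype=bool).ravel() for a in associated]
    for m, y, a in zip(maps, ratings, associated):
        if m.shape[1] != y.size or y.size != a.size:
            raise ValueError("sentence counts disagree within a subject")
        if a.sum() < 3 or (~a).sum() < 3:
            raise ValueError("each condition needs at least 3 sentences per subject")

    def statistic(labels: Sequence[np.ndarray]) -> np.ndarray:
        diffs = []
        for m, y, a in zip(maps, ratings, labels):
            r_w = _rating_correlations(m[:, a], y[a])
            r_wo = _rating_correlations(m[:, ~a], y[~a])
            diffs.append(fisher_z(r_w) - fisher_z(r_wo))
        return np.mean(diffs, axis=0)

    observed = statistic(associated)
    max_null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm_labels = [rng.permutation(a) for a in associated]
        max_null[b] = np.nanmax(statistic(perm_labels))
    finite = np.isfinite(observed)
    p = np.full_like(observed, np.nan)
    p[finite] = (1.0 + (max_null[None, :] >= observed[finite, None]).sum(axis=1)) / (
        n_permutations + 1.0
    )
    return observed, p
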