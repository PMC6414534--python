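"""Smoothed, z-scored gaze maps and gaze similarity matrices (GSMs).

A gaze map accumulates a trial's valid sample positions on a (downsampled)
screen grid, smooths with an isotropic Gaussian whose SD is given in degrees
of visual angle (default 1 deg), and z-scores over all grid cells.  The GSM
is the trials x trials matrix of Fisher-transformed Pearson correlations
between flattened maps; averaging each trial's row (excluding the diagonal)
and sorting gives the consistency curve, with percentile-bootstrap
confidence intervals across participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import ScreenGeometry
from .io import DataError, GazeRecording

__all__ = [
    "GazeMap",
    "SimilarityMatrix",
    "SimilarityCurve",
    "build_gaze_map",
    "similarity_matrix",
    "similarity_curve",
    "FISHER_CLIP",
]

#: correlations are clipped to +/-(1 - 1e-6) so atanh stays finite for
#: duplicate maps
FISHER_CLIP = 1.0 - 1e-6


@dataclass
class GazeMap:
    grid: np.ndarray  # (height, width)
    sigma_deg: float
    downsample: int
    z_scored: bool


@dataclass
class SimilarityMatrix:
    z: np.ndarray  # (n_trials, n_trials), Fisher z; diagonal present but excluded from summaries
    trial_ids: list[str]


@dataclass
class SimilarityCurve:
    """Group mean similarity per trial, sorted descending, with bootstrap CIs."""

    trial_ids: list[str]  # in sorted (descending) order
    mean_z: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def build_gaze_map(
    samples: GazeRecording | tuple[np.ndarray, np.ndarray],
    geometry: ScreenGeometry,
    sigma_deg: float = 1.0,
    downsample: int = 4,
    z_score: bool = True,
) -> GazeMap:
    """Accumulate, smooth and z-score one trial's gaze positions.

    ``samples`` is either a GazeRecording (only valid samples are used) or a
    raw ``(x, y)`` pixel-coordinate pair.  The smoothing SD is converted to
    pixels with the horizontal screen-centre factor, then divided by the
    downsampling factor.
    """
    if isinstance(samples, GazeRecording):
        x = samples.x[samples.valid]
        y = samples.y[samples.valid]
    else:
        x, y = np.asarray(samples[0], float), np.asarray(samples[1], float)
    if x.size == 0:
        raise DataError("build_gaze_map needs at least one valid sample")
    if downsample < 1 or geometry.width_px % downsample or geometry.height_px % downsample:
        raise ValueError("downsample must be a positive divisor of the screen resolution")
    w = geometry.width_px // downsample
    h = geometry.height_px // downsample
    ix = np.clip((x / downsample).astype(int), 0, w - 1)
    iy = np.clip((y / downsample).astype(int), 0, h - 1)
    grid = np.zeros((h, w))
    np.add.at(grid, (iy, ix), 1.0)
    sigma_px = geometry.degrees_to_pixels(sigma_deg, "x") / downsample
    grid = gaussian_filter(grid, sigma=sigma_px)
    if z_score:
        sd = grid.std()
        if sd == 0:
            raise DataError("gaze map is constant; cannot z-score")
        grid = (grid - grid.mean()) / sd
    return GazeMap(grid=grid, sigma_deg=sigma_deg, downsample=downsample, z_scored=z_score)


def similarity_matrix(
    maps: Sequence[GazeMap],
    trial_ids: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Pairwise Fisher-z correlations between trials' gaze maps."""
    if len(maps) < 2:
        raise ValueError("similarity_matrix needs at least 2 maps")
    shapes = {m.grid.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"gaze maps on different grids: {sorted(shapes)}")
    flat = np.stack([m.grid.ravel() for m in maps])
    r = np.corrcoef(flat)
    z = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    ids = list(trial_ids) if trial_ids is not None else [str(i) for i in range(len(maps))]
    return SimilarityMatrix(z=z, trial_ids=ids)


def mean_offdiagonal(matrix: SimilarityMatrix) -> np.ndarray:
    """Per-trial mean Fisher z to all *other* trials."""
    z = matrix.z
    n = z.shape[0]
    return (z.sum(axis=1) - np.diag(z)) / (n - 1)


def similarity_curve(
    matrices_by_participant: dict[str, SimilarityMatrix],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> SimilarityCurve:
    """Group consistency curve with participant-level bootstrap CIs.

    Per participant and trial the mean Fisher z to all other trials is
    computed; the group curve is the across-participant mean, sorted
    descending.  CIs are percentile bootstrap over participants (the curve's
    sort order is fixed by the point estimate).
    """
    if not matrices_by_participant:
        raise ValueError("need at least one participant")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    pids = sorted(matrices_by_participant)
    ref_ids = matrices_by_participant[pids[0]].trial_ids
    for pid in pids:
        if matrices_by_participant[pid].trial_ids != ref_ids:
            raise ValueError("all participants must contribute the same trial set")
    per_part = np.stack([mean_offdiagonal(matrices_by_participant[p]) for p in pids])
    mean = per_part.mean(axis=0)
    order = np.argsort(-mean, kind="stable")

    n_p = len(pids)
    if n_p == 1:
        warnings.warn("single participant: CIs degenerate to the point estimate")
        lo = hi = mean.copy()
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_p, size=(n_boot, n_p))
        boot = per_part[idx].mean(axis=1)  # (n_boot, n_trials)
        a = (1.0 - ci) / 2.0
        lo = np.quantile(boot, a, axis=0)
        hi = np.quantile(boot, 1.0 - a, axis=0)
        lo = np.minimum(lo, mean)
        hi = np.maximum(hi, mean)
    return SimilarityCurve(
        trial_ids=[ref_ids[i] for i in order],
        mean_z=mean[order],
        ci_low=lo[order],
        ci_high=hi[order],
    )
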