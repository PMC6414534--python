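"""Vehicle counting from video frames.

Traffic density per trial is estimated by classic background subtraction:
a per-pixel online mixture of Gaussians (Stauffer–Grimson style) models the
static scene; pixels not explained by a background component form the
foreground mask, which is cleaned by morphological opening and counted by
8-connected blob labelling.  The per-trial density is the maximum number of
simultaneously visible moving objects, matching the "more than N vehicles
on screen" dichotomisation used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

__all__ = [
    "BackgroundModel",
    "fit_background",
    "foreground_mask",
    "count_moving_objects",
    "count_vehicles",
    "trial_density",
]

_MATCH_SIGMA = 2.5  # a sample matches a component within 2.5 SDs
_BACKGROUND_WEIGHT = 0.4  # components at or above this weight model the background
_INIT_VAR = 0.02
_MIN_VAR = 1e-4


@dataclass
class BackgroundModel:
    """Per-pixel Gaussian mixture: arrays of shape (K, H, W)."""

    weight: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    learning_rate: float

    @property
    def n_components(self) -> int:
        return self.weight.shape[0]

    def update(self, frame: np.ndarray) -> None:
        """One online update step with the current frame."""
        w, mu, var = self.weight, self.mean, self.var
        lr = self.learning_rate
        dist2 = (frame[None] - mu) ** 2
        match = dist2 <= (_MATCH_SIGMA**2) * var
        # only the best-matching (highest-weight) matching component absorbs the sample
        rank = np.where(match, w, -np.inf)
        best = np.argmax(rank, axis=0)
        any_match = match.any(axis=0)
        onehot = np.zeros_like(w, dtype=bool)
        np.put_along_axis(onehot, best[None], True, axis=0)
        absorb = onehot & any_match[None]

        w += lr * (absorb.astype(float) - w)
        rho = lr
        mu_new = mu + rho * (frame[None] - mu)
        var_new = var + rho * (dist2 - var)
        self.mean = np.where(absorb, mu_new, mu)
        self.var = np.clip(np.where(absorb, var_new, var), _MIN_VAR, None)

        # unmatched pixels: replace the weakest component with a fresh one
        if (~any_match).any():
            weakest = np.argmin(w, axis=0)
            repl = np.zeros_like(w, dtype=bool)
            np.put_along_axis(repl, weakest[None], True, axis=0)
            repl &= ~any_match[None]
            self.mean = np.where(repl, frame[None], self.mean)
            self.var = np.where(repl, _INIT_VAR, self.var)
            w[:] = np.where(repl, lr, w)
        w /= w.sum(axis=0, keepdims=True)
        self.weight = w

    def background_components(self) -> np.ndarray:
        """Boolean (K, H, W): components belonging to the background model.

        A component is background if its weight dominates (at least
        ``_BACKGROUND_WEIGHT``); the highest-weight component per pixel is
        always background.  Transient foreground objects accumulate only
        modest weight at any pixel and stay out.
        """
        keep = self.weight >= _BACKGROUND_WEIGHT
        top = np.argmax(self.weight, axis=0)
        np.put_along_axis(keep, top[None], True, axis=0)
        return keep


def fit_background(
    frames: np.ndarray,
    n_components: int = 3,
    learning_rate: float = 0.02,
) -> BackgroundModel:
    """Fit the per-pixel mixture by streaming over the frame stack.

    Expects a (T, H, W) grayscale stack in [0, 1] with T >= 2 (>= 10 for a
    stable estimate).
    """
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("frames must be a (T, H, W) stack with T >= 2")
    T, H, W = frames.shape
    model = _init_model(frames[0], n_components, learning_rate)
    for f in frames:
        model.update(f)
    return model


def _init_model(first_frame: np.ndarray, n_components: int, learning_rate: float) -> BackgroundModel:
    """Seed every component at the first frame (dominant weight on the first);
    novel intensities later displace the weakest component.  Initialising
    from the data keeps the whole pipeline invariant to a global brightness
    offset."""
    H, W = first_frame.shape
    model = BackgroundModel(
        weight=np.full((n_components, H, W), 0.2 / max(n_components - 1, 1)),
        mean=np.repeat(first_frame[None], n_components, axis=0).copy(),
        var=np.full((n_components, H, W), _INIT_VAR),
        learning_rate=learning_rate,
    )
    model.weight[0] = 0.8
    return model


def foreground_mask(frame: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Pixels not within 2.5 SD of any background component."""
    bg = model.background_components()
    dist2 = (frame[None] - model.mean) ** 2
    match_bg = bg & (dist2 <= (_MATCH_SIGMA**2) * model.var)
    return ~match_bg.any(axis=0)


def count_moving_objects(
    frame: np.ndarray,
    model: BackgroundModel,
    min_area_px: int = 30,
) -> int:
    """Blob count of the cleaned foreground mask of one frame.

    The mask is opened with a 3x3 structuring element and labelled with
    8-connectivity; components smaller than ``min_area_px`` are ignored.
    Overlapping objects merge into a single blob.
    """
    mask = foreground_mask(frame, model)
    mask = morphology.opening(mask, morphology.footprint_rectangle((3, 3)))
    lab = measure.label(mask, connectivity=2)
    if lab.max() == 0:
        return 0
    areas = np.bincount(lab.ravel())[1:]
    return int(np.sum(areas >= min_area_px))


def trial_density(frame_counts: np.ndarray) -> int:
    """Per-trial vehicle count: the maximum simultaneous per-frame count."""
    counts = np.asarray(frame_counts)
    if counts.size == 0:
        raise ValueError("frame_counts is empty")
    return int(counts.max())


def count_vehicles(
    frames: np.ndarray,
    min_area_px: int = 30,
    n_components: int = 3,
    learning_rate: float = 0.02,
    warmup_fraction: float = 0.25,
) -> tuple[int, np.ndarray]:
    """End-to-end trial pipeline: fit background, count blobs, take the max.

    The model is fitted online over all frames; per-frame counts are taken
    only after the warm-up fraction of the clip, when the background
    estimate has stabilised.  Returns ``(n_vehicles, per_frame_counts)``.
    """
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("frames must be a (T, H, W) stack with T >= 2")
    T = frames.shape[0]
    model = _init_model(frames[0], n_components, learning_rate)
    warmup = int(warmup_fraction * T)
    counts = []
    for i, f in enumerate(frames):
        model.update(f)
        if i >= warmup:
            counts.append(count_moving_objects(f, model, min_area_px))
        else:
            counts.append(0)
    counts = np.asarray(counts)
    return trial_density(counts[warmup:]) if T > warmup else trial_density(counts), counts
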