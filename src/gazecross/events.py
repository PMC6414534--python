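"""Oculomotor event parsing: fixations, saccades and smooth pursuits.

The parser works on 1000 Hz gaze streams in three passes:

1. per-sample angular speed (central differences, converted to deg/s with the
   screen-centre linear factor, smoothed by a short centred moving average);
2. saccades: maximal runs with speed above a velocity threshold (50 deg/s,
   the EyeLink default);
3. smooth segments: among the remaining samples, maximal runs holding speed
   at or below 30 deg/s for at least 100 ms become pursuit *candidates*.
   Each candidate is scored by fitting low-order polynomials x(t), y(t)
   (after one pass of robust outlier removal), taking the root-mean-square
   residual P_RMSE and the arc length A of the fitted 2D curve (both in
   pixels), and computing ``score = P_RMSE / exp(A)``.  A genuinely moving
   eye accrues tens to hundreds of pixels of arc length, so exp(A) explodes
   and the score collapses below the 1e-9 threshold; a jittering fixation
   has A of a few pixels and a score many orders of magnitude larger.

Everything not saccade, pursuit or missing is fixation.  Segments partition
each trial's time span exactly, using half-open [t_start, t_end) intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScreenGeometry
from .io import DataError, EventSegment, GazeRecording

__all__ = [
    "ParserParams",
    "VelocityTrace",
    "TrialEventSummary",
    "InsufficientDataError",
    "compute_velocity",
    "extract_saccades",
    "candidate_smooth_segments",
    "pursuit_score",
    "parse_trial",
    "qc_filter",
    "summarize_events",
]


class InsufficientDataError(DataError):
    """Too few valid samples to compute the requested quantity."""


@dataclass(frozen=True)
class ParserParams:
    """Thresholds and knobs of the event parser.

    saccade_vel_thresh : deg/s; samples faster than this are saccade.
    pursuit_vel_max : deg/s; pursuit candidates must stay at or below this.
    pursuit_min_dur_ms : minimum duration of a pursuit candidate run.
    score_thresh : pursuit decision threshold on P_RMSE / exp(A).
    poly_degree : degree of the x(t), y(t) fits.
    vel_window_ms : width of the centred moving average applied to speed.
    min_pursuit_displacement_px : net displacement guard; degenerate
        noiseless fixations fit perfectly (score 0) and would otherwise be
        called pursuit.
    min_fixation_ms : fixation runs shorter than this that border a saccade
        are absorbed into it; velocity smoothing otherwise leaves few-ms
        intermediate-speed slivers at saccade flanks.
    """

    saccade_vel_thresh: float = 50.0
    pursuit_vel_max: float = 30.0
    pursuit_min_dur_ms: float = 100.0
    score_thresh: float = 1e-9
    poly_degree: int = 2
    vel_window_ms: float = 20.0
    min_pursuit_displacement_px: float = 10.0
    min_fixation_ms: float = 40.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"ParserParams.{name} must be positive")
        if not self.pursuit_vel_max < self.saccade_vel_thresh:
            raise ValueError("pursuit_vel_max must be below saccade_vel_thresh")


@dataclass
class VelocityTrace:
    """Per-sample angular speed in deg/s; NaN where undefined (invalid spans)."""

    t: np.ndarray
    speed: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class TrialEventSummary:
    """Counts, total time and proportion of trial time per event label."""

    counts: dict[str, int]
    total_ms: dict[str, float]
    proportions: dict[str, float]
    trial_duration_ms: float


def _nan_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average ignoring NaNs; NaN positions stay NaN."""
    if window <= 1:
        return values
    mask = np.isfinite(values)
    filled = np.where(mask, values, 0.0)
    kernel = np.ones(window)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(mask.astype(float), kernel, mode="same")
    out = np.full_like(values, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    out[~mask] = np.nan
    return out


def compute_velocity(
    recording: GazeRecording,
    geometry: ScreenGeometry,
    params: ParserParams = ParserParams(),
) -> VelocityTrace:
    """Per-sample angular speed from central differences, smoothed.

    Displacements are converted per-axis with the linear screen-centre
    factor (deg/px) and combined as the Euclidean norm.  Speed is NaN for
    invalid samples and for samples whose central difference would straddle
    an invalid sample.
    """
    if int(np.sum(recording.valid)) < 3:
        raise InsufficientDataError("compute_velocity needs at least 3 valid samples")
    t, x, y, valid = recording.t, recording.x, recording.y, recording.valid
    n = len(t)
    # central differences in px/ms (one-sided at the ends)
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    kx = geometry.deg_per_px("x")
    ky = geometry.deg_per_px("y")
    speed = np.hypot(vx * kx, vy * ky) * 1000.0  # deg/s

    # undefined on invalid samples and their immediate neighbours
    bad = ~valid
    near_bad = bad.copy()
    near_bad[:-1] |= bad[1:]
    near_bad[1:] |= bad[:-1]
    speed = np.where(near_bad, np.nan, speed)

    window = max(1, int(round(params.vel_window_ms * recording.rate_hz / 1000.0)))
    if window % 2 == 0:
        window += 1
    speed = _nan_moving_average(speed, window)
    speed[~valid] = np.nan
    return VelocityTrace(t=t, speed=speed)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of ``mask`` as (start, stop) index pairs, stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def _sample_edges(t: np.ndarray, dt_ms: float) -> np.ndarray:
    """Half-open cell edges: edge[i] = t[i], edge[n] = t[-1] + dt."""
    return np.concatenate([t, [t[-1] + dt_ms]])


def extract_saccades(
    trace: VelocityTrace,
    params: ParserParams = ParserParams(),
) -> list[tuple[int, int]]:
    """Maximal runs of samples with speed strictly above the saccade threshold.

    Returns (start, stop) sample-index pairs, stop exclusive.
    """
    supra = np.zeros(len(trace), dtype=bool)
    defined = np.isfinite(trace.speed)
    supra[defined] = trace.speed[defined] > params.saccade_vel_thresh
    return _runs(supra)


def candidate_smooth_segments(
    trace: VelocityTrace,
    saccades: list[tuple[int, int]],
    params: ParserParams = ParserParams(),
) -> list[tuple[int, int]]:
    """Pursuit candidates: sub-30 deg/s runs lasting at least 100 ms.

    Runs are broken by saccade samples, undefined samples and samples in the
    intermediate (30, 50] deg/s band.  The duration bound is inclusive.
    """
    sub = np.zeros(len(trace), dtype=bool)
    defined = np.isfinite(trace.speed)
    sub[defined] = trace.speed[defined] <= params.pursuit_vel_max
    for a, b in saccades:
        sub[a:b] = False
    dt = float(np.median(np.diff(trace.t))) if len(trace) > 1 else 1.0
    out = []
    for a, b in _runs(sub):
        if (b - a) * dt >= params.pursuit_min_dur_ms:
            out.append((a, b))
    return out


def pursuit_score(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    params: ParserParams = ParserParams(),
) -> float:
    """Smooth-segment score ``P_RMSE / exp(A)``.

    Fits polynomials of ``poly_degree`` to x(t) and y(t) after removing
    gross outliers (Euclidean fit residual beyond 3 MAD-based robust SDs,
    one pass), then returns the pooled root-mean-square residual divided by
    the exponential of the numerically integrated arc length of the fitted
    2D curve.  Residuals and arc length are in pixels.

    Raises
    ------
    InsufficientDataError
        If fewer than ``poly_degree + 2`` samples remain; the caller labels
        such segments fixation.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    min_n = params.poly_degree + 2
    if len(t) < min_n:
        raise InsufficientDataError(
            f"pursuit_score needs >= {min_n} samples, got {len(t)}"
        )
    ts = t - t[0]  # shift for conditioning

    def fit(tv, xv, yv):
        cx = np.polyfit(tv, xv, params.poly_degree)
        cy = np.polyfit(tv, yv, params.poly_degree)
        return cx, cy

    cx, cy = fit(ts, x, y)
    rx = x - np.polyval(cx, ts)
    ry = y - np.polyval(cy, ts)
    res = np.hypot(rx, ry)
    med = np.median(res)
    mad_sd = 1.4826 * np.median(np.abs(res - med))
    keep = res <= med + 3.0 * mad_sd if mad_sd > 0 else np.ones_like(res, bool)
    if keep.sum() >= min_n and keep.sum() < len(t):
        cx, cy = fit(ts[keep], x[keep], y[keep])
        rx = x[keep] - np.polyval(cx, ts[keep])
        ry = y[keep] - np.polyval(cy, ts[keep])
        ts_used = ts[keep]
    else:
        ts_used = ts

    p_rmse = float(np.sqrt(np.mean(np.concatenate([rx, ry]) ** 2)))

    # arc length of the fitted curve over the segment's time span, trapezoid rule
    dense = np.linspace(ts_used[0], ts_used[-1], max(10 * len(ts_used), 100))
    dxdt = np.polyval(np.polyder(cx), dense)
    dydt = np.polyval(np.polyder(cy), dense)
    arc = float(np.trapezoid(np.hypot(dxdt, dydt), dense))
    # exp(arc) overflows float64 past ~709; the score is then exactly 0 for
    # any finite residual, which is the intended limit
    if arc > 700.0:
        return 0.0 if p_rmse == 0.0 else p_rmse * float(np.exp(-arc))
    return p_rmse / float(np.exp(arc))


def parse_trial(
    recording: GazeRecording,
    geometry: ScreenGeometry,
    params: ParserParams = ParserParams(),
) -> list[EventSegment]:
    """Parse one trial into fixation / saccade / pursuit / missing segments.

    Every sample belongs to exactly one segment; the segments partition
    [t[0], t[-1] + dt) without overlap.  Smooth candidates become pursuit
    iff their score falls below ``score_thresh`` *and* their net displacement
    is at least ``min_pursuit_displacement_px``.
    """
    trace = compute_velocity(recording, geometry, params)
    labels = sample_labels(recording, trace, params)
    _absorb_fixation_slivers(labels, recording, params)
    return _labels_to_segments(recording, labels)


def _absorb_fixation_slivers(labels: np.ndarray, recording: GazeRecording, params: ParserParams) -> None:
    """Relabel sub-minimum fixation runs bordering a saccade as saccade, in place."""
    n = len(labels)
    min_samples = params.min_fixation_ms * recording.rate_hz / 1000.0
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            if labels[start] == "fixation" and (i - start) < min_samples:
                before = labels[start - 1] if start > 0 else None
                after = labels[i] if i < n else None
                if before == "saccade" or after == "saccade":
                    labels[start:i] = "saccade"
            start = i


def sample_labels(
    recording: GazeRecording,
    trace: VelocityTrace,
    params: ParserParams = ParserParams(),
) -> np.ndarray:
    """Per-sample label codes as an array of strings from EVENT_LABELS."""
    n = len(recording)
    labels = np.full(n, "fixation", dtype=object)
    labels[~recording.valid] = "missing"

    saccades = extract_saccades(trace, params)
    for a, b in saccades:
        labels[a:b] = "saccade"

    for a, b in candidate_smooth_segments(trace, saccades, params):
        seg = slice(a, b)
        ok = recording.valid[seg]
        tt = recording.t[seg][ok]
        xx = recording.x[seg][ok]
        yy = recording.y[seg][ok]
        if len(tt) < params.poly_degree + 2:
            continue  # degenerate: stays fixation
        disp = float(np.hypot(xx[-1] - xx[0], yy[-1] - yy[0]))
        if disp < params.min_pursuit_displacement_px:
            continue
        try:
            score = pursuit_score(tt, xx, yy, params)
        except InsufficientDataError:
            continue
        if score < params.score_thresh:
            labels[seg] = np.where(recording.valid[seg], "pursuit", "missing")
    return labels


def _labels_to_segments(recording: GazeRecording, labels: np.ndarray) -> list[EventSegment]:
    edges = _sample_edges(recording.t, recording.dt_ms)
    segments: list[EventSegment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            sl = slice(start, i)
            label = str(labels[start])
            ok = recording.valid[sl]
            mx = float(np.mean(recording.x[sl][ok])) if ok.any() else float("nan")
            my = float(np.mean(recording.y[sl][ok])) if ok.any() else float("nan")
            segments.append(
                EventSegment(
                    trial_id=recording.trial_id,
                    label=label,
                    t_start=float(edges[start]),
                    t_end=float(edges[i]),
                    mean_x=mx,
                    mean_y=my,
                )
            )
            start = i
    return segments


def qc_filter(
    trials_by_participant: dict[str, list[GazeRecording]],
    geometry: ScreenGeometry,
    params: ParserParams = ParserParams(),
) -> tuple[dict[str, list[GazeRecording]], list[tuple[str, str]], list[str]]:
    """Noisy-recording exclusions.

    A trial is removed iff strictly more than 50% of its valid samples
    exceed the saccade velocity threshold; a participant is excluded iff
    strictly more than 50% of their trials are removed.

    Returns ``(kept, removed_trials, excluded_participants)`` where
    ``removed_trials`` lists (participant_id, trial_id) pairs and ``kept``
    retains only surviving trials of surviving participants.
    """
    kept: dict[str, list[GazeRecording]] = {}
    removed: list[tuple[str, str]] = []
    excluded: list[str] = []
    for pid, trials in trials_by_participant.items():
        surviving = []
        n_removed = 0
        for rec in trials:
            try:
                trace = compute_velocity(rec, geometry, params)
            except InsufficientDataError:
                n_removed += 1
                removed.append((pid, rec.trial_id))
                continue
            sp = trace.speed[np.isfinite(trace.speed)]
            if sp.size and np.mean(sp > params.saccade_vel_thresh) > 0.5:
                n_removed += 1
                removed.append((pid, rec.trial_id))
            else:
                surviving.append(rec)
        if trials and n_removed / len(trials) > 0.5:
            excluded.append(pid)
        else:
            kept[pid] = surviving
    return kept, removed, excluded


def summarize_events(
    segments: list[EventSegment],
    trial_duration_ms: float,
) -> TrialEventSummary:
    """Per-label counts, total time and proportion of trial time."""
    from .io import EVENT_LABELS

    counts = {lab: 0 for lab in EVENT_LABELS}
    total = {lab: 0.0 for lab in EVENT_LABELS}
    for s in segments:
        counts[s.label] += 1
        total[s.label] += s.duration
    props = {
        lab: (total[lab] / trial_duration_ms if trial_duration_ms > 0 else 0.0)
        for lab in EVENT_LABELS
    }
    return TrialEventSummary(
        counts=counts,
        total_ms=total,
        proportions=props,
        trial_duration_ms=trial_duration_ms,
    )
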