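"""Independent reference implementations used to cross-check the pipeline.

Everything here is deliberately written as plain one-pass loops over
samples, separate from the package's vectorised code paths.
"""

from __future__ import annotations

import math

import numpy as np


def deg_per_px_centre(geometry) -> tuple[float, float]:
    """Closed-form small-extent conversion factors at screen centre."""
    kx = math.degrees((geometry.width_mm / geometry.width_px) / geometry.distance_mm)
    ky = math.degrees((geometry.height_mm / geometry.height_px) / geometry.distance_mm)
    return kx, ky


def reference_speeds(rec, geometry, window_ms: float = 20.0) -> np.ndarray:
    """Per-sample angular speed, computed with explicit loops.

    Central difference over neighbouring samples, centre-linear conversion,
    then a plain centred moving average over defined samples.
    """
    kx, ky = deg_per_px_centre(geometry)
    n = len(rec.t)
    raw = np.full(n, np.nan)
    for i in range(n):
        if not rec.valid[i]:
            continue
        lo = max(i - 1, 0)
        hi = min(i + 1, n - 1)
        if not (rec.valid[lo] and rec.valid[hi]):
            continue
        dt = rec.t[hi] - rec.t[lo]
        vx = (rec.x[hi] - rec.x[lo]) / dt
        vy = (rec.y[hi] - rec.y[lo]) / dt
        raw[i] = math.hypot(vx * kx, vy * ky) * 1000.0
    w = int(round(window_ms * rec.rate_hz / 1000.0))
    if w % 2 == 0:
        w += 1
    half = w // 2
    out = np.full(n, np.nan)
    for i in range(n):
        if not rec.valid[i]:
            continue
        vals = [raw[j] for j in range(max(0, i - half), min(n, i + half + 1)) if np.isfinite(raw[j])]
        if vals:
            out[i] = sum(vals) / len(vals)
    return out


def reference_pursuit_score(t, x, y, degree: int = 2) -> float:
    """Direct evaluation of RMSE / exp(arc length) via an independent path
    (numpy.polynomial API, midpoint-rule arc integral)."""
    from numpy.polynomial import polynomial as P

    t = np.asarray(t, float) - t[0]
    cx = P.polyfit(t, x, degree)
    cy = P.polyfit(t, y, degree)
    rx = x - P.polyval(t, cx)
    ry = y - P.polyval(t, cy)
    res = np.hypot(rx, ry)
    med = np.median(res)
    mad_sd = 1.4826 * np.median(np.abs(res - med))
    keep = res <= med + 3 * mad_sd if mad_sd > 0 else np.ones(len(t), bool)
    if keep.sum() >= degree + 2 and keep.sum() < len(t):
        t2, x2, y2 = t[keep], np.asarray(x)[keep], np.asarray(y)[keep]
        cx = P.polyfit(t2, x2, degree)
        cy = P.polyfit(t2, y2, degree)
        rx = x2 - P.polyval(t2, cx)
        ry = y2 - P.polyval(t2, cy)
        t = t2
    rmse = math.sqrt(float(np.mean(np.concatenate([rx, ry]) ** 2)))
    dcx = P.polyder(cx)
    dcy = P.polyder(cy)
    m = 5000
    mid = np.linspace(t[0], t[-1], m + 1)
    mid = (mid[:-1] + mid[1:]) / 2
    h = (t[-1] - t[0]) / m
    arc = float(np.sum(np.hypot(P.polyval(mid, dcx), P.polyval(mid, dcy))) * h)
    if arc > 700:
        return 0.0 if rmse == 0 else rmse * math.exp(-min(arc, 745.0))
    return rmse / math.exp(arc)


def reference_labels(rec, geometry, params) -> np.ndarray:
    """One-pass per-sample classifier: the brute-force counterpart of the
    pipeline's segmentation (velocity threshold, candidate scan, score)."""
    speeds = reference_speeds(rec, geometry, params.vel_window_ms)
    n = len(rec.t)
    labels = np.array(["fixation"] * n, dtype=object)
    for i in range(n):
        if not rec.valid[i]:
            labels[i] = "missing"
        elif np.isfinite(speeds[i]) and speeds[i] > params.saccade_vel_thresh:
            labels[i] = "saccade"
    dt = float(np.median(np.diff(rec.t))) if n > 1 else 1.0
    i = 0
    while i < n:
        if labels[i] == "fixation" and np.isfinite(speeds[i]) and speeds[i] <= params.pursuit_vel_max:
            j = i
            while (
                j < n
                and labels[j] == "fixation"
                and np.isfinite(speeds[j])
                and speeds[j] <= params.pursuit_vel_max
            ):
                j += 1
            if (j - i) * dt >= params.pursuit_min_dur_ms:
                tt, xx, yy = rec.t[i:j], rec.x[i:j], rec.y[i:j]
                disp = math.hypot(xx[-1] - xx[0], yy[-1] - yy[0])
                if len(tt) >= params.poly_degree + 2 and disp >= params.min_pursuit_displacement_px:
                    score = reference_pursuit_score(tt, xx, yy, params.poly_degree)
                    if score < params.score_thresh:
                        labels[i:j] = "pursuit"
            i = j
        else:
            i += 1
    return labels


def segments_from_labels(labels: np.ndarray, t: np.ndarray, dt: float):
    """Compress per-sample labels into (label, t_start, t_end) triples."""
    out = []
    start = 0
    edges = np.concatenate([t, [t[-1] + dt]])
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((str(labels[start]), float(edges[start]), float(edges[i])))
            start = i
    return out
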