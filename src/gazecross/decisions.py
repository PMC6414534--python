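"""Road-crossing decision statistics.

Four robust tools used on button-press data and oculomotor characteristics:

* :func:`kmeans_pp` — best-of-restarts k-means with k-means++ seeding, used
  to split participants into performance clusters by their mean number of
  crossing decisions.
* :func:`yuen_test` — Yuen's two-sample test on 20% trimmed means with
  winsorized variances and Welch–Satterthwaite degrees of freedom, plus an
  explanatory (xi-type) effect size reported as ``d``.
* :func:`shift_function` — Harrell–Davis decile estimates of two samples
  and their differences with percentile-bootstrap confidence intervals.
* :func:`density_split` — dichotomisation of per-trial vehicle counts into
  low/high traffic, either at a fixed cut (dense = more than 3 vehicles on
  screen) or at the centre of a Gaussian-kernel density estimate of the
  counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "ClusterResult",
    "YuenResult",
    "ShiftFunction",
    "kmeans_pp",
    "yuen_test",
    "harrell_davis",
    "shift_function",
    "density_split",
]

DECILES = np.arange(1, 10) / 10.0


@dataclass
class ClusterResult:
    k: int
    centroids: np.ndarray  # sorted ascending
    assignments: np.ndarray  # index into sorted centroids
    wcss: float
    n_restarts: int
    seed: int


@dataclass
class YuenResult:
    t: float
    df: float
    p: float
    d: float  # explanatory effect size
    trim: float


@dataclass
class ShiftFunction:
    deciles: np.ndarray  # 0.1 .. 0.9
    x_deciles: np.ndarray
    y_deciles: np.ndarray
    difference: np.ndarray  # x - y at each decile
    ci_low: np.ndarray
    ci_high: np.ndarray


def kmeans_pp(
    values: np.ndarray,
    k: int = 2,
    n_restarts: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Best-of-restarts Lloyd's algorithm with k-means++ seeding on 1D (or nD) data.

    Centroids are reported sorted ascending (by first coordinate for nD
    data) and assignments re-indexed accordingly.  Deterministic given
    ``seed``; the best run is the one with the lowest within-cluster sum of
    squares.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if len(v) < k:
        raise ValueError(f"need at least k={k} points, got {len(v)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    km.fit(v)
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return ClusterResult(
        k=k,
        centroids=km.cluster_centers_[order].squeeze(),
        assignments=remap[km.labels_],
        wcss=float(km.inertia_),
        n_restarts=n_restarts,
        seed=seed,
    )


def _winsorized(a: np.ndarray, g: int) -> np.ndarray:
    s = np.sort(a)
    if g > 0:
        s[:g] = s[g]
        s[len(s) - g :] = s[len(s) - g - 1]
    return s


def _trimmed_mean(a: np.ndarray, trim: float) -> float:
    return float(stats.trim_mean(a, trim)) if trim > 0 else float(np.mean(a))


def yuen_test(x: np.ndarray, y: np.ndarray, trim: float = 0.2, alpha: float = 0.05) -> YuenResult:
    """Yuen's test for trimmed-mean equality of two independent samples.

    With ``trim = 0`` this reduces exactly to Welch's t-test.  The effect
    size is the explanatory measure: the ratio of the variance of the
    "predicted" values (each observation replaced by its group's trimmed
    mean) to the variance of the winsorized pooled data, square-rooted —
    a robust analogue of a correlation-based effect size, reported as ``d``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not 0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    nx, ny = len(x), len(y)
    gx, gy = int(np.floor(trim * nx)), int(np.floor(trim * ny))
    hx, hy = nx - 2 * gx, ny - 2 * gy
    if hx < 2 or hy < 2:
        raise ValueError("samples too small for this trim proportion")

    mx, my = _trimmed_mean(x, trim), _trimmed_mean(y, trim)
    swx = np.var(_winsorized(x, gx), ddof=1)
    swy = np.var(_winsorized(y, gy), ddof=1)
    dx = (nx - 1) * swx / (hx * (hx - 1))
    dy = (ny - 1) * swy / (hy * (hy - 1))
    se = np.sqrt(dx + dy)
    t = 0.0 if se == 0 else (mx - my) / se
    df = (dx + dy) ** 2 / (dx**2 / (hx - 1) + dy**2 / (hy - 1)) if se > 0 else float(hx + hy - 2)
    p = 1.0 if se == 0 else float(2.0 * stats.t.sf(abs(t), df))

    # explanatory effect size: spread of the trimmed-mean prediction over
    # the winsorized spread of the pooled data
    yhat_var = np.var(np.concatenate([np.full(nx, mx), np.full(ny, my)]), ddof=1)
    pooled = np.concatenate([x, y])
    gp = int(np.floor(trim * len(pooled)))
    tot_var = np.var(_winsorized(pooled, gp), ddof=1)
    d = float(np.sqrt(yhat_var / tot_var)) if tot_var > 0 else 0.0
    return YuenResult(t=float(t), df=float(df), p=min(p, 1.0), d=d, trim=trim)


def _hd_weights(n: int, qs: np.ndarray) -> np.ndarray:
    """Beta-cdf weights of the order statistics, shape (len(qs), n).

    The weights depend only on the sample size and the quantiles, so
    bootstrap resamples of the same size reuse one weight matrix.
    """
    edges = np.arange(n + 1) / n
    a = (n + 1) * qs[:, None]
    b = (n + 1) * (1 - qs)[:, None]
    cdf = stats.beta.cdf(edges[None, :], a, b)
    return np.diff(cdf, axis=1)


def harrell_davis(a: np.ndarray, q: float | np.ndarray) -> np.ndarray:
    """Harrell–Davis quantile estimator: a beta-weighted mean of order statistics."""
    a = np.sort(np.asarray(a, float))
    n = len(a)
    if n < 2:
        raise ValueError("harrell_davis needs n >= 2")
    qs = np.atleast_1d(np.asarray(q, float))
    return _hd_weights(n, qs) @ a


def shift_function(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> ShiftFunction:
    """Decile shift function between two independent samples.

    Estimates the nine deciles of each sample with the Harrell–Davis
    estimator and forms the differences ``x - y``; percentile-bootstrap
    confidence intervals resample each sample independently.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 10 or len(y) < 10:
        raise ValueError("shift_function needs n >= 10 per sample")
    qx = harrell_davis(x, DECILES)
    qy = harrell_davis(y, DECILES)
    diff = qx - qy

    rng = np.random.default_rng(seed)
    wx = _hd_weights(len(x), DECILES)
    wy = _hd_weights(len(y), DECILES)
    bx = np.sort(rng.choice(x, (n_boot, len(x)), replace=True), axis=1)
    by = np.sort(rng.choice(y, (n_boot, len(y)), replace=True), axis=1)
    boot = bx @ wx.T - by @ wy.T  # (n_boot, 9)
    a = (1.0 - ci) / 2.0
    lo = np.quantile(boot, a, axis=0)
    hi = np.quantile(boot, 1.0 - a, axis=0)
    return ShiftFunction(
        deciles=DECILES.copy(),
        x_deciles=qx,
        y_deciles=qy,
        difference=diff,
        ci_low=np.minimum(lo, diff),
        ci_high=np.maximum(hi, diff),
    )


def kde_centre(counts: np.ndarray) -> float:
    """Centre of a Gaussian-KDE (Silverman bandwidth) of the counts.

    The centre is the half-mass point of the smoothed density (its median),
    which for two balanced traffic regimes falls in the trough between them
    — the natural place to dichotomise into low and high density.  Constant
    input returns that constant.
    """
    counts = np.asarray(counts, float)
    if np.ptp(counts) == 0:
        return float(counts[0])
    kde = stats.gaussian_kde(counts, bw_method="silverman")
    lo = counts.min() - 3 * kde.factor * counts.std()
    hi = counts.max() + 3 * kde.factor * counts.std()
    grid = np.linspace(lo, hi, 1024)
    dens = kde(grid)
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    return float(np.interp(0.5, cdf, grid))


def density_split(vehicle_counts: np.ndarray, rule: str | float = "fixed:3") -> tuple[np.ndarray, float]:
    """Classify per-trial vehicle counts into low/high traffic density.

    ``rule`` is either ``"fixed:<c>"`` (high iff count > c; the default cut
    is 3, i.e. dense means more than 3 vehicles on screen) or ``"kde"``
    (threshold at the centre of the count density, see :func:`kde_centre`).

    Returns ``(classes, threshold)`` with classes an array of "low"/"high".
    """
    counts = np.asarray(vehicle_counts)
    if counts.size == 0:
        raise ValueError("vehicle_counts is empty")
    if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("vehicle counts must be non-negative integers")
    if isinstance(rule, str) and rule.startswith("fixed"):
        threshold = float(rule.split(":")[1]) if ":" in rule else 3.0
    elif rule == "kde":
        threshold = kde_centre(counts.astype(float))
    else:
        raise ValueError(f"unknown density rule {rule!r}")
    classes = np.where(counts > threshold, "high", "low")
    return classes, threshold
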