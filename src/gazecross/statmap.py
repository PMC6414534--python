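"""Pixel-wise statistical mapping of gaze maps with bootstrap cluster correction.

Fixed-effect inference over z-scored gaze maps is done with a two-stage
summary-statistics scheme: maps are first averaged within each participant x
condition cell, then an ordinary linear model with the requested fixed
effects is fitted independently at every pixel.  Under a balanced design
this yields the same fixed-effect tests as a mixed model with a random
participant intercept, at a fraction of the cost.

Multiple comparisons across pixels are handled with a cluster-based
bootstrap: contiguous suprathreshold regions (8-connectivity) of the F (or
|t|) map are summarised by their mass (sum of the statistic over the
cluster), and compared against the distribution of the *maximum* cluster
mass obtained by refitting on participant-resampled residual maps (the
fitted effects removed), which controls the familywise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import label as cc_label

from .gazemaps import GazeMap

__all__ = [
    "StatMap",
    "DesignError",
    "pixelwise_fit",
    "cluster_bootstrap_correct",
    "contrast_map",
    "significant_area",
]


class DesignError(ValueError):
    """The design matrix cannot support the requested test."""


@dataclass
class Cluster:
    label: int
    size_px: int  # at map resolution
    mass: float
    significant: bool = False


@dataclass
class StatMap:
    """Per-pixel statistic map for one effect, optionally cluster-corrected."""

    effect: str
    stat: np.ndarray  # F map (kind="F") or signed t map (kind="t")
    kind: str
    df: tuple[float, float]  # (df1, df2) for F; (df, nan) for t
    coef: dict[str, np.ndarray] = field(default_factory=dict)
    downsample: int = 1
    threshold: float | None = None  # cluster-forming threshold on F or |t|
    mask: np.ndarray | None = None  # corrected significance mask
    clusters: list[Cluster] = field(default_factory=list)
    null_mass_quantile: float | None = None


def _as_stack(maps: Sequence[GazeMap] | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(maps, np.ndarray):
        return maps.astype(float), 1
    ds = maps[0].downsample
    return np.stack([m.grid for m in maps]).astype(float), ds


def _design_matrix(cells: pd.DataFrame, factors: list[str], effect: str) -> tuple[np.ndarray, np.ndarray]:
    """Intercept + treatment-coded main effects (+ the effect's interaction
    columns when ``effect`` contains ':').  Returns (X_full, effect_col_mask)."""
    cols: list[np.ndarray] = [np.ones(len(cells))]
    names: list[str] = ["Intercept"]
    owner: list[str] = ["Intercept"]

    def dummies(f: str) -> pd.DataFrame:
        d = pd.get_dummies(cells[f].astype(str), prefix=f, drop_first=True)
        return d.astype(float)

    for f in factors:
        d = dummies(f)
        for c in d.columns:
            cols.append(d[c].to_numpy())
            names.append(c)
            owner.append(f)
    if ":" in effect:
        f1, f2 = effect.split(":")
        d1, d2 = dummies(f1), dummies(f2)
        for c1 in d1.columns:
            for c2 in d2.columns:
                cols.append(d1[c1].to_numpy() * d2[c2].to_numpy())
                names.append(f"{c1}:{c2}")
                owner.append(effect)
    X = np.column_stack(cols)
    is_effect = np.array([o == effect for o in owner])
    if not is_effect.any():
        raise DesignError(f"effect {effect!r} not among factors {factors}")
    return X, is_effect


def _rss(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Residual sum of squares per column of Y, plus fitted coefficients and rank."""
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.einsum("ij,ij->j", resid, resid), beta, rank


def _ortho(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank-revealing)."""
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    return Q[:, keep]


def _fmap_proj(
    Qf: np.ndarray, Qr: np.ndarray, Y: np.ndarray, df1: float, df2: float
) -> np.ndarray:
    """F map from precomputed orthonormal bases of the full/reduced designs."""
    yy = np.einsum("ij,ij->j", Y, Y)
    cf = Qf.T @ Y
    cr = Qr.T @ Y
    rss_f = yy - np.einsum("ij,ij->j", cf, cf)
    rss_r = yy - np.einsum("ij,ij->j", cr, cr)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    return np.maximum(np.where(rss_f <= 0, 0.0, F), 0.0)


def _fmap(X: np.ndarray, effect_cols: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, float, float, np.ndarray]:
    rss_full, beta, rank_full = _rss(X, Y)
    X_red = X[:, ~effect_cols]
    rss_red, _, rank_red = _rss(X_red, Y)
    df1 = rank_full - rank_red
    df2 = X.shape[0] - rank_full
    if df1 <= 0:
        raise DesignError("effect columns are aliased with the reduced model")
    if df2 <= 0:
        raise DesignError("no residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    # guard degenerate pixels where the model fits exactly (rounding-level RSS)
    tiny = rss_red <= 1e-12 * max(float(np.einsum("ij,ij->j", Y, Y).max()), 1.0)
    F = np.where(tiny | (rss_full <= 0), 0.0, F)
    return np.maximum(F, 0.0), float(df1), float(df2), beta


def _aggregate_cells(
    maps: Sequence[GazeMap] | np.ndarray,
    design: pd.DataFrame,
    factors: list[str],
) -> tuple[np.ndarray, pd.DataFrame, int, tuple[int, int]]:
    """Average maps within participant x condition cell."""
    stack, ds = _as_stack(maps)
    if len(stack) != len(design):
        raise ValueError("one design row per map required")
    shape = stack.shape[1:]
    flat = stack.reshape(len(stack), -1)
    df = design.reset_index(drop=True).copy()
    keys = ["participant_id"] + factors
    groups = df.groupby(keys, sort=True, observed=True).indices
    cell_rows = []
    Y = np.empty((len(groups), flat.shape[1]))
    for i, (key, idx) in enumerate(sorted(groups.items())):
        Y[i] = flat[np.asarray(idx)].mean(axis=0)
        key = (key,) if not isinstance(key, tuple) else key
        cell_rows.append(dict(zip(keys, key)))
    cells = pd.DataFrame(cell_rows)
    for f in factors:
        levels = cells.groupby(f, observed=True).size()
        if len(levels) < 2:
            raise DesignError(f"factor {f!r} needs >= 2 levels, has {len(levels)}")
    return Y, cells, ds, shape


def pixelwise_fit(
    maps: Sequence[GazeMap] | np.ndarray,
    design: pd.DataFrame,
    effect: str,
    factors: list[str] | None = None,
) -> StatMap:
    """Uncorrected per-pixel F map for ``effect``.

    ``design`` has one row per map with a ``participant_id`` column and one
    column per factor.  ``factors`` defaults to the main effect(s) named in
    ``effect`` (use ``"a:b"`` for an interaction, which adds both mains).
    """
    base = effect.split(":")
    factors = list(factors) if factors is not None else base
    for f in base:
        if f not in factors:
            factors.append(f)
    Y, cells, ds, shape = _aggregate_cells(maps, design, factors)
    X, eff_cols = _design_matrix(cells, factors, effect)
    F, df1, df2, beta = _fmap(X, eff_cols, Y)
    names = _column_names(cells, factors, effect)
    coef = {name: beta[i].reshape(shape) for i, name in enumerate(names)}
    return StatMap(
        effect=effect,
        stat=F.reshape(shape),
        kind="F",
        df=(df1, df2),
        coef=coef,
        downsample=ds,
    )


def _column_names(cells: pd.DataFrame, factors: list[str], effect: str) -> list[str]:
    names = ["Intercept"]
    for f in factors:
        d = pd.get_dummies(cells[f].astype(str), prefix=f, drop_first=True)
        names.extend(d.columns)
    if ":" in effect:
        f1, f2 = effect.split(":")
        d1 = pd.get_dummies(cells[f1].astype(str), prefix=f1, drop_first=True)
        d2 = pd.get_dummies(cells[f2].astype(str), prefix=f2, drop_first=True)
        names.extend(f"{c1}:{c2}" for c1 in d1.columns for c2 in d2.columns)
    return names


def _clusters(stat: np.ndarray, threshold: float) -> tuple[np.ndarray, list[Cluster]]:
    mask = stat > threshold
    lab = cc_label(mask, connectivity=2)
    out = []
    for k in range(1, lab.max() + 1):
        sel = lab == k
        out.append(Cluster(label=k, size_px=int(sel.sum()), mass=float(stat[sel].sum())))
    return lab, out


def _max_cluster_mass(stat: np.ndarray, threshold: float) -> float:
    mask = stat > threshold
    if not mask.any():
        return 0.0
    lab = cc_label(mask, connectivity=2)
    return float(max(stat[lab == k].sum() for k in range(1, lab.max() + 1)))


def _strata(cells: pd.DataFrame, factors: list[str]) -> list[np.ndarray]:
    """Row indices of each participant, grouped so that resampling keeps the
    between-participant design intact (participants are swapped only within
    identical between-factor combinations)."""
    between = []
    for f in factors:
        per_part = cells.groupby("participant_id", observed=True)[f].nunique()
        if (per_part == 1).all():
            between.append(f)
    strata: list[list[np.ndarray]] = []
    grouped = cells.groupby(between, observed=True) if between else [(None, cells)]
    for _, sub in grouped:
        strata.append(
            [sub.index[sub["participant_id"] == p].to_numpy() for p in sub["participant_id"].unique()]
        )
    return strata


def cluster_bootstrap_correct(
    statmap: StatMap,
    maps: Sequence[GazeMap] | np.ndarray,
    design: pd.DataFrame,
    alpha: float = 0.05,
    n_boot: int = 500,
    seed: int = 0,
    factors: list[str] | None = None,
) -> StatMap:
    """Cluster-mass bootstrap correction of an uncorrected F map.

    The cluster-forming threshold is the pointwise ``1 - alpha`` F quantile.
    The null distribution of the maximum cluster mass is built by refitting
    the model on residual maps (all fixed effects removed) whose participants
    are resampled with replacement within their design stratum.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for cluster correction")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    effect = statmap.effect
    base = effect.split(":")
    factors = list(factors) if factors is not None else base
    for f in base:
        if f not in factors:
            factors.append(f)
    Y, cells, ds, shape = _aggregate_cells(maps, design, factors)
    X, eff_cols = _design_matrix(cells, factors, effect)
    F, df1, df2, beta = _fmap(X, eff_cols, Y)
    threshold = float(stats.f.ppf(1.0 - alpha, df1, df2))
    F_map = F.reshape(shape)
    lab, clusters = _clusters(F_map, threshold)

    # effect-removed residuals are the bootstrap population
    resid = Y - X @ beta
    strata = _strata(cells, factors)
    Qf = _ortho(X)
    Qr = _ortho(X[:, ~eff_cols])
    rng = np.random.default_rng(seed)
    null_mass = np.empty(n_boot)
    for b in range(n_boot):
        # swap each participant's residual block for a same-stratum donor's,
        # keeping the design rows aligned (requires balanced cells)
        idx = np.empty(len(cells), dtype=int)
        for participants in strata:
            k = len(participants)
            donors = rng.integers(0, k, size=k)
            for slot, j in enumerate(donors):
                src, dst = participants[j], participants[slot]
                if len(src) != len(dst):
                    raise DesignError(
                        "participant cells are unbalanced; residual bootstrap needs balanced cells"
                    )
                idx[dst] = src
        Fb = _fmap_proj(Qf, Qr, resid[idx], df1, df2)
        null_mass[b] = _max_cluster_mass(Fb.reshape(shape), threshold)
    q = float(np.quantile(null_mass, 1.0 - alpha))

    mask = np.zeros(shape, dtype=bool)
    for c in clusters:
        c.significant = c.mass > q
        if c.significant:
            mask |= lab == c.label
    return StatMap(
        effect=effect,
        stat=F_map,
        kind="F",
        df=(df1, df2),
        coef=statmap.coef,
        downsample=ds,
        threshold=threshold,
        mask=mask,
        clusters=clusters,
        null_mass_quantile=q,
    )


def contrast_map(
    maps: Sequence[GazeMap] | np.ndarray,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    column: str = "age_group",
    alpha: float = 0.05,
    n_boot: int = 500,
    seed: int = 0,
) -> StatMap:
    """Signed pairwise-contrast t map (group_a - group_b) with cluster correction.

    Participant-mean maps are compared with a pooled-variance two-sample t
    per pixel; clusters form where ``|t|`` exceeds the pointwise two-sided
    threshold, and cluster mass (sum of |t|) is tested against the maximum
    cluster mass over within-group resamples of mean-centred maps.
    """
    for g in (group_a, group_b):
        if g not in set(design[column].astype(str)):
            raise KeyError(f"group {g!r} not present in design column {column!r}")
    stack, ds = _as_stack(maps)
    shape = stack.shape[1:]
    flat = stack.reshape(len(stack), -1)
    df = design.reset_index(drop=True)

    def part_means(group: str) -> np.ndarray:
        sub = df.index[df[column].astype(str) == group]
        sel = df.loc[sub]
        return np.stack(
            [flat[sel.index[sel["participant_id"] == p]].mean(axis=0) for p in sel["participant_id"].unique()]
        )

    A, B = part_means(group_a), part_means(group_b)
    na, nb = len(A), len(B)
    if min(na, nb) < 2:
        raise DesignError("each group needs >= 2 participants")
    dof = na + nb - 2

    def tmap(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        va = A.var(axis=0, ddof=1)
        vb = B.var(axis=0, ddof=1)
        sp = ((na - 1) * va + (nb - 1) * vb) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (A.mean(axis=0) - B.mean(axis=0)) / np.sqrt(sp * (1 / na + 1 / nb))
        return np.where(sp <= 0, 0.0, t)

    t_obs = tmap(A, B).reshape(shape)
    threshold = float(stats.t.ppf(1.0 - alpha / 2.0, dof))
    lab, clusters = _clusters(np.abs(t_obs), threshold)

    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    rng = np.random.default_rng(seed)
    null_mass = np.empty(n_boot)
    for b in range(n_boot):
        Ab = A0[rng.integers(0, na, na)]
        Bb = B0[rng.integers(0, nb, nb)]
        null_mass[b] = _max_cluster_mass(np.abs(tmap(Ab, Bb)).reshape(shape), threshold)
    q = float(np.quantile(null_mass, 1.0 - alpha))

    mask = np.zeros(shape, dtype=bool)
    for c in clusters:
        c.significant = c.mass > q
        if c.significant:
            mask |= lab == c.label
    return StatMap(
        effect=f"{group_a}-{group_b}",
        stat=t_obs,
        kind="t",
        df=(float(dof), float("nan")),
        downsample=ds,
        threshold=threshold,
        mask=mask,
        clusters=clusters,
        null_mass_quantile=q,
    )


def significant_area(statmap: StatMap) -> int:
    """Significant pixel count rescaled to full-resolution screen pixels."""
    if statmap.mask is None:
        raise ValueError("statmap has no corrected mask; run cluster correction first")
    return int(statmap.mask.sum()) * statmap.downsample**2
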