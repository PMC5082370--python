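"""Intraclass-correlation synchronization surfaces and companion measures.

Synchronization of cells sharing a droplet is quantified with the
intraclass correlation (ICC) under a balanced one-way variance-components
model: at one time point, with n droplets of exactly a cells each and X_ij
the fluorescence of cell j in droplet i,

    SS_B = a * sum_i (Xbar_i - Xbar)^2        (between droplets, n-1 df)
    SS_W = sum_ij (X_ij - Xbar_i)^2           (within droplets, n(a-1) df)
    EMS_B = SS_B/(n-1),  EMS_W = SS_W/(n(a-1))
    ICC   = (EMS_B - EMS_W) / (EMS_B + (a-1) * EMS_W)

which estimates the within-droplet correlation rho by equating the mean
squares to their expectations sigma^2(1 + (a-1)rho) and sigma^2(1 - rho).
The ICC *surface* evaluates this on every (cells-per-droplet, time) cell of
the experiment. The strangers-resampling control replaces each cell of a
multi-cell droplet with a random singleton at the same time point,
destroying any within-droplet communication signal while preserving the
marginal fluorescence distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import spearman
from .tables import TrajectorySet

__all__ = [
    "icc",
    "ICCSurface",
    "icc_surface",
    "strangers_control",
    "garcia_ojalvo_R",
    "kuramoto_order",
    "SurfaceRegression",
    "surface_regression",
    "period_vs_droplet_size",
]


def icc(snapshot: np.ndarray) -> tuple[float, float, float]:
    """ICC of one balanced droplets-by-cells snapshot.

    ``snapshot`` has shape (n_droplets, a). Returns (ICC, EMS_B, EMS_W).
    Raises for n < 2 or a < 2; a zero total sum of squares is degenerate
    and returns NaN for the ICC (flagged by the NaN itself).
    """
    X = np.asarray(snapshot, dtype=float)
    if X.ndim != 2:
        raise ValueError("snapshot must be a droplets x cells matrix")
    n, a = X.shape
    if n < 2 or a < 2:
        raise ValueError("need at least 2 droplets of at least 2 cells")
    mi = X.mean(axis=1)
    m = X.mean()
    ss_b = a * np.sum((mi - m) ** 2)
    ss_w = np.sum((X - mi[:, None]) ** 2)
    if ss_b + ss_w == 0:
        return np.nan, 0.0, 0.0
    ems_b = ss_b / (n - 1)
    ems_w = ss_w / (n * (a - 1))
    denom = ems_b + (a - 1) * ems_w
    return float((ems_b - ems_w) / denom), float(ems_b), float(ems_w)


@dataclass
class ICCSurface:
    """ICC over (cells-per-droplet a, frame), with droplet counts per a.

    ``values`` has shape (len(a_levels), n_frames); cells where fewer than
    ``min_droplets`` droplets of exactly that size exist are NaN.
    """

    a_levels: np.ndarray
    frames: np.ndarray
    values: np.ndarray
    n_droplets: np.ndarray  # per a-level

    def row(self, a: int) -> np.ndarray:
        return self.values[list(self.a_levels).index(a)]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, a in enumerate(self.a_levels):
            for j, fr in enumerate(self.frames):
                recs.append((a, fr, self.values[i, j], self.n_droplets[i]))
        return pd.DataFrame(recs, columns=["a", "frame", "icc", "n_droplets"])


def _droplet_groups(ts: TrajectorySet) -> dict:
    """droplet_id -> row indices, using the set's droplet assignment."""
    groups: dict = {}
    for i, d in enumerate(ts.droplet_ids):
        groups.setdefault(d, []).append(i)
    return groups


def icc_surface(ts: TrajectorySet, min_droplets: int = 2) -> ICCSurface:
    """ICC surface of a trajectory set, stratified by exact droplet size.

    For each droplet size a >= 2 represented by at least ``min_droplets``
    droplets, the ICC is computed independently at every frame.
    """
    groups = _droplet_groups(ts)
    by_size: dict = {}
    for d, idx in groups.items():
        by_size.setdefault(len(idx), []).append(idx)
    sizes = sorted(a for a, g in by_size.items() if a >= 2 and len(g) >= min_droplets)
    if not sizes:
        return ICCSurface(
            a_levels=np.array([], dtype=int), frames=ts.frames.copy(),
            values=np.zeros((0, ts.n_frames)), n_droplets=np.array([], dtype=int),
        )
    values = np.full((len(sizes), ts.n_frames), np.nan)
    counts = np.zeros(len(sizes), dtype=int)
    for i, a in enumerate(sizes):
        rows = np.array(by_size[a])  # (n_droplets, a) of row indices
        counts[i] = rows.shape[0]
        data = ts.values[rows]  # (n_droplets, a, n_frames)
        for j in range(ts.n_frames):
            values[i, j] = icc(data[:, :, j])[0]
    return ICCSurface(
        a_levels=np.asarray(sizes, dtype=int), frames=ts.frames.copy(),
        values=values, n_droplets=counts,
    )


def strangers_control(
    ts: TrajectorySet,
    n_reps: int = 20,
    seed: int = 0,
    min_droplets: int = 2,
) -> list:
    """Strangers-resampling null surfaces.

    For every replicate, each cell in every multi-cell droplet is replaced,
    at every frame independently, by the value of a singleton cell drawn
    with replacement from the singleton pool at the same frame; the ICC
    surface of the resampled data is recomputed. Returns the list of
    ``n_reps`` null surfaces.
    """
    groups = _droplet_groups(ts)
    singles = [idx[0] for idx in groups.values() if len(idx) == 1]
    if not singles:
        raise ValueError("strangers control needs singleton cells in the pool")
    pool = ts.values[np.asarray(singles)]  # (n_single, n_frames)
    multi_rows = np.asarray(
        [i for idx in groups.values() if len(idx) > 1 for i in idx]
    )
    rng = np.random.default_rng(seed)
    surfaces = []
    for _ in range(n_reps):
        resampled = ts.values.copy()
        draw = rng.integers(0, pool.shape[0], size=(multi_rows.size, ts.n_frames))
        resampled[multi_rows] = pool[draw, np.arange(ts.n_frames)[None, :]]
        null_ts = ts.copy_with(values=resampled)
        surfaces.append(icc_surface(null_ts, min_droplets=min_droplets))
    return surfaces


def garcia_ojalvo_R(droplet_values: np.ndarray) -> float:
    """Variance of the within-droplet mean trajectory over the mean
    single-cell variance.

    ``droplet_values`` has shape (a, n_frames) with a >= 2. R = 1 for
    identical trajectories, ~1/a for independent cells, 0 for exactly
    cancelling (e.g. antiphase) cells. NaN when the single-cell variance is
    zero.
    """
    X = np.asarray(droplet_values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (a >= 2) x frames matrix")
    if X.shape[1] < 10:
        raise ValueError("need at least 10 frames")
    denom = X.var(axis=1, ddof=1).mean()
    if denom == 0:
        return np.nan
    return float(X.mean(axis=0).var(ddof=1) / denom)


def kuramoto_order(phases_rad: np.ndarray, droplet_ids, by_size: bool = True):
    """Time-averaged Kuramoto order parameter per droplet, averaged per
    droplet-size stratum.

    ``phases_rad`` has shape (n_cells, n_frames) in radians;
    ``droplet_ids`` aligns cells to droplets. Per droplet,
    K = mean_t | (1/a) sum_j exp(i phi_j(t)) |; with ``by_size`` the per-
    droplet values are averaged within each exact-size stratum and a dict
    {a: K} is returned, otherwise a dict {droplet_id: K}.
    """
    phases_rad = np.asarray(phases_rad, dtype=float)
    groups: dict = {}
    for i, d in enumerate(droplet_ids):
        groups.setdefault(d, []).append(i)
    per_droplet = {}
    for d, idx in groups.items():
        z = np.exp(1j * phases_rad[idx])
        per_droplet[d] = float(np.abs(z.mean(axis=0)).mean())
    if not by_size:
        return per_droplet
    out: dict = {}
    for d, idx in groups.items():
        out.setdefault(len(idx), []).append(per_droplet[d])
    return {a: float(np.mean(v)) for a, v in sorted(out.items())}


@dataclass
class SurfaceRegression:
    """Common-slope, per-size-intercept fit of one ICC surface on another."""

    slope: float
    intercepts: dict  # a -> b_a
    r_squared: float
    slope_se: float
    mean_icc_y: dict  # a -> (mean, 2*SE)
    n_points: int


def surface_regression(y: ICCSurface, x: ICCSurface) -> SurfaceRegression:
    """Least squares of y-surface values on x-surface values.

    The model is y = m*x + b_a: one common slope and one intercept per
    droplet size a. Strata with fewer than 3 jointly defined points are
    dropped with a warning-free skip; all defined (a, frame) cells weigh
    equally.
    """
    common_a = [a for a in y.a_levels if a in set(x.a_levels)]
    xs, ys, labels = [], [], []
    for a in common_a:
        yr = y.row(a)
        xr = x.row(a)
        m = min(yr.size, xr.size)
        ok = np.isfinite(yr[:m]) & np.isfinite(xr[:m])
        if ok.sum() < 3:
            continue
        xs.append(xr[:m][ok])
        ys.append(yr[:m][ok])
        labels.extend([a] * int(ok.sum()))
    if not xs:
        raise ValueError("no stratum with >= 3 jointly defined surface cells")
    xv = np.concatenate(xs)
    yv = np.concatenate(ys)
    labels = np.asarray(labels)
    strata = sorted(set(labels.tolist()))
    # design: [x, dummy_a2, dummy_a3, ...]
    D = np.zeros((xv.size, 1 + len(strata)))
    D[:, 0] = xv
    for k, a in enumerate(strata):
        D[labels == a, 1 + k] = 1.0
    coef, *_ = np.linalg.lstsq(D, yv, rcond=None)
    fitted = D @ coef
    ss_res = float(np.sum((yv - fitted) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    dof = max(yv.size - D.shape[1], 1)
    s2 = ss_res / dof
    cov = s2 * np.linalg.inv(D.T @ D)
    mean_icc = {}
    for a in strata:
        vals = yv[labels == a]
        mean_icc[a] = (float(vals.mean()), float(2 * vals.std(ddof=1) / np.sqrt(vals.size)))
    return SurfaceRegression(
        slope=float(coef[0]),
        intercepts={a: float(coef[1 + k]) for k, a in enumerate(strata)},
        r_squared=r2,
        slope_se=float(np.sqrt(cov[0, 0])),
        mean_icc_y=mean_icc,
        n_points=int(yv.size),
    )


def period_vs_droplet_size(
    periods_primary: np.ndarray,
    droplet_ids,
    periods_secondary: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-droplet-size mean and variance of single-cell periods, with
    Spearman rank tests of each column against droplet size a.

    Returns the per-size summary table and a dict of
    {column_name: (r_s, p)} Spearman results.
    """
    periods_primary = np.asarray(periods_primary, dtype=float)
    sizes: dict = {}
    for i, d in enumerate(droplet_ids):
        sizes.setdefault(d, []).append(i)
    cell_a = np.empty(periods_primary.size, dtype=int)
    for d, idx in sizes.items():
        cell_a[idx] = len(idx)
    recs = []
    for a in sorted(set(cell_a.tolist())):
        sel = cell_a == a
        if sel.sum() < 2:
            continue
        rec = {
            "a": a,
            "mean_period": periods_primary[sel].mean(),
            "var_period": periods_primary[sel].var(ddof=1),
            "n_cells": int(sel.sum()),
        }
        if periods_secondary is not None:
            ps = np.asarray(periods_secondary, dtype=float)[sel]
            ps = ps[np.isfinite(ps)]
            if ps.size >= 2:
                rec["mean_period_secondary"] = ps.mean()
                rec["var_period_secondary"] = ps.var(ddof=1)
        recs.append(rec)
    table = pd.DataFrame(recs)
    tests = {}
    for col in table.columns:
        if col in ("a", "n_cells"):
            continue
        sub = table[["a", col]].dropna()
        if len(sub) >= 3:
            try:
                tests[col] = spearman(sub["a"].to_numpy(), sub[col].to_numpy())
            except ValueError:  # constant column: correlation undefined
                tests[col] = (np.nan, np.nan)
    return table, tests
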