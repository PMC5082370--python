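"""Normalization, detrending and quality control of raw trajectories.

The measurement chain motivating these steps: the fluorescence recorded for
each cell is modulated by shared excitation-lamp fluctuations (removed by
dividing by the concurrently imaged Rhodamine-B reference), rides on slow
nonstationarities such as photobleaching (removed by subtracting a centered
24-h moving average), and individual cells can be mistracked (removed by
rule-based quality filters).

Detrending is a *linear* operator; its weights are exported so the detector
noise propagation in :mod:`dropclock.varpart` can push measurement noise
through exactly the same filter the data went through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FRAME_DT_H, TrajectorySet, table_to_set

__all__ = [
    "rhodamine_normalize",
    "moving_average_detrend",
    "ma_kernel",
    "ma_transfer",
    "detrend_matrix",
    "qc_filter",
    "QCReport",
    "DEFAULT_WINDOW_H",
    "ANALYSIS_WINDOW_FRAMES",
]

DEFAULT_WINDOW_H = 24.0
#: default phase-analysis window in original frame indices (85 h span)
ANALYSIS_WINDOW_FRAMES = (60, 230)


def rhodamine_normalize(table: pd.DataFrame) -> tuple[TrajectorySet, np.ndarray]:
    """Divide every cell series frame-wise by the shared reference series.

    Returns the normalized TrajectorySet and the reference series used.
    Raises if the reference is nonpositive anywhere, naming the frames.
    """
    ts, rho = table_to_set(table)
    bad = np.flatnonzero(~(rho > 0))
    if bad.size:
        raise ValueError(f"nonpositive rhodamine reference at frames {bad.tolist()}")
    out = ts.copy_with(values=ts.values / rho[None, :], normalized=True)
    return out, rho


def ma_kernel(window_h: float = DEFAULT_WINDOW_H, frame_dt: float = FRAME_DT_H) -> np.ndarray:
    """Symmetric, exactly centered moving-average weights.

    A ``window_h`` of 24 h at 0.5 h frames gives a 49-point window (half
    width 24 frames); an odd length keeps the filter zero-phase so its
    transfer function is real.
    """
    half = int(round(window_h / frame_dt / 2))
    w = 2 * half + 1
    return np.full(w, 1.0 / w)


def ma_transfer(f_cycles_per_frame: np.ndarray, window: int) -> np.ndarray:
    """Real transfer function of the centered ``window``-point moving average.

    Dirichlet kernel sin(pi w f)/(w sin(pi f)) with the f -> 0 limit of 1.
    The detrend step (subtract the MA) therefore attenuates a sinusoid of
    frequency f by the factor 1 - ma_transfer(f, w).
    """
    f = np.asarray(f_cycles_per_frame, dtype=float)
    out = np.ones_like(f)
    nz = f != 0
    out[nz] = np.sin(np.pi * window * f[nz]) / (window * np.sin(np.pi * f[nz]))
    return out


def moving_average_detrend(
    ts: TrajectorySet, window_h: float = DEFAULT_WINDOW_H
) -> TrajectorySet:
    """Subtract a centered moving average; drop edge frames.

    Edge frames where the full window does not fit carry a partially
    supported average and are dropped from the analysis window rather than
    computed with shrunken windows — this keeps the operator's weights
    identical for every retained frame, which the noise propagation relies
    on.
    """
    kernel = ma_kernel(window_h)
    half = kernel.size // 2
    if ts.n_frames <= kernel.size:
        raise ValueError(
            f"series of {ts.n_frames} frames shorter than the "
            f"{kernel.size}-frame detrending window"
        )
    # full-window moving average, valid region only
    ma = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, ts.values)
    interior = ts.values[:, half:-half]
    detrended = interior - ma
    return ts.copy_with(
        values=detrended, frames=ts.frames[half:-half], detrended=True
    )


def detrend_matrix(n_frames: int, window_h: float = DEFAULT_WINDOW_H) -> np.ndarray:
    """Dense matrix Q with (Q x) equal to moving_average_detrend of x.

    Shape (n_frames - w + 1, n_frames) for a w-point window. Used to
    propagate white detector noise through the exact detrending filter.
    """
    kernel = ma_kernel(window_h)
    w = kernel.size
    half = w // 2
    n_out = n_frames - w + 1
    if n_out <= 0:
        raise ValueError("series shorter than the detrending window")
    Q = np.zeros((n_out, n_frames))
    for i in range(n_out):
        Q[i, i + half] = 1.0
        Q[i, i : i + w] -= kernel
    return Q


@dataclass
class QCReport:
    """Counts of cells rejected per quality rule."""

    n_input: int
    n_kept: int
    rejected: dict

    def __str__(self) -> str:
        parts = ", ".join(f"{k}: {len(v)}" for k, v in self.rejected.items())
        return f"QC kept {self.n_kept}/{self.n_input} cells ({parts})"


def qc_filter(
    ts: TrajectorySet,
    spike_mad: float = 10.0,
    min_frame_fraction: float = 0.95,
    drop_flat: bool = True,
) -> tuple[TrajectorySet, QCReport]:
    """Remove improperly tracked cells.

    Rules (each configurable):

    * ``missing``  — more than ``1 - min_frame_fraction`` of frames non-finite
      (a stand-in for tracking dropouts).
    * ``spike``    — any frame deviating from the cell median by more than
      ``spike_mad`` times the cell's median absolute deviation (tracking
      jumps onto a neighboring particle).
    * ``flat``     — zero variance (dead recorder / stuck pixel).
    """
    rejected = {"missing": [], "spike": [], "flat": []}
    keep = []
    for i in range(ts.n_cells):
        row = ts.values[i]
        finite = np.isfinite(row)
        if finite.mean() < min_frame_fraction:
            rejected["missing"].append(ts.cell_ids[i])
            continue
        r = row[finite]
        med = np.median(r)
        mad = np.median(np.abs(r - med))
        if drop_flat and (r.std() == 0 or mad == 0):
            rejected["flat"].append(ts.cell_ids[i])
            continue
        if np.max(np.abs(r - med)) > spike_mad * mad:
            rejected["spike"].append(ts.cell_ids[i])
            continue
        keep.append(i)
    report = QCReport(n_input=ts.n_cells, n_kept=len(keep), rejected=rejected)
    kept = ts.subset_cells(np.asarray(keep, dtype=int))
    return kept, report
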