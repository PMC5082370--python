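"""Long-format trajectory tables and their in-memory matrix form.

The on-disk interchange format throughout the package is a delimited text
table with one row per (cell, frame):

    droplet_id, cell_id, frame, fluorescence, rhodamine[, is_bead]

Frames are spaced 0.5 h apart. One Rhodamine-B reference series is shared by
every cell in an acquisition, so the ``rhodamine`` column is a function of
``frame`` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FRAME_DT_H = 0.5  # imaging cadence: one frame every 30 minutes

REQUIRED_COLUMNS = ("droplet_id", "cell_id", "frame", "fluorescence", "rhodamine")


def validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    if (table["fluorescence"] <= 0).any():
        raise ValueError("fluorescence must be positive in a raw table")
    if (table["rhodamine"] <= 0).any():
        raise ValueError("rhodamine reference must be positive")


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_table(table)
    return table


@dataclass
class TrajectorySet:
    """Cells-by-frames matrix view of a trajectory table.

    Attributes
    ----------
    values : ndarray, shape (n_cells, n_frames)
        Fluorescence (raw, normalized, or detrended depending on flags).
    cell_ids : list of str
    droplet_ids : list of str
        Droplet containing each cell, aligned with ``cell_ids``.
    frames : ndarray of int
        Frame indices of the columns (contiguous).
    normalized, detrended : bool
        Provenance flags set by the preprocessing steps.
    """

    values: np.ndarray
    cell_ids: list = field(default_factory=list)
    droplet_ids: list = field(default_factory=list)
    frames: np.ndarray = None
    normalized: bool = False
    detrended: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.frames is None:
            self.frames = np.arange(self.values.shape[1])
        self.frames = np.asarray(self.frames, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a cells x frames matrix")
        if self.values.shape[1] != self.frames.size:
            raise ValueError("frames must match the number of columns")
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("frame grid must be contiguous")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times_h(self) -> np.ndarray:
        return self.frames * FRAME_DT_H

    def copy_with(self, values=None, frames=None, **flags) -> "TrajectorySet":
        out = TrajectorySet(
            values=self.values.copy() if values is None else values,
            cell_ids=list(self.cell_ids),
            droplet_ids=list(self.droplet_ids),
            frames=self.frames.copy() if frames is None else frames,
            normalized=self.normalized,
            detrended=self.detrended,
        )
        for k, v in flags.items():
            setattr(out, k, v)
        return out

    def subset_cells(self, index) -> "TrajectorySet":
        index = np.asarray(index)
        return TrajectorySet(
            values=self.values[index],
            cell_ids=[self.cell_ids[i] for i in index],
            droplet_ids=[self.droplet_ids[i] for i in index],
            frames=self.frames.copy(),
            normalized=self.normalized,
            detrended=self.detrended,
        )


def table_to_set(table: pd.DataFrame) -> tuple[TrajectorySet, np.ndarray]:
    """Pivot a long-format table into a TrajectorySet plus the shared
    rhodamine series (indexed by frame)."""
    validate_table(table)
    wide = table.pivot_table(
        index=["droplet_id", "cell_id"], columns="frame", values="fluorescence"
    )
    if wide.isna().any().any():
        raise ValueError("incomplete frame grid: missing (cell, frame) entries")
    frames = np.asarray(wide.columns, dtype=int)
    if np.any(np.diff(frames) != 1):
        raise ValueError("frame grid must be contiguous")
    rho = (
        table.drop_duplicates("frame")
        .set_index("frame")["rhodamine"]
        .reindex(frames)
        .to_numpy()
    )
    droplet_ids = [d for d, _ in wide.index]
    cell_ids = [c for _, c in wide.index]
    ts = TrajectorySet(
        values=wide.to_numpy(), cell_ids=cell_ids, droplet_ids=droplet_ids, frames=frames
    )
    return ts, rho


def set_to_table(ts: TrajectorySet, rhodamine: np.ndarray | None = None) -> pd.DataFrame:
    """Flatten a TrajectorySet back into the long format."""
    rho = np.ones(ts.n_frames) if rhodamine is None else np.asarray(rhodamine, float)
    rows = {
        "droplet_id": np.repeat(ts.droplet_ids, ts.n_frames),
        "cell_id": np.repeat(ts.cell_ids, ts.n_frames),
        "frame": np.tile(ts.frames, ts.n_cells),
        "fluorescence": ts.values.ravel(),
        "rhodamine": np.tile(rho, ts.n_cells),
    }
    return pd.DataFrame(rows)
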