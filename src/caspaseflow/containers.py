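"""Shared in-memory containers for per-cell multi-channel time series.

All trace containers share a uniform time grid: ``time_s = frame * frame_interval``.
Intensities are in arbitrary linear units; nothing downstream depends on the
absolute scale (every derived quantity is a ratio or is normalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ChannelTraceSet", "AbundanceTraceSet"]


@dataclass
class ChannelTraceSet:
    """Per-cell, per-channel mean-intensity time series on a fixed frame grid.

    Parameters
    ----------
    cell_ids
        One identifier per cell (row of ``data``).
    labels
        Detection-channel (or fluorophore) names, one per ``data`` column axis.
    frame_interval
        Seconds between frames.
    data
        Array of shape ``(n_cells, n_labels, n_frames)``.
    """

    cell_ids: list
    labels: tuple
    frame_interval: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (n_cells, n_labels, n_frames)")
        if self.data.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length does not match data")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("labels length does not match data")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time of each frame in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    def cell(self, cell_id) -> np.ndarray:
        """Return the ``(n_labels, n_frames)`` block for one cell."""
        return self.data[self.cell_ids.index(cell_id)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cell_id, frame, time_s, channel, intensity."""
        n_cells, n_labels, n_frames = self.data.shape
        cells = np.repeat(self.cell_ids, n_labels * n_frames)
        chans = np.tile(np.repeat(self.labels, n_frames), n_cells)
        frames = np.tile(np.arange(n_frames), n_cells * n_labels)
        return pd.DataFrame(
            {
                "cell_id": cells,
                "frame": frames,
                "time_s": frames * self.frame_interval,
                "channel": chans,
                "intensity": self.data.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_interval: float | None = None) -> "ChannelTraceSet":
        """Rebuild from the long format written by :meth:`to_frame`.

        Requires a complete uniform grid: every cell must have every channel at
        every frame (gaps are an input error, not silently filled).
        """
        required = {"cell_id", "frame", "channel", "intensity"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trace table is missing columns: {sorted(missing)}")
        cell_ids = list(pd.unique(df["cell_id"]))
        labels = tuple(pd.unique(df["channel"]))
        frames = np.sort(pd.unique(df["frame"]))
        n_frames = len(frames)
        if not np.array_equal(frames, np.arange(n_frames)):
            raise ValueError("non-uniform frame grid: frames must be 0..n-1 with no gaps")
        if frame_interval is None:
            if "time_s" in df.columns and n_frames > 1:
                sub = df[df["frame"] == 1]
                frame_interval = float(sub["time_s"].iloc[0])
            else:
                raise ValueError("frame_interval not given and not recoverable from time_s")
        if len(df) != len(cell_ids) * len(labels) * n_frames:
            raise ValueError("non-uniform grid: some cell/channel/frame entries are missing or duplicated")
        pivot = df.pivot_table(
            index=["cell_id", "channel"], columns="frame", values="intensity", sort=False
        )
        data = np.empty((len(cell_ids), len(labels), n_frames))
        for i, cid in enumerate(cell_ids):
            for j, lab in enumerate(labels):
                data[i, j] = pivot.loc[(cid, lab)].to_numpy()
        return cls(cell_ids=cell_ids, labels=labels, frame_interval=float(frame_interval), data=data)


@dataclass
class AbundanceTraceSet(ChannelTraceSet):
    """Per-cell, per-fluorophore abundance series plus per-frame residual norms.

    ``labels`` are fluorophore names; ``residuals`` has shape
    ``(n_cells, n_frames)`` and holds the least-squares residual norm of the
    unmixing solve at each frame.
    """

    residuals: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.residuals is None:
            self.residuals = np.zeros((self.n_cells, self.n_frames))
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.residuals.shape != (self.n_cells, self.n_frames):
            raise ValueError("residuals must have shape (n_cells, n_frames)")
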