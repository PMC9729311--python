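"""ROI trace extraction, donor/acceptor ratio computation and normalization.

The ratio is oriented donor/acceptor so that probe cleavage (loss of FRET)
increases it: GFP/Alexa 532 reports caspase-9 activity, RFP/Alexa 660
reports caspase-3 activity. Ratios are normalized to the mean of the first
``baseline_window`` frames ("initial values"), so the normalized baseline is
exactly 1 and every downstream index is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .containers import ChannelTraceSet

__all__ = [
    "SensorDefinition",
    "RatioTrace",
    "SENSOR_C9",
    "SENSOR_C3",
    "extract_roi_traces",
    "compute_fret_ratio",
    "normalize_trace",
]


@dataclass(frozen=True)
class SensorDefinition:
    """Maps one probe to its donor and acceptor fluorophore labels."""

    target: str
    donor: str
    acceptor: str

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")


SENSOR_C9 = SensorDefinition(target="caspase-9", donor="GFP", acceptor="Alexa532")
SENSOR_C3 = SensorDefinition(target="caspase-3", donor="RFP", acceptor="Alexa660")


@dataclass
class RatioTrace:
    """Donor/acceptor ratio series of one sensor in one cell.

    ``raw`` is donor/acceptor; ``norm`` is ``raw`` divided by the baseline
    estimate (None until :func:`normalize_trace` is applied). ``valid`` flags
    frames whose acceptor signal was above the floor; ``usable`` is False
    when too many frames were invalid.
    """

    cell_id: int
    sensor: SensorDefinition
    frame_interval: float
    raw: np.ndarray
    valid: np.ndarray
    usable: bool = True
    norm: np.ndarray | None = None
    baseline: float | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.raw)) * self.frame_interval


def extract_roi_traces(
    stack: np.ndarray, roi_mask: np.ndarray, frame_interval: float, channel_labels=None
) -> ChannelTraceSet:
    """Mean intensity over each labeled ROI, per channel per frame.

    ``stack`` has shape ``(T, C, Y, X)``; ``roi_mask`` is a label image
    (0 = background) whose nonzero labels become the cell ids.
    """
    stack = np.asarray(stack, dtype=float)
    roi_mask = np.asarray(roi_mask)
    if stack.ndim != 4:
        raise ValueError("stack must have shape (T, C, Y, X)")
    if roi_mask.shape != stack.shape[2:]:
        raise ValueError(
            f"mask shape {roi_mask.shape} does not match stack frames {stack.shape[2:]}"
        )
    labels = np.unique(roi_mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("mask contains no ROI labels")
    t, c = stack.shape[:2]
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(c))
    data = np.empty((labels.size, c, t))
    for ti in range(t):
        for ci in range(c):
            data[:, ci, ti] = ndimage.mean(stack[ti, ci], labels=roi_mask, index=labels)
    return ChannelTraceSet(
        cell_ids=[int(v) for v in labels],
        labels=tuple(channel_labels),
        frame_interval=frame_interval,
        data=data,
    )


def compute_fret_ratio(
    traces: ChannelTraceSet,
    sensor: SensorDefinition,
    eps_fraction: float = 1e-6,
    max_invalid_fraction: float = 0.2,
) -> list[RatioTrace]:
    """Element-wise donor/acceptor ratio for every cell in a trace set.

    Frames whose acceptor falls at or below ``eps_fraction`` times the
    cell's maximum intensity are flagged invalid (the ratio there is NaN,
    never silently dropped); a cell with more than ``max_invalid_fraction``
    invalid frames is marked unusable.
    """
    for label in (sensor.donor, sensor.acceptor):
        if label not in traces.labels:
            raise ValueError(f"trace set has no series labelled {label!r}")
    di = traces.labels.index(sensor.donor)
    ai = traces.labels.index(sensor.acceptor)
    out = []
    for i, cid in enumerate(traces.cell_ids):
        donor = traces.data[i, di]
        acceptor = traces.data[i, ai]
        floor = eps_fraction * max(np.max(np.abs(traces.data[i])), np.finfo(float).tiny)
        valid = acceptor > floor
        raw = np.full_like(donor, np.nan)
        raw[valid] = donor[valid] / acceptor[valid]
        usable = (~valid).mean() <= max_invalid_fraction
        out.append(
            RatioTrace(
                cell_id=cid,
                sensor=sensor,
                frame_interval=traces.frame_interval,
                raw=raw,
                valid=valid,
                usable=bool(usable),
            )
        )
    return out


def normalize_trace(trace: RatioTrace, baseline_window: int = 10) -> RatioTrace:
    """Divide a raw ratio trace by its initial-value baseline.

    The baseline is the mean of the raw ratio over the first
    ``baseline_window`` valid frames (these should precede stimulation).
    The mean of the normalized series over that window is exactly 1.
    """
    if not 1 <= baseline_window <= len(trace.raw):
        raise ValueError("baseline_window must be in [1, series length]")
    window = trace.raw[:baseline_window]
    window = window[trace.valid[:baseline_window]]
    if window.size == 0:
        raise ValueError(f"cell {trace.cell_id}: no valid baseline frames")
    baseline = float(window.mean())
    if baseline <= 0:
        raise ValueError(f"cell {trace.cell_id}: nonpositive baseline ratio {baseline}")
    return replace(trace, norm=trace.raw / baseline, baseline=baseline)
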