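"""Readers and writers for the pipeline's on-disk formats.

Traces and tables are plain CSV (long format for traces), mixing models are
JSON, image stacks are multi-page TIFF in T×C×Y×X order and ROI masks are
single-page 16-bit label TIFFs. Times are serialized in seconds; frame
numbers are derived, never primary.
"""

from __future__ import annotations



import numpy as np
import pandas as pd
import tifffile

from .containers import ChannelTraceSet
from .indices import CascadeProfile, ResponseProfile
from .quantify import RatioTrace, SensorDefinition
from .vocab import INDEX_COLUMNS, SENSOR_INDEX_NAMES

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_ratio_csv",
    "read_ratio_csv",
    "write_profiles_csv",
    "read_profiles_csv",
    "write_ground_truth_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
]


def write_traces_csv(traces: ChannelTraceSet, path) -> None:
    traces.to_frame().to_csv(path, index=False)


def read_traces_csv(path, frame_interval: float | None = None) -> ChannelTraceSet:
    return ChannelTraceSet.from_frame(pd.read_csv(path), frame_interval=frame_interval)


def write_ratio_csv(ratio_traces, path) -> None:
    """Ratio traces as cell_id, frame, time_s, sensor, raw_ratio, norm_ratio, valid."""
    parts = []
    for rt in ratio_traces:
        n = len(rt.raw)
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": rt.cell_id,
                    "frame": np.arange(n),
                    "time_s": np.arange(n) * rt.frame_interval,
                    "sensor": rt.sensor.target,
                    "raw_ratio": rt.raw,
                    "norm_ratio": rt.norm if rt.norm is not None else np.nan,
                    "valid": rt.valid.astype(int),
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_ratio_csv(path, sensors: dict | None = None) -> list[RatioTrace]:
    """Rebuild :class:`RatioTrace` objects; ``sensors`` maps target name to a
    :class:`SensorDefinition` (a minimal one is synthesized if omitted)."""
    df = pd.read_csv(path)
    out = []
    for (cid, target), sub in df.groupby(["cell_id", "sensor"], sort=False):
        sub = sub.sort_values("frame")
        if sensors and target in sensors:
            sensor = sensors[target]
        else:
            sensor = SensorDefinition(target=target, donor="donor", acceptor="acceptor")
        frames = sub["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(frames))):
            raise ValueError(f"cell {cid}/{target}: non-uniform frame grid")
        dt = float(sub["time_s"].iloc[1]) if len(sub) > 1 else 1.0
        norm = sub["norm_ratio"].to_numpy(dtype=float)
        out.append(
            RatioTrace(
                cell_id=cid,
                sensor=sensor,
                frame_interval=dt,
                raw=sub["raw_ratio"].to_numpy(dtype=float),
                valid=sub["valid"].to_numpy() > 0,
                norm=None if np.isnan(norm).all() else norm,
            )
        )
    return out


def write_profiles_csv(cascades, exclusions, path) -> None:
    """Per-cell profile rows for every cell, accepted or not, with reasons."""
    reason = dict(exclusions)
    rows = []
    for c in cascades:
        row = {"cell_id": c.cell_id, "accepted": int(c.cell_id not in reason),
               "exclusion_reason": reason.get(c.cell_id, "")}
        for tag, prof in (("c9", c.profile9), ("c3", c.profile3)):
            row[f"responded_{tag}"] = int(prof.responded)
            for name in SENSOR_INDEX_NAMES:
                row[f"{name}_{tag}"] = getattr(prof, name if name != "response_scale" else "response_scale")
        row["promotion_interval"] = c.promotion_interval
        row["activation_interval"] = c.activation_interval
        row["completion_interval"] = c.completion_interval
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles_csv(path) -> list[CascadeProfile]:
    df = pd.read_csv(path)
    cascades = []
    for _, row in df.iterrows():
        profs = {}
        for tag in ("c9", "c3"):
            profs[tag] = ResponseProfile(
                sensor=tag,
                responded=bool(row[f"responded_{tag}"]),
                **{name: float(row[f"{name}_{tag}"]) for name in SENSOR_INDEX_NAMES},
            )
        cascades.append(
            CascadeProfile(
                cell_id=int(row["cell_id"]),
                profile9=profs["c9"],
                profile3=profs["c3"],
                promotion_interval=float(row["promotion_interval"]),
                activation_interval=float(row["activation_interval"]),
                completion_interval=float(row["completion_interval"]),
            )
        )
    return cascades


def write_ground_truth_csv(records, path) -> None:
    rows = []
    for rec in records:
        row = {"cell_id": rec.cell_id,
               "responded_c9": int(rec.responded_c9),
               "responded_c3": int(rec.responded_c3)}
        row.update({col: rec.values.get(col, float("nan")) for col in INDEX_COLUMNS})
        k = rec.kinetics
        row.update(
            t_init9=k.t_init9, t_sat9=k.t_sat9, scale9=k.scale9,
            t_init3=k.t_init3, t_sat3=k.t_sat3, scale3=k.scale3,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_stack_tiff(stack: np.ndarray, path) -> None:
    tifffile.imwrite(
        path,
        np.asarray(stack, dtype=np.float32),
        photometric="minisblack",
        metadata={"axes": "TCYX"},
    )


def read_stack_tiff(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim != 4:
        raise ValueError(f"expected a T x C x Y x X stack, got shape {stack.shape}")
    return np.asarray(stack, dtype=float)


def write_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def read_mask_tiff(path) -> np.ndarray:
    mask = tifffile.imread(path)
    if mask.ndim != 2:
        raise ValueError(f"expected a single-page label mask, got shape {mask.shape}")
    return mask
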