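"""Kinetic response indices of a normalized FRET-ratio trace.

The index vocabulary per sensor:

* **response initiation** — first time the trace begins a sustained run
  above the local baseline mean + k·SD threshold (the onset rule);
* **response saturation** — first time it begins a sustained run at or above
  a plateau fraction of the net maximum;
* **response duration** — saturation − initiation;
* **response scale** — maximum of the normalized trace minus 1 (the
  normalized baseline), **maximum ratio** — the maximum itself;
* **ratio-maximize slope** — least-squares rise rate on the
  [initiation, saturation] window (1/s);
* **ratio-maximize integration** — trapezoidal area of the above-baseline
  excess over that window (s·ratio units), read as cumulative enzymatic
  output;
* **time at max** — time of the global maximum, reported separately from
  saturation.

Per cell, the two sensors are paired into a cascade profile with three
signed cross-intervals between their initiation/saturation landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResponseProfile",
    "CascadeProfile",
    "detect_initiation",
    "detect_saturation",
    "compute_strengths",
    "compute_slope",
    "time_at_max",
    "extract_profile",
    "pair_cascade",
    "filter_responders",
]

# Floor on the baseline-window SD so a noise-free trace still yields a
# usable (tiny) supra-threshold rule instead of a degenerate zero threshold.
SD_FLOOR = 1e-4


@dataclass
class ResponseProfile:
    """All single-sensor indices of one cell (times s, amplitudes unitless)."""

    sensor: str
    responded: bool
    initiation: float = float("nan")
    saturation: float = float("nan")
    duration: float = float("nan")
    response_scale: float = float("nan")
    maximum_ratio: float = float("nan")
    slope: float = float("nan")
    integration: float = float("nan")
    time_at_max: float = float("nan")


@dataclass
class CascadeProfile:
    """Paired caspase-9/-3 profiles of one cell plus the cross-intervals."""

    cell_id: int
    profile9: ResponseProfile
    profile3: ResponseProfile
    promotion_interval: float = float("nan")
    activation_interval: float = float("nan")
    completion_interval: float = float("nan")

    @property
    def responded(self) -> bool:
        return self.profile9.responded and self.profile3.responded


def _frame(time_s: float, dt: float) -> int:
    return int(round(time_s / dt))


def detect_initiation(
    trace: np.ndarray,
    frame_interval: float,
    baseline_n: int = 10,
    k_sigma: float = 3.0,
    min_run: int = 3,
    sd_floor: float = SD_FLOOR,
) -> float | None:
    """Onset rule: mean + k·SD of the preceding ``baseline_n`` frames.

    Candidate onsets are scanned left to right; each candidate frame is
    compared with the threshold computed from the ``baseline_n`` frames
    immediately before it, and the first candidate that begins a run of
    ``min_run`` consecutive frames strictly above its threshold is the
    initiation. Returns the time in seconds, or None when no such run exists.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n <= baseline_n + min_run:
        raise ValueError(f"trace too short for onset detection ({n} frames)")
    windows = np.lib.stride_tricks.sliding_window_view(trace, baseline_n)
    # windows[i] covers frames [i, i + baseline_n); candidate frame c uses
    # windows[c - baseline_n]
    mu = windows.mean(axis=1)
    sd = np.maximum(windows.std(axis=1), sd_floor)
    thresholds = mu + k_sigma * sd
    candidates = np.arange(baseline_n, n - min_run + 1)
    above = np.ones(candidates.shape, dtype=bool)
    for offset in range(min_run):
        above &= trace[candidates + offset] > thresholds[candidates - baseline_n]
    hits = np.flatnonzero(above)
    if hits.size == 0:
        return None
    return float(candidates[hits[0]] * frame_interval)


def detect_saturation(
    trace: np.ndarray,
    initiation: float,
    frame_interval: float,
    plateau_fraction: float = 0.95,
    min_run: int = 3,
    baseline: float = 1.0,
) -> float:
    """First sustained attainment of the plateau after initiation.

    The plateau criterion is evaluated on ``min_run``-frame windows:
    saturation is the first frame at or after initiation beginning a window
    whose mean reaches ``baseline + plateau_fraction * (max - baseline)``,
    where the net maximum anchoring the threshold is the largest such window
    mean. Judging sustained windows rather than single frames is what the
    run-length requirement is for: one noisy frame can neither raise the
    plateau criterion nor break an attained plateau, and on a noiseless
    trace the window means coincide with the plain maximum and threshold
    crossing. The result never exceeds the time of the (raw) global maximum,
    which is also the fallback when no window qualifies.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    i_init = _frame(initiation, frame_interval)
    t_max_frame = int(np.nanargmax(trace))
    width = min(max(min_run, 1), n)
    window_means = np.convolve(trace, np.ones(width) / width, mode="valid")
    threshold = baseline + plateau_fraction * (np.nanmax(window_means) - baseline)
    hits = np.flatnonzero(window_means[i_init:] >= threshold)
    if hits.size == 0:
        return float(t_max_frame * frame_interval)
    return float(min(i_init + int(hits[0]), t_max_frame) * frame_interval)


def compute_strengths(trace: np.ndarray, initiation: float, saturation: float, frame_interval: float):
    """(response_scale, maximum_ratio, integration) of a normalized trace.

    Integration is the trapezoidal area of ``max(trace - 1, 0)`` between the
    initiation and saturation frames, in s·ratio units.
    """
    trace = np.asarray(trace, dtype=float)
    maximum_ratio = float(np.nanmax(trace))
    response_scale = maximum_ratio - 1.0
    i0 = _frame(initiation, frame_interval)
    i1 = _frame(saturation, frame_interval)
    seg = np.clip(trace[i0 : i1 + 1] - 1.0, 0.0, None)
    integration = float(np.trapezoid(seg, dx=frame_interval)) if i1 > i0 else 0.0
    return response_scale, maximum_ratio, integration


def compute_slope(trace: np.ndarray, initiation: float, saturation: float, frame_interval: float) -> float:
    """Least-squares rise rate (1/s) on the [initiation, saturation] window.

    A degenerate single-frame window falls back to a two-point difference.
    """
    trace = np.asarray(trace, dtype=float)
    i0 = _frame(initiation, frame_interval)
    i1 = _frame(saturation, frame_interval)
    if i1 <= i0:
        j = min(i0 + 1, len(trace) - 1)
        return float((trace[j] - trace[j - 1]) / frame_interval)
    t = np.arange(i0, i1 + 1) * frame_interval
    return float(np.polyfit(t, trace[i0 : i1 + 1], 1)[0])


def time_at_max(trace: np.ndarray, frame_interval: float) -> float:
    """Time of the global maximum (first occurrence).

    Frames within one part in 10^12 of the maximum count as ties, so an
    exactly flat plateau yields its first frame regardless of last-ulp
    perturbations (e.g. a global intensity rescale).
    """
    trace = np.asarray(trace, dtype=float)
    top = np.nanmax(trace)
    return float(np.argmax(trace >= top - 1e-12 * max(abs(top), 1.0)) * frame_interval)


def extract_profile(
    trace: np.ndarray,
    frame_interval: float,
    sensor: str,
    baseline_n: int = 10,
    k_sigma: float = 3.0,
    min_run: int = 3,
    plateau_fraction: float = 0.95,
    sd_floor: float = SD_FLOOR,
) -> ResponseProfile:
    """Run the full index extraction on one normalized trace."""
    init = detect_initiation(
        trace, frame_interval, baseline_n=baseline_n, k_sigma=k_sigma,
        min_run=min_run, sd_floor=sd_floor,
    )
    if init is None:
        return ResponseProfile(sensor=sensor, responded=False)
    sat = detect_saturation(
        trace, init, frame_interval, plateau_fraction=plateau_fraction, min_run=min_run
    )
    scale, max_ratio, integration = compute_strengths(trace, init, sat, frame_interval)
    slope = compute_slope(trace, init, sat, frame_interval)
    return ResponseProfile(
        sensor=sensor,
        responded=True,
        initiation=init,
        saturation=sat,
        duration=sat - init,
        response_scale=scale,
        maximum_ratio=max_ratio,
        slope=slope,
        integration=integration,
        time_at_max=time_at_max(trace, frame_interval),
    )


def pair_cascade(profile9: ResponseProfile, profile3: ResponseProfile, cell_id: int) -> CascadeProfile:
    """Pair the two sensors of one cell and compute the signed cross-intervals.

    Convention: promotion = initiation(c3) − initiation(c9); completion =
    saturation(c3) − saturation(c9); activation = initiation(c3) −
    saturation(c9). Intervals are defined only when both probes responded.
    """
    cascade = CascadeProfile(cell_id=cell_id, profile9=profile9, profile3=profile3)
    if profile9.responded and profile3.responded:
        cascade.promotion_interval = profile3.initiation - profile9.initiation
        cascade.completion_interval = profile3.saturation - profile9.saturation
        cascade.activation_interval = profile3.initiation - profile9.saturation
    return cascade


def filter_responders(cascades, min_scale: float = 0.05):
    """Keep cells in which both probes responded cleanly.

    A cell is accepted when both sensors responded, both durations are
    positive and both response scales reach ``min_scale``. Returns
    ``(accepted, exclusion_log)`` where the log is a list of
    ``(cell_id, reason_code)`` so that every exclusion is auditable.
    """
    accepted, log = [], []
    for cascade in cascades:
        if not cascade.profile9.responded:
            log.append((cascade.cell_id, "no_c9_response"))
        elif not cascade.profile3.responded:
            log.append((cascade.cell_id, "no_c3_response"))
        elif cascade.profile9.duration <= 0 or cascade.profile3.duration <= 0:
            log.append((cascade.cell_id, "nonpositive_duration"))
        elif cascade.profile9.response_scale < min_scale:
            log.append((cascade.cell_id, "scale9_below_min"))
        elif cascade.profile3.response_scale < min_scale:
            log.append((cascade.cell_id, "scale3_below_min"))
        else:
            accepted.append(cascade)
    return accepted, log
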