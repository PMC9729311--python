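"""End-to-end self-checks of the analysis pipeline on generated data.

Each function runs one complete study on synthetic ground truth — the same
code paths a real analysis uses — and reports summary numbers: unmixing
round-trip accuracy, onset/saturation/scale recovery rates, recovery of the
planted cascade correlation structure, power of the between-caspase paired
comparison, internal-consistency deviations, and the bulk-cleavage
half-time check. The test suite asserts on these numbers and the
acceptance script reports them.
"""

from __future__ import annotations

import numpy as np

from .indices import extract_profile, filter_responders, pair_cascade
from .mixing import build_mixing_model, default_mixing_model, unmix, unmix_traces
from .population import build_population_table, compare_caspases, correlation_heatmap
from .quantify import SENSOR_C3, SENSOR_C9, compute_fret_ratio, extract_roi_traces, normalize_trace
from .simulate import (
    PopulationConfig,
    disk_layout,
    render_channel_traces,
    render_image_stack,
    render_ratio_traces,
    simulate_bulk_cleavage,
    simulate_population,
)
from .vocab import INTERVAL_COLUMNS

__all__ = [
    "unmixing_roundtrip",
    "index_recovery",
    "headline_structure",
    "comparison_power",
    "consistency_suite",
    "bulk_half_time",
]


def _sub_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


def unmixing_roundtrip(n_models: int = 100, seed: int = 0) -> dict:
    """Forward-mix random abundances through random nonsingular models and
    invert; also measure abundance error under 1% channel noise with the
    default four-band model."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_models):
        w = rng.uniform(0.05, 1.0, (4, 4)) + 3.0 * np.eye(4)
        model = build_mixing_model(w)
        a_true = rng.uniform(0.1, 10.0, (10, 4))
        a_hat, _ = unmix(a_true @ model.weights.T, model)
        worst = max(worst, float(np.max(np.abs(a_hat - a_true) / a_true)))

    model = default_mixing_model()
    a_true = rng.uniform(0.2, 1.0, (2000, 4))
    obs = a_true @ model.weights.T
    obs = obs * (1.0 + 0.01 * rng.standard_normal(obs.shape))
    a_hat, _ = unmix(obs, model)
    median_rel = float(np.median(np.abs(a_hat - a_true) / a_true))
    return {
        "noise_free_max_rel_error": worst,
        "noisy_median_rel_error_pct": 100.0 * median_rel,
        "n_models": n_models,
    }


def _normalized(trace: np.ndarray, window: int = 10) -> np.ndarray:
    return trace / trace[:window].mean()


def index_recovery(n_cells: int = 200, noise_sd: float = 0.01, seed: int = 0) -> dict:
    """Detection accuracy against ground truth on a noisy population.

    Reports the fraction of sensor traces whose detected initiation and
    saturation fall within two frames of the noiseless ground truth, and the
    median relative error of the response scale, pooled over both probes.
    """
    config = PopulationConfig(n_cells=n_cells, rng_seed=_sub_seed(seed, 1))
    kinetics, records = simulate_population(config)
    traces = render_ratio_traces(
        kinetics, frame_interval=config.frame_interval, n_frames=config.n_frames,
        noise_sd=noise_sd, seed=_sub_seed(seed, 2),
    )
    h = config.frame_interval
    init_ok, sat_ok, scale_err = [], [], []
    for tag in ("c9", "c3"):
        for i, rec in enumerate(records):
            profile = extract_profile(_normalized(traces[tag][i]), h, tag)
            truth = rec.values
            if profile.responded:
                init_ok.append(abs(profile.initiation - truth[f"initiation_{tag}"]) <= 2 * h)
                sat_ok.append(abs(profile.saturation - truth[f"saturation_{tag}"]) <= 2 * h)
                scale_err.append(
                    abs(profile.response_scale - truth[f"response_scale_{tag}"])
                    / truth[f"response_scale_{tag}"]
                )
            else:
                init_ok.append(False)
                sat_ok.append(False)
    return {
        "initiation_within_2_frames_pct": 100.0 * float(np.mean(init_ok)),
        "saturation_within_2_frames_pct": 100.0 * float(np.mean(sat_ok)),
        "scale_median_rel_error_pct": 100.0 * float(np.median(scale_err)),
        "n_cells": n_cells,
    }


def _cascades_from_ratio_traces(traces, h):
    cascades = []
    for i in range(traces["c9"].shape[0]):
        p9 = extract_profile(_normalized(traces["c9"][i]), h, "c9")
        p3 = extract_profile(_normalized(traces["c3"][i]), h, "c3")
        cascades.append(pair_cascade(p9, p3, i + 1))
    return cascades


def cross_caspase_pairs(corr):
    """(|R|, c9 index, partner) for every cross-caspase pair, sorted by
    magnitude: a pure caspase-9 index against a pure caspase-3 index or a
    cross-interval. maximum_ratio is an affine duplicate of response_scale
    (identical correlations by construction) and is collapsed out."""
    c9 = [c for c in corr.labels if c.endswith("_c9") and c != "maximum_ratio_c9"]
    partners = [
        c for c in corr.labels if c.endswith("_c3") and c != "maximum_ratio_c3"
    ] + [c for c in INTERVAL_COLUMNS if c in corr.labels]
    pairs = [(abs(corr.entry(a, b)), a, b) for a in c9 for b in partners]
    return sorted(pairs, reverse=True)


def headline_structure(n_cells: int = 200, noise_sd: float = 0.01, seed: int = 0) -> dict:
    """Recovery of the planted cascade structure through the full pipeline.

    The generator plants r = -0.8 between the caspase-9 response scale (and,
    through the duration coupling, its integration) and the completion
    interval; the heatmap should recover both and rank them as the
    strongest cross-caspase couplings.
    """
    config = PopulationConfig(n_cells=n_cells, rng_seed=_sub_seed(seed, 3))
    kinetics, _ = simulate_population(config)
    traces = render_ratio_traces(
        kinetics, frame_interval=config.frame_interval, n_frames=config.n_frames,
        noise_sd=noise_sd, seed=_sub_seed(seed, 4),
    )
    accepted, _ = filter_responders(_cascades_from_ratio_traces(traces, config.frame_interval))
    corr = correlation_heatmap(build_population_table(accepted))
    ranked = cross_caspase_pairs(corr)
    top_two = {(a, b) for _, a, b in ranked[:2]}
    expected = {
        ("response_scale_c9", "completion_interval"),
        ("integration_c9", "completion_interval"),
    }
    return {
        "r_scale9_completion": corr.entry("response_scale_c9", "completion_interval"),
        "r_integration9_completion": corr.entry("integration_c9", "completion_interval"),
        "planted_pairs_are_top_two": top_two == expected,
        "third_largest_cross_magnitude": ranked[2][0],
        "n_accepted": len(accepted),
    }


def comparison_power(n_replicates: int = 100, n_cells: int = 44, seed: int = 0) -> dict:
    """Fraction of seeded replicates in which the paired t-test finds the
    caspase-3 time-at-max and response scale significantly above caspase-9's."""
    wins = {"time_at_max": 0, "response_scale": 0}
    for rep in range(n_replicates):
        config = PopulationConfig(n_cells=n_cells, rng_seed=_sub_seed(seed, 10 + 2 * rep))
        kinetics, _ = simulate_population(config)
        traces = render_ratio_traces(
            kinetics, frame_interval=config.frame_interval, n_frames=config.n_frames,
            noise_sd=0.01, seed=_sub_seed(seed, 11 + 2 * rep),
        )
        accepted, _ = filter_responders(
            _cascades_from_ratio_traces(traces, config.frame_interval)
        )
        table = build_population_table(accepted)
        for index in wins:
            report = compare_caspases(table, index=index)
            if report["p"] < 0.05 and report["mean_c3"] > report["mean_c9"]:
                wins[index] += 1
    return {
        "time_at_max_power_pct": 100.0 * wins["time_at_max"] / n_replicates,
        "response_scale_power_pct": 100.0 * wins["response_scale"] / n_replicates,
        "n_replicates": n_replicates,
        "n_cells": n_cells,
    }


def consistency_suite(seed: int = 0) -> dict:
    """Internal-consistency deviations that should all sit at numerical zero:
    image-stack vs trace path, global intensity rescaling, correlation-matrix
    layout, and the normalized baseline."""
    model = default_mixing_model()
    config = PopulationConfig(n_cells=3, rng_seed=_sub_seed(seed, 20), noise_sd=0.0)
    kinetics, _ = simulate_population(config)

    # image-stack path vs trace path on noiseless data
    layout = disk_layout(3, (64, 64), radius=8)
    stack, mask = render_image_stack(
        kinetics, layout, model, noise_sd=0.0, seed=_sub_seed(seed, 21),
        frame_shape=(64, 64), n_frames=config.n_frames,
    )
    roi = extract_roi_traces(stack, mask, config.frame_interval, channel_labels=model.channels)
    direct = render_channel_traces(
        kinetics, model, noise_sd=0.0, seed=_sub_seed(seed, 21), n_frames=config.n_frames
    )
    stack_vs_trace = float(np.max(np.abs(roi.data - direct.data) / np.abs(direct.data)))

    # global rescaling of every channel
    def indices_of(trace_set):
        out = []
        abundances = unmix_traces(trace_set, model)
        for sensor, tag in ((SENSOR_C9, "c9"), (SENSOR_C3, "c3")):
            for rt in compute_fret_ratio(abundances, sensor):
                out.append(extract_profile(normalize_trace(rt).norm, rt.frame_interval, tag))
        return out

    import dataclasses

    scaled = dataclasses.replace(direct, data=direct.data * 37.5)
    rescale_dev = 0.0
    time_dev = 0.0
    for a, b in zip(indices_of(direct), indices_of(scaled)):
        time_dev = max(
            time_dev,
            abs(a.initiation - b.initiation),
            abs(a.saturation - b.saturation),
            abs(a.time_at_max - b.time_at_max),
        )
        for name in ("response_scale", "maximum_ratio", "slope", "integration"):
            va, vb = getattr(a, name), getattr(b, name)
            rescale_dev = max(rescale_dev, abs(va - vb) / max(abs(va), 1e-300))

    # correlation layout consistency and baseline normalization
    config2 = PopulationConfig(n_cells=40, rng_seed=_sub_seed(seed, 22))
    kinetics2, _ = simulate_population(config2)
    traces2 = render_ratio_traces(
        kinetics2, n_frames=config2.n_frames, noise_sd=0.01, seed=_sub_seed(seed, 23)
    )
    baseline_dev = max(
        abs(_normalized(trace)[:10].mean() - 1.0)
        for tag in ("c9", "c3")
        for trace in traces2[tag]
    )
    accepted, _ = filter_responders(_cascades_from_ratio_traces(traces2, 20.0))
    corr = correlation_heatmap(build_population_table(accepted))
    iu = np.triu_indices(len(corr.labels), k=1)
    layout_dev = float(np.max(np.abs(corr.matrix[iu] - corr.r.T[iu] ** 2)))

    return {
        "stack_vs_trace_max_rel_dev": stack_vs_trace,
        "rescale_max_rel_dev": rescale_dev,
        "rescale_max_time_dev_s": time_dev,
        "corr_layout_max_dev": layout_dev,
        "baseline_mean_max_dev": float(baseline_dev),
    }


def bulk_half_time(k_rates=(5e-4, 2e-3, 1e-2), dt: float = 1.0) -> dict:
    """Half-change time of the first-order cleavage curve vs ln(2)/k."""
    worst = 0.0
    for k in k_rates:
        t = np.arange(0.0, 10.0 * np.log(2) / k, dt)
        ratio = simulate_bulk_cleavage(k, 1.0, 2.0, t)
        crossing = t[np.argmax(ratio >= 1.5)]
        worst = max(worst, abs(crossing - np.log(2) / k))
    return {"half_time_max_error_steps": worst / dt, "dt_s": dt}
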