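import numpy as np
import pytest

import caspaseflow as cf

H = 20.0  # frame interval, seconds


def step_trace(n=60, step_frame=20, level=1.5, baseline_jitter=0.005):
    """10+ baseline frames with known small SD, then an instant sustained step."""
    rng = np.random.default_rng(0)
    trace = 1.0 + baseline_jitter * rng.standard_normal(n)
    trace[step_frame:] = level
    return trace


class TestDetectInitiation:
    def test_step_is_detected_at_the_step_frame(self):
        trace = step_trace(step_frame=20)
        assert cf.detect_initiation(trace, H) == pytest.approx(20 * H)

    def test_constant_trace_has_no_onset(self):
        assert cf.detect_initiation(np.ones(50), H) is None

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError, match="too short"):
            cf.detect_initiation(np.ones(12), H)

    def test_threshold_uses_local_window_before_candidate(self):
        """A slow drift inside the window raises the threshold and is not an
        onset; the sustained step beyond mean + 3 SD is."""
        trace = np.ones(60)
        trace[10:40] += np.linspace(0, 0.002, 30)  # sub-threshold drift
        trace[40:] = 1.5
        assert cf.detect_initiation(trace, H) == pytest.approx(40 * H)

    def test_noise_recovery_on_synthetic_population(self, small_population):
        """mean + 3 SD rule finds onsets within two frames of ground truth."""
        from conftest import normalized_traces

        cfg, kinetics, records = small_population
        traces = normalized_traces(kinetics, cfg, noise_sd=0.01, seed=13)
        hits = 0
        total = 0
        for tag in ("c9", "c3"):
            for i, rec in enumerate(records):
                init = cf.detect_initiation(traces[tag][i], H)
                total += 1
                if init is not None and abs(init - rec.values[f"initiation_{tag}"]) <= 2 * H:
                    hits += 1
        assert hits / total >= 0.9


class TestDetectSaturation:
    def test_step_saturates_at_the_step_frame(self):
        trace = step_trace(step_frame=20)
        init = cf.detect_initiation(trace, H)
        assert cf.detect_saturation(trace, init, H) == pytest.approx(20 * H)

    def test_linear_ramp_to_last_frame(self):
        """Closed-form position: first window of 3 whose mean reaches 95% of
        the net maximum of the best window."""
        n = 51
        trace = 1.0 + np.arange(n) / (n - 1)  # ramp 1 -> 2 ending at the last frame
        # independent brute-force oracle over all windows
        means = np.array([trace[i : i + 3].mean() for i in range(n - 2)])
        thr = 1.0 + 0.95 * (means.max() - 1.0)
        expected = np.flatnonzero(means >= thr)[0]
        sat = cf.detect_saturation(trace, 0.0, H)
        assert sat == pytest.approx(expected * H)

    def test_never_after_global_maximum(self):
        trace = np.ones(40)
        trace[20] = 2.0  # single-frame spike, then back to baseline
        sat = cf.detect_saturation(trace, 0.0, H)
        assert sat <= 20 * H

    def test_noise_recovery_on_synthetic_population(self, small_population):
        from conftest import normalized_traces

        cfg, kinetics, records = small_population
        traces = normalized_traces(kinetics, cfg, noise_sd=0.01, seed=14)
        hits = 0
        total = 0
        for tag in ("c9", "c3"):
            for i, rec in enumerate(records):
                init = cf.detect_initiation(traces[tag][i], H)
                if init is None:
                    continue
                sat = cf.detect_saturation(traces[tag][i], init, H)
                total += 1
                if abs(sat - rec.values[f"saturation_{tag}"]) <= 2 * H:
                    hits += 1
        assert hits / total >= 0.85


class TestStrengths:
    def test_flat_trace_has_zero_scale_and_integration(self):
        scale, max_ratio, integration = cf.compute_strengths(np.ones(30), 100.0, 300.0, H)
        assert scale == 0.0
        assert max_ratio == 1.0
        assert integration == 0.0

    def test_scale_is_max_minus_baseline(self):
        trace = np.ones(30)
        trace[10:] = 1.8
        scale, max_ratio, _ = cf.compute_strengths(trace, 200.0, 300.0, H)
        assert scale == pytest.approx(0.8)
        assert max_ratio == pytest.approx(1.8)

    def test_triangle_rise_integration_matches_analytic_area(self):
        # rise 1.0 -> 1.5 over 100 s (5 frames), then plateau
        trace = np.ones(30)
        trace[10:15] = 1.0 + 0.5 * np.arange(5) / 5.0
        trace[15:] = 1.5
        _, _, integration = cf.compute_strengths(trace, 10 * H, 15 * H, H)
        # trapezoid on the sampled grid of the analytic triangle area 25
        expected = np.trapezoid(np.clip(trace[10:16] - 1, 0, None), dx=H)
        assert integration == pytest.approx(expected)
        assert integration == pytest.approx(25.0, rel=0.2)


class TestSlope:
    def test_exact_ramp_rate(self):
        rate = 1.7e-3
        trace = 1.0 + rate * np.arange(50) * H
        assert cf.compute_slope(trace, 10 * H, 40 * H, H) == pytest.approx(rate, abs=1e-12)

    def test_time_stretch_halves_slope_and_doubles_integration(self):
        base = np.ones(60)
        base[10:20] = 1.0 + 0.5 * np.arange(10) / 10
        base[20:] = 1.5
        stretched = np.ones(120)
        stretched[10:30] = 1.0 + 0.5 * np.arange(20) / 20
        stretched[30:] = 1.5
        s1 = cf.compute_slope(base, 10 * H, 20 * H, H)
        s2 = cf.compute_slope(stretched, 10 * H, 30 * H, H)
        assert s2 == pytest.approx(s1 / 2, rel=1e-6)
        i1 = cf.compute_strengths(base, 10 * H, 20 * H, H)[2]
        i2 = cf.compute_strengths(stretched, 10 * H, 30 * H, H)[2]
        assert i2 == pytest.approx(2 * i1, rel=0.06)

    def test_degenerate_window_uses_two_point_difference(self):
        trace = np.array([1.0, 1.0, 1.0, 1.4, 1.4])
        slope = cf.compute_slope(trace, 2 * H, 2 * H, H)
        assert slope == pytest.approx(0.4 / H)


class TestEquivariance:
    def _trace(self):
        trace = np.ones(80)
        trace[30:40] = 1.0 + 0.6 * np.arange(10) / 10
        trace[40:] = 1.6
        return trace

    def test_time_shift_moves_all_times_and_keeps_strengths(self):
        shift = 7
        base = self._trace()
        shifted = np.concatenate([np.ones(shift), base])[: len(base) + shift]
        p0 = cf.extract_profile(base, H, "c9")
        p1 = cf.extract_profile(shifted, H, "c9")
        for name in ("initiation", "saturation", "time_at_max"):
            assert getattr(p1, name) - getattr(p0, name) == pytest.approx(shift * H)
        assert p1.duration == pytest.approx(p0.duration)
        for name in ("response_scale", "maximum_ratio", "slope", "integration"):
            assert getattr(p1, name) == pytest.approx(getattr(p0, name), rel=1e-9)

    @pytest.mark.parametrize("c", [1.0, 1.5, 3.0])
    def test_amplitude_scaling_scales_strengths_not_times(self, c):
        base = self._trace()
        scaled = 1.0 + c * (base - 1.0)
        p0 = cf.extract_profile(base, H, "c9")
        p1 = cf.extract_profile(scaled, H, "c9")
        assert p1.initiation == p0.initiation
        assert p1.saturation == p0.saturation
        assert p1.response_scale == pytest.approx(c * p0.response_scale, rel=1e-9)
        assert p1.integration == pytest.approx(c * p0.integration, rel=1e-9)
        assert p1.slope == pytest.approx(c * p0.slope, rel=1e-9)

    def test_duration_identity_holds_exactly(self, small_population):
        from conftest import normalized_traces

        cfg, kinetics, _ = small_population
        traces = normalized_traces(kinetics, cfg, noise_sd=0.01, seed=21)
        for tag in ("c9", "c3"):
            for trace in traces[tag]:
                p = cf.extract_profile(trace, H, tag)
                if p.responded:
                    assert p.duration == p.saturation - p.initiation


class TestCascade:
    def _profile(self, init, sat, scale=0.5, sensor="c9"):
        return cf.ResponseProfile(
            sensor=sensor, responded=True, initiation=init, saturation=sat,
            duration=sat - init, response_scale=scale, maximum_ratio=1 + scale,
            slope=1e-3, integration=10.0, time_at_max=sat,
        )

    def test_identical_profiles_give_zero_intervals(self):
        p = self._profile(400.0, 700.0)
        cascade = cf.pair_cascade(p, self._profile(400.0, 700.0, sensor="c3"), 1)
        assert cascade.promotion_interval == 0.0
        assert cascade.completion_interval == 0.0
        assert cascade.activation_interval == pytest.approx(-300.0)

    def test_shifted_c3_shifts_intervals_by_the_shift(self):
        p9 = self._profile(400.0, 700.0)
        p3 = self._profile(600.0, 900.0, sensor="c3")
        cascade = cf.pair_cascade(p9, p3, 1)
        assert cascade.promotion_interval == pytest.approx(200.0)
        assert cascade.completion_interval == pytest.approx(200.0)
        assert cascade.activation_interval == pytest.approx(200.0 - p9.duration)

    def test_nonresponding_profile_leaves_intervals_undefined(self):
        p9 = self._profile(400.0, 700.0)
        p3 = cf.ResponseProfile(sensor="c3", responded=False)
        cascade = cf.pair_cascade(p9, p3, 1)
        assert not cascade.responded
        assert np.isnan(cascade.completion_interval)


class TestFilterResponders:
    def _cascades(self, n_flat):
        cfg = cf.PopulationConfig(n_cells=50, nonresponder_fraction=0.0, rng_seed=3)
        kinetics, _ = cf.simulate_population(cfg)
        from conftest import normalized_traces

        traces = normalized_traces(kinetics, cfg, noise_sd=0.0)
        cascades = []
        for i in range(50):
            p9 = cf.extract_profile(traces["c9"][i], H, "c9")
            if i < n_flat:
                p3 = cf.extract_profile(np.ones(cfg.n_frames), H, "c3")
            else:
                p3 = cf.extract_profile(traces["c3"][i], H, "c3")
            cascades.append(cf.pair_cascade(p9, p3, i + 1))
        return cascades

    def test_flat_caspase3_cells_excluded_with_reason(self):
        accepted, log = cf.filter_responders(self._cascades(n_flat=10))
        assert len(accepted) == 40
        assert len(log) == 10
        assert all(reason == "no_c3_response" for _, reason in log)

    def test_all_responders_pass_unchanged(self):
        cascades = self._cascades(n_flat=0)
        accepted, log = cf.filter_responders(cascades)
        assert accepted == cascades
        assert log == []
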