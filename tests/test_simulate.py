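import dataclasses

import numpy as np
import pytest

import caspaseflow as cf
from caspaseflow.simulate import ParameterSpec, _default_marginals


def _kin(**kw):
    base = dict(t_init9=400.0, t_sat9=700.0, scale9=0.5,
                t_init3=800.0, t_sat3=1200.0, scale3=1.0)
    base.update(kw)
    return cf.CellKinetics(**base)


class TestRatioTrajectory:
    t = np.arange(0, 2600, 20.0)

    def test_baseline_is_exactly_one_before_onset(self):
        traj = cf.ratio_trajectory(_kin(), self.t, "c9")
        assert (traj[self.t < 400] == 1.0).all()

    def test_plateau_is_exactly_one_plus_scale(self):
        traj = cf.ratio_trajectory(_kin(), self.t, "c9")
        assert traj[self.t >= 700].max() == traj[self.t >= 700].min() == pytest.approx(1.5)

    @pytest.mark.parametrize("shape", ["logistic", "linear"])
    def test_midpoint_of_rise_is_half_scale(self, shape):
        k = _kin()
        mid = cf.ratio_trajectory(k, np.array([550.0]), "c9", shape=shape)
        assert mid[0] == pytest.approx(1.25, abs=1e-12)

    def test_trajectory_is_monotone_on_the_rise(self):
        traj = cf.ratio_trajectory(_kin(), self.t, "c3")
        rise = traj[(self.t >= 800) & (self.t <= 1200)]
        assert (np.diff(rise) >= 0).all()

    def test_dip_subtracts_half_cosine_bump_and_recovers(self):
        k = _kin(dip_depth=0.1, dip_duration=200.0, dip_delay=100.0)
        traj = cf.ratio_trajectory(k, self.t, "c9")
        assert traj[self.t < 100].min() == 1.0
        bottom = traj[(self.t >= 100) & (self.t <= 300)].min()
        assert bottom == pytest.approx(0.9, abs=1e-9)
        recovered = traj[(self.t > 300) & (self.t < 400)]
        np.testing.assert_allclose(recovered, 1.0, atol=1e-12)

    def test_nonresponder_is_flat(self):
        k = _kin()
        k = dataclasses.replace(k, responds3=False)
        traj = cf.ratio_trajectory(k, self.t, "c3")
        assert (traj == 1.0).all()

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError, match="t_init9"):
            _kin(t_init9=900.0, t_sat9=700.0)


class TestSimulatePopulation:
    def test_same_seed_is_bitwise_identical(self):
        cfg = cf.PopulationConfig(n_cells=30, rng_seed=5)
        kin_a, _ = cf.simulate_population(cfg)
        kin_b, _ = cf.simulate_population(cf.PopulationConfig(n_cells=30, rng_seed=5))
        for a, b in zip(kin_a, kin_b):
            assert a == b

    def test_zero_sd_marginals_give_identical_cells(self):
        marg = {k: ParameterSpec(v.mean, 0.0, v.lower, v.upper)
                for k, v in _default_marginals().items()}
        cfg = cf.PopulationConfig(n_cells=5, marginals=marg, planted_correlations=(), rng_seed=1)
        kin, _ = cf.simulate_population(cfg)
        assert all(k == kin[0] for k in kin)

    def test_planted_correlation_is_realized(self):
        """Empirical Pearson r of the drawn parameters hits the target."""
        cfg = cf.PopulationConfig(n_cells=2000, rng_seed=11)
        kin, _ = cf.simulate_population(cfg)
        s9 = np.array([k.scale9 for k in kin])
        comp = np.array([k.t_sat3 - k.t_sat9 for k in kin])
        assert np.corrcoef(s9, comp)[0, 1] == pytest.approx(-0.8, abs=0.05)

    def test_non_psd_request_is_rejected(self):
        cfg = cf.PopulationConfig(
            n_cells=10,
            planted_correlations=(
                ("scale9", "completion", 0.9),
                ("scale9", "promotion", 0.9),
                ("promotion", "completion", -0.9),
            ),
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            cf.simulate_population(cfg)

    def test_out_of_range_r_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            cf.PopulationConfig(planted_correlations=(("scale9", "completion", -1.2),))

    def test_nonresponder_fraction_plants_flat_cells(self):
        cfg = cf.PopulationConfig(n_cells=200, nonresponder_fraction=0.2, rng_seed=9)
        kin, rec = cf.simulate_population(cfg)
        n_flat = sum(not k.responds3 for k in kin)
        assert 0 < n_flat < 200
        assert n_flat == sum(not r.responded_c3 for r in rec)

    def test_default_population_orders_caspase3_above_caspase9(self):
        """Mean time-at-max and response scale are larger for caspase-3."""
        cfg = cf.PopulationConfig(n_cells=200, rng_seed=2)
        _, rec = cf.simulate_population(cfg)
        tmax9 = np.mean([r.values["time_at_max_c9"] for r in rec])
        tmax3 = np.mean([r.values["time_at_max_c3"] for r in rec])
        s9 = np.mean([r.values["response_scale_c9"] for r in rec])
        s3 = np.mean([r.values["response_scale_c3"] for r in rec])
        assert tmax3 > tmax9
        assert s3 > s9


class TestRenderChannelTraces:
    def test_identity_mixing_noise_free_round_trips_to_trajectory(self, small_population):
        cfg, kinetics, _ = small_population
        model = cf.identity_mixing_model()
        traces = cf.render_channel_traces(
            kinetics, model, noise_sd=0.0, seed=1,
            frame_interval=cfg.frame_interval, n_frames=cfg.n_frames,
        )
        abundances = cf.unmix_traces(traces, model)
        ratios = [cf.normalize_trace(rt) for rt in cf.compute_fret_ratio(abundances, cf.SENSOR_C9)]
        t = cfg.times
        for kin, rt in zip(kinetics, ratios):
            np.testing.assert_allclose(rt.norm, cf.ratio_trajectory(kin, t, "c9"), atol=1e-9)

    def test_cross_talk_plus_unmixing_round_trips_to_trajectory(self, small_population, default_mix):
        cfg, kinetics, _ = small_population
        traces = cf.render_channel_traces(
            kinetics, default_mix, noise_sd=0.0, seed=1,
            frame_interval=cfg.frame_interval, n_frames=cfg.n_frames,
        )
        abundances = cf.unmix_traces(traces, default_mix)
        t = cfg.times
        for sensor, tag in ((cf.SENSOR_C9, "c9"), (cf.SENSOR_C3, "c3")):
            ratios = [cf.normalize_trace(rt) for rt in cf.compute_fret_ratio(abundances, sensor)]
            for kin, rt in zip(kinetics, ratios):
                np.testing.assert_allclose(rt.norm, cf.ratio_trajectory(kin, t, tag), atol=1e-9)

    def test_static_probe_gives_constant_channels(self, default_mix):
        kin = _kin(t_init9=1.0e9, t_sat9=2.0e9, t_init3=1.0e9, t_sat3=2.0e9)
        traces = cf.render_channel_traces([kin], default_mix, noise_sd=0.0, seed=0, n_frames=50)
        assert np.ptp(traces.data, axis=2).max() == pytest.approx(0.0, abs=1e-12)

    def test_full_cleavage_endpoint(self):
        """f = 1: donor emission maximal, sensitized acceptor minimal, ratio at
        the probe's dynamic-range ceiling."""
        probe = cf.ProbeParams(fret_efficiency=0.9, direct_excitation=0.08)
        r_max = probe.ratio_gain(np.array([1.0]))[0]
        assert probe.invert_fraction(np.array([r_max]))[0] == pytest.approx(1.0, abs=1e-9)
        assert probe.invert_fraction(np.array([1.0]))[0] == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError, match="dynamic range"):
            probe.invert_fraction(np.array([r_max * 1.1]))

    def test_determinism(self, small_population, default_mix):
        cfg, kinetics, _ = small_population
        a = cf.render_channel_traces(kinetics, default_mix, noise_sd=0.02, seed=3, n_frames=cfg.n_frames)
        b = cf.render_channel_traces(kinetics, default_mix, noise_sd=0.02, seed=3, n_frames=cfg.n_frames)
        np.testing.assert_array_equal(a.data, b.data)


class TestRenderImageStack:
    def test_roi_extraction_reproduces_channel_traces(self, default_mix):
        kinetics = [_kin(), _kin(t_init9=500.0, t_sat9=800.0)]
        layout = cf.disk_layout(2, (64, 64), radius=8)
        stack, mask = cf.render_image_stack(
            kinetics, layout, default_mix, noise_sd=0.0, seed=4,
            frame_shape=(64, 64), n_frames=80,
        )
        extracted = cf.extract_roi_traces(stack, mask, 20.0)
        direct = cf.render_channel_traces(kinetics, default_mix, noise_sd=0.0, seed=4, n_frames=80)
        np.testing.assert_allclose(extracted.data, direct.data, rtol=1e-12)

    def test_single_cell_single_frame_roi_mean(self, default_mix):
        kin = _kin()
        stack, mask = cf.render_image_stack(
            [kin], [(16, 16, 6)], default_mix, noise_sd=0.0, seed=1,
            frame_shape=(32, 32), n_frames=2,
        )
        direct = cf.render_channel_traces([kin], default_mix, noise_sd=0.0, seed=1, n_frames=2)
        inside = stack[0][:, mask == 1]
        np.testing.assert_allclose(inside.mean(axis=1), direct.data[0, :, 0], rtol=1e-12)

    def test_empty_layout_is_background_only(self, default_mix):
        stack, mask = cf.render_image_stack([], [], default_mix, frame_shape=(16, 16), n_frames=3)
        assert (stack == 0).all()
        assert mask.max() == 0

    def test_overlapping_disks_rejected(self, default_mix):
        kinetics = [_kin(), _kin()]
        with pytest.raises(ValueError, match="overlap"):
            cf.render_image_stack(
                kinetics, [(16, 16, 6), (20, 16, 6)], default_mix,
                frame_shape=(48, 48), n_frames=2,
            )

    def test_out_of_bounds_disk_rejected(self, default_mix):
        with pytest.raises(ValueError, match="outside"):
            cf.render_image_stack([_kin()], [(2, 2, 6)], default_mix, frame_shape=(32, 32), n_frames=2)


class TestBulkCleavage:
    def test_zero_rate_is_constant(self):
        t = np.linspace(0, 1000, 101)
        np.testing.assert_array_equal(cf.simulate_bulk_cleavage(0.0, 1.2, 3.0, t), 1.2)

    def test_asymptote_reaches_r_max(self):
        r = cf.simulate_bulk_cleavage(0.01, 1.0, 3.0, np.array([5000.0]))
        assert r[0] == pytest.approx(3.0, rel=1e-6)

    @pytest.mark.parametrize("k_rate", [0.002, 0.01, 0.05])
    def test_half_change_at_ln2_over_k(self, k_rate):
        t_half = np.log(2) / k_rate
        r = cf.simulate_bulk_cleavage(k_rate, 1.0, 2.0, np.array([t_half]))
        assert r[0] == pytest.approx(1.5, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            cf.simulate_bulk_cleavage(-0.1, 1.0, 2.0, np.arange(3.0))


class TestGroundTruthClosure:
    def test_noiseless_pipeline_recovers_every_index(self, small_population):
        """Oracle closure: the full index extraction on noiseless rendered
        traces reproduces the ground-truth record (times within one frame,
        amplitudes to 1e-6 relative)."""
        cfg, kinetics, records = small_population
        from conftest import normalized_traces

        traces = normalized_traces(kinetics, cfg, noise_sd=0.0)
        h = cfg.frame_interval
        for i, rec in enumerate(records):
            for tag in ("c9", "c3"):
                prof = cf.extract_profile(traces[tag][i], h, tag)
                assert prof.responded
                for name in ("initiation", "saturation", "duration", "time_at_max"):
                    assert abs(getattr(prof, name) - rec.values[f"{name}_{tag}"]) <= h
                for name in ("response_scale", "maximum_ratio", "slope", "integration"):
                    assert getattr(prof, name) == pytest.approx(
                        rec.values[f"{name}_{tag}"], rel=1e-6
                    )
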