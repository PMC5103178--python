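"""Synthetic-culture generator: growth law, rendering fidelity, sensor physics."""

import numpy as np
import pytest

from sourmon.oxygen import phase_to_do
from sourmon.simulate import (
    CultureSimConfig,
    RespiratoryProtocol,
    SensorSimConfig,
    default_sim_calibration,
    phase_from_concentration,
    render_frame,
    simulate_do_series,
    simulate_growth,
    simulate_respiratory_assay,
)


class TestGrowth:
    def test_exponential_closed_form(self):
        # X0 * exp(mu t): 3e4 cells/cm2 at mu 0.041/h for 40 h -> 1.547e5
        cfg = CultureSimConfig(saturation_confluency=1.0)
        truth = simulate_growth(cfg, [0.0, 40.0])
        assert truth.density[-1] == pytest.approx(3e4 * np.exp(0.041 * 40.0), rel=1e-3)
        assert truth.density[-1] == pytest.approx(1.547e5, rel=1e-3)

    def test_zero_growth_rate_constant_density(self):
        cfg = CultureSimConfig(mu_max=0.0)
        truth = simulate_growth(cfg, np.linspace(0, 100, 11))
        assert np.allclose(truth.density, cfg.seeding_density)

    def test_lag_holds_seeding_density(self):
        cfg = CultureSimConfig(seeding_density=5e4, lag_h=72.0, mu_max=0.035)
        truth = simulate_growth(cfg, [0.0, 36.0, 72.0, 100.0])
        assert truth.density[2] == pytest.approx(5e4, rel=1e-9)
        assert truth.density[3] > 5e4

    def test_confluency_capped_at_saturation(self):
        cfg = CultureSimConfig(saturation_confluency=0.6)
        truth = simulate_growth(cfg, np.linspace(0, 400, 81))
        assert truth.confluency.max() <= 0.6 + 1e-6
        assert np.all(np.diff(truth.density) >= -1e-9)

    def test_invariants_count_density_area(self):
        cfg = CultureSimConfig()
        truth = simulate_growth(cfg, np.linspace(0, 40, 9))
        assert np.allclose(truth.cell_count, truth.density * cfg.chamber_area_cm2)
        assert np.all((truth.confluency >= 0) & (truth.confluency <= 1))
        assert np.all(truth.packing_factor >= 1)

    def test_nonfinite_config_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            CultureSimConfig(mu_max=float("nan"))
        with pytest.raises(ValueError):
            CultureSimConfig(seeding_density=-1)
        with pytest.raises(ValueError):
            CultureSimConfig(saturation_confluency=1.5)


class TestRendering:
    def test_zero_confluency_blank_mask(self, small_geometry, cho_config):
        fr = render_frame(0.0, small_geometry, cho_config, np.random.default_rng(0))
        assert fr.mask.sum() == 0
        assert fr.realized_count == 0

    def test_confluency_above_max_rejected(self, small_geometry, cho_config):
        with pytest.raises(ValueError, match="achievable"):
            render_frame(0.97, small_geometry, cho_config, np.random.default_rng(0))

    def test_mask_confluency_is_pixel_count(self, small_geometry, cho_config):
        fr = render_frame(0.25, small_geometry, cho_config, np.random.default_rng(1))
        n_px = np.prod(small_geometry.canvas_shape)
        assert fr.realized_confluency == pytest.approx(fr.mask.sum() / n_px, abs=1e-12)

    @pytest.mark.parametrize("target", [0.05, 0.3, 0.6, 0.8])
    def test_realized_confluency_tracks_request(self, target, small_geometry, cho_config):
        # property over 20 seeds: realized within 2% absolute of requested
        for seed in range(20):
            fr = render_frame(target, small_geometry, cho_config, np.random.default_rng(seed))
            assert abs(fr.realized_confluency - target) <= 0.02

    def test_tile_overlap_strips_identical(self, tile_geometry, cho_config):
        fr = render_frame(0.3, tile_geometry, cho_config, np.random.default_rng(2))
        t0, t1 = fr.tiles[0], fr.tiles[1]  # horizontally adjacent
        step = tile_geometry.step_w
        left_strip = t0["pixels"][:, step:]
        right_strip = t1["pixels"][:, : tile_geometry.tile_w - step]
        assert np.array_equal(left_strip, right_strip)

    def test_colony_mode_packs_denser(self, small_geometry):
        iso = CultureSimConfig(colony_mode=False)
        col = CultureSimConfig(colony_mode=True)
        pf_iso = render_frame(0.4, small_geometry, iso, np.random.default_rng(3)).realized_packing
        pf_col = render_frame(0.4, small_geometry, col, np.random.default_rng(3)).realized_packing
        assert pf_col > pf_iso

    def test_rendering_deterministic(self, small_geometry, cho_config):
        a = render_frame(0.3, small_geometry, cho_config, np.random.default_rng(7))
        b = render_frame(0.3, small_geometry, cho_config, np.random.default_rng(7))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)


class TestSensors:
    def test_outlet_matches_mass_balance(self, quiet_sensors):
        # 20 amol/cell/s uptake by 8.333e4 cells at 300 µL/h depletes 20 µM
        cfg = CultureSimConfig(
            seeding_density=8.3333e4 / 0.8, mu_max=0.0, true_sour_profile=20.0
        )
        truth = simulate_growth(cfg, np.arange(0, 2.1, 0.25))
        raw = simulate_do_series(truth, quiet_sensors, np.random.default_rng(0))
        assert raw.outlet_uM[-1] == pytest.approx(195.0, abs=0.01)
        assert raw.inlet_uM[-1] == pytest.approx(215.0, abs=1e-9)

    def test_no_cells_outlet_equals_inlet(self, quiet_sensors):
        cfg = CultureSimConfig(true_sour_profile=0.0, mu_max=0.0)
        truth = simulate_growth(cfg, np.arange(0, 5.1, 0.5))
        raw = simulate_do_series(truth, quiet_sensors, np.random.default_rng(0))
        assert np.allclose(raw.outlet_uM, raw.inlet_uM)

    def test_mass_conservation_noise_free(self, quiet_sensors):
        cfg = CultureSimConfig(true_sour_profile=60.0)
        truth = simulate_growth(cfg, np.arange(0, 40.1, 0.5))
        raw = simulate_do_series(truth, quiet_sensors, np.random.default_rng(0))
        assert np.all(raw.outlet_uM <= raw.inlet_uM + 1e-9)
        assert np.all(raw.outlet_uM >= 0)

    def test_spikes_are_common_mode(self):
        sensors = SensorSimConfig(noise_sd_uM=0.0, spike_rate_per_h=1.0,
                                  sensor_lag_min=0.0, outlet_transport_delay_min=0.0)
        cfg = CultureSimConfig(mu_max=0.0)
        truth = simulate_growth(cfg, np.arange(0, 20.1, 0.25))
        raw = simulate_do_series(truth, sensors, np.random.default_rng(4))
        assert len(raw.spike_times_h) > 0
        diff = raw.inlet_uM - raw.outlet_uM
        # the differential is untouched by spikes: constant everywhere
        assert np.allclose(diff, diff[0], atol=1e-9)

    def test_insitu_depleted_by_overgrowth(self, quiet_sensors):
        cfg = CultureSimConfig()
        truth = simulate_growth(cfg, np.arange(0, 40.1, 0.5))
        raw = simulate_do_series(truth, quiet_sensors, np.random.default_rng(0))
        assert raw.insitu_uM[-1] < raw.outlet_uM[-1]
        assert np.all(raw.insitu_uM >= 0)

    def test_determinism_same_seed(self):
        cfg = CultureSimConfig()
        truth = simulate_growth(cfg, np.arange(0, 10.1, 0.5))
        sensors = SensorSimConfig()
        a = simulate_do_series(truth, sensors, np.random.default_rng(9))
        b = simulate_do_series(truth, sensors, np.random.default_rng(9))
        assert np.array_equal(a.inlet_uM, b.inlet_uM)
        assert np.array_equal(a.outlet_uM, b.outlet_uM)
        assert np.array_equal(a.insitu_uM, b.insitu_uM)


class TestRespiratoryAssay:
    def test_multiplier_one_matches_plain_series(self, quiet_sensors):
        protocol = RespiratoryProtocol(segments=((0.0, 1.0),), labels=("basal",))
        cfg = CultureSimConfig(mu_max=0.0, true_sour_profile=25.0)
        traces, events = simulate_respiratory_assay(
            protocol, cfg, quiet_sensors, np.random.default_rng(5), t_end_h=6.0
        )
        truth = simulate_growth(cfg, np.arange(0, 6.01, 0.25))
        plain = simulate_do_series(truth, quiet_sensors, np.random.default_rng(5), t_end_h=6.0)
        assert np.array_equal(traces.outlet_uM, plain.outlet_uM)
        assert events == []

    def test_uptake_decrease_raises_insitu(self, quiet_sensors):
        protocol = RespiratoryProtocol(segments=((0.0, 1.0), (2.5, 0.2)), labels=("basal", "oligomycin"))
        cfg = CultureSimConfig(seeding_density=5e5, mu_max=0.0, true_sour_profile=25.0,
                               cell_footprint_um2=(180.0, 40.0), colony_mode=True)
        sensors = SensorSimConfig(noise_sd_uM=0.0, spike_rate_per_h=0.0, bias_max_uM=60.0)
        traces, _ = simulate_respiratory_assay(protocol, cfg, sensors, np.random.default_rng(0), t_end_h=5.0)
        post = (traces.t_h > 2.5) & (traces.t_h <= 3.5)
        assert np.all(np.diff(traces.insitu_uM[post]) > 0)

    def test_uptake_increase_drops_insitu(self, quiet_sensors):
        protocol = RespiratoryProtocol(segments=((0.0, 1.0), (6.0, 3.0)), labels=("basal", "FCCP"))
        cfg = CultureSimConfig(seeding_density=2e5, mu_max=0.0, true_sour_profile=20.0,
                               cell_footprint_um2=(180.0, 40.0), colony_mode=True)
        sensors = SensorSimConfig(noise_sd_uM=0.0, spike_rate_per_h=0.0, bias_max_uM=60.0,
                                  sensor_lag_min=3.0)
        traces, _ = simulate_respiratory_assay(protocol, cfg, sensors, np.random.default_rng(0), t_end_h=8.0)
        post = (traces.t_h > 6.0) & (traces.t_h <= 7.0)
        assert np.all(np.diff(traces.insitu_uM[post]) < 0)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            RespiratoryProtocol(segments=((0.0, 1.0), (2.5, 0.2), (2.5, 3.0)),
                                labels=("a", "b", "c"))

    def test_segment_outside_span_rejected(self, quiet_sensors):
        protocol = RespiratoryProtocol()
        with pytest.raises(ValueError, match="span"):
            simulate_respiratory_assay(
                protocol, CultureSimConfig(), quiet_sensors, np.random.default_rng(0), t_end_h=4.0
            )


class TestPhaseInversion:
    def test_calibration_anchors(self):
        cal = default_sim_calibration()
        assert phase_from_concentration(0.0, cal) == pytest.approx(cal.phi0_deg, abs=1e-12)
        assert phase_from_concentration(cal.c_air_uM, cal) == pytest.approx(cal.phi_air_deg, abs=1e-9)

    def test_round_trip(self):
        cal = default_sim_calibration()
        conc = np.array([0.0, 10.0, 123.4, 200.0, 500.0])
        back, flags = phase_to_do(phase_from_concentration(conc, cal), cal)
        assert np.allclose(back, conc, rtol=1e-9)
        assert all(f == "" for f in flags)

    def test_out_of_range_rejected(self):
        cal = default_sim_calibration()
        with pytest.raises(ValueError, match="range"):
            phase_from_concentration(2000.0, cal)
        with pytest.raises(ValueError):
            phase_from_concentration(-1.0, cal)
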