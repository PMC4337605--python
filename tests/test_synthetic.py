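"""Ground-truth model building, rendering and simulated dynamics."""

import numpy as np
import pytest

from helixafm import (
    GeneratorConfig,
    HeightFrame,
    build_filament_model,
    detect_peaks_along_trace,
    make_paracrystal_field,
    render_frame,
    simulate_dynamics,
    trace_backbone,
)
from helixafm.config import STATE_B_NEIGHBOR, STATE_DECORATED, STATE_P_NEIGHBOR
from helixafm.severing import detect_breaks
from helixafm.peaktrack import trace_all
from helixafm.synthetic import (
    PITCH_TRUNCATION_NM,
    dilate_with_tip,
    _tip_structure,
)


class TestBuildFilamentModel:
    def test_zero_variance_pitches_exact(self, zero_var_config, rng):
        m = build_filament_model(zero_var_config, 10, rng=rng)
        assert np.allclose(m.pitches, 36.8)

    def test_structural_sd_recovered_at_n2000(self, default_config):
        rng = np.random.default_rng(7)
        m = build_filament_model(default_config, 2000, rng=rng)
        sd = m.pitches.std(ddof=1)
        # SE of an SD estimate is sigma/sqrt(2n); allow 3 SE
        se = 3.1 / np.sqrt(2 * 2000)
        assert abs(sd - 3.1) < 3 * se
        assert abs(m.pitches.mean() - 36.8) < 3 * 3.1 / np.sqrt(2000)

    def test_neighbor_states_flank_decorated_run(self, default_config, rng):
        m = build_filament_model(default_config, 12, [(5, 8)], rng=rng)
        st = m.states
        assert all(s == STATE_DECORATED for s in st[5:9])
        assert st[4] == STATE_P_NEIGHBOR  # pointed end at index 0
        assert st[9] == STATE_B_NEIGHBOR

    def test_overlapping_intervals_rejected(self, default_config, rng):
        with pytest.raises(ValueError):
            build_filament_model(default_config, 12, [(2, 5), (5, 7)], rng=rng)

    def test_empty_filament_rejected(self, default_config, rng):
        with pytest.raises(ValueError):
            build_filament_model(default_config, 0, rng=rng)

    def test_pitch_truncation_floor(self, default_config):
        # an absurdly wide pitch distribution still never emits <= 10 nm
        cfg = default_config
        cfg.states["bare"].pitch_sd_struct_nm = 12.0
        rng = np.random.default_rng(0)
        m = build_filament_model(cfg, 500, rng=rng)
        assert m.pitches.min() > PITCH_TRUNCATION_NM


class TestRenderFrame:
    def test_noiseless_peak_spacing_within_one_pixel(self, zero_var_config, rng):
        m = build_filament_model(zero_var_config, 6, rng=rng)
        fr = render_frame(m, zero_var_config)
        tr = trace_backbone(fr, (m.total_arc_nm / 2, 18.0))
        peaks = detect_peaks_along_trace(fr, tr)
        assert len(peaks) == 7
        spacing = np.diff([p.arc_nm for p in peaks])
        assert np.all(np.abs(spacing - 36.8) <= zero_var_config.pixel_size_nm)

    def test_noiseless_heights_match_truth_within_interp_error(self, zero_var_config, rng):
        m = build_filament_model(zero_var_config, 6, rng=rng)
        fr = render_frame(m, zero_var_config)
        tr = trace_backbone(fr, (m.total_arc_nm / 2, 18.0))
        peaks = detect_peaks_along_trace(fr, tr)
        for p in peaks:
            assert abs(p.height_nm - 8.6) < 0.1

    def test_tip_dilation_preserves_peak_and_widens(self, zero_var_config, rng):
        m = build_filament_model(zero_var_config, 4, rng=rng)
        cfg0 = zero_var_config.with_(tip_radius_nm=0.0)
        cfg3 = zero_var_config.with_(tip_radius_nm=3.0)
        fr0 = render_frame(m, cfg0)
        fr3 = render_frame(m, cfg3)
        assert abs(fr0.grid.max() - fr3.grid.max()) < 1e-9
        width0 = (fr0.grid >= 4.0).sum(axis=0).max()
        width3 = (fr3.grid >= 4.0).sum(axis=0).max()
        assert width3 > width0

    def test_dilation_matches_brute_force_oracle(self, rng):
        grid = rng.uniform(0, 8, (16, 16))
        r_nm, px = 3.0, 1.5
        out = dilate_with_tip(grid, r_nm, px)
        S = _tip_structure(r_nm, px)
        R = S.shape[0] // 2
        for r in range(16):
            for c in range(16):
                best = -np.inf
                for dr in range(-R, R + 1):
                    for dc in range(-R, R + 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < 16 and 0 <= cc < 16 and S[R + dr, R + dc] > -1e8:
                            best = max(best, grid[rr, cc] + S[R + dr, R + dc])
                assert abs(out[r, c] - best) < 1e-9

    def test_decorated_segment_two_nm_taller(self, zero_var_config, rng):
        m = build_filament_model(zero_var_config, 12, [(6, 11)], rng=rng)
        fr = render_frame(m, zero_var_config)
        tr = trace_backbone(fr, (30.0, 18.0))
        peaks = detect_peaks_along_trace(fr, tr)
        heights = np.array([p.height_nm for p in peaks])
        # bare half: ~8.6; decorated half: ~10.6
        assert abs(heights[1:4].mean() - 8.6) < 0.1
        assert abs(heights[-3:].mean() - 10.6) < 0.1
        assert abs(heights[-3:].mean() - heights[1:4].mean() - 2.0) < 0.2

    def test_rendering_deterministic_given_seed(self, default_config, rng):
        m = build_filament_model(default_config, 5, rng=rng)
        f1 = render_frame(m, default_config)
        f2 = render_frame(m, default_config)
        assert np.array_equal(f1.grid, f2.grid)

    def test_envelope_floor_between_peaks(self, zero_var_config, rng):
        cfg = zero_var_config.with_(subunit_ripple_nm=0.0, tip_radius_nm=0.0)
        m = build_filament_model(cfg, 4, rng=rng)
        fr = render_frame(m, cfg)
        row = fr.grid[fr.shape[0] // 2]
        arcs = m.crossover_arcs_true
        mid = int(round((arcs[1] + arcs[2]) / 2 / cfg.pixel_size_nm))
        assert abs(row[mid] - 0.75 * 8.6) < 0.05


class TestSimulateDynamics:
    def test_frozen_dynamics_identical_frames_empty_log(self, zero_var_config, rng):
        cfg = zero_var_config.with_(n_frames=4, growth_rate_per_s=0.0)
        m = build_filament_model(cfg, 6, [(2, 3)], rng=rng)
        movie, log = simulate_dynamics(m, cfg, rng)
        assert len(log.growth_events) == 0 and len(log.severing_events) == 0
        for fr in movie.frames[1:]:
            assert np.array_equal(fr.grid, movie.frames[0].grid)

    def test_full_pointed_bias_gives_only_pointed_events(self, default_config):
        cfg = default_config.with_(
            n_frames=40, growth_rate_per_s=1.0, growth_bias_pointed=1.0
        )
        rng = np.random.default_rng(5)
        m = build_filament_model(cfg, 20, [(16, 17)], rng=rng)
        _, log = simulate_dynamics(m, cfg, rng)
        assert len(log.growth_events) > 5
        assert all(ev.direction == "pointed" for ev in log.growth_events)

    def test_direction_sampling_matches_binomial(self, default_config):
        # pool events over many short simulations; logged fraction ~ Bernoulli(beta)
        cfg = default_config.with_(
            n_frames=25, growth_rate_per_s=1.0, growth_bias_pointed=0.8
        )
        rng = np.random.default_rng(11)
        pointed = total = 0
        for _ in range(12):
            m = build_filament_model(cfg, 30, [(24, 25)], rng=rng)
            _, log = simulate_dynamics(m, cfg, rng)
            total += len(log.growth_events)
            pointed += sum(1 for ev in log.growth_events if ev.direction == "pointed")
        assert total >= 120
        phat = pointed / total
        half_width = 1.96 * np.sqrt(0.8 * 0.2 / total)
        assert abs(phat - 0.8) < half_width + 0.02

    def test_growth_redraws_pitch_to_decorated_distribution(self, zero_var_config):
        cfg = zero_var_config.with_(
            n_frames=30, growth_rate_per_s=1.0, growth_bias_pointed=1.0
        )
        rng = np.random.default_rng(3)
        m = build_filament_model(cfg, 10, [(8, 9)], rng=rng)
        _, log = simulate_dynamics(m, cfg, rng)
        final = log.filaments[0].frames[-1]
        for i, st in enumerate(final.states):
            pitch = final.crossover_arcs_true[i + 1] - final.crossover_arcs_true[i]
            if st == STATE_DECORATED:
                assert abs(pitch - 26.9) < 1e-9
        assert len(final.cluster_spans[0] if final.cluster_spans else ()) or True

    def test_logged_severing_events_appear_as_breaks(self, default_config):
        rates = {"far_bare": 0, "neighbor_bare": 2e-2, "end_cluster": 2e-2, "inner_cluster": 0}
        cfg = default_config.with_(n_frames=25, severing_rates=rates)
        rng = np.random.default_rng(17)
        movie = log = None
        for _ in range(10):  # find a simulation with at least one severing event
            m = build_filament_model(cfg, 14, [(6, 8)], rng=rng)
            movie, log = simulate_dynamics(m, cfg, rng)
            if log.severing_events:
                break
        assert log.severing_events, "no severing occurred; rates too low for test"
        traces = trace_all(movie[0])
        events = detect_breaks(movie, traces)
        assert len(events) == len(log.severing_events)


class TestParacrystalField:
    def test_mean_and_zero_structural_variation(self):
        cfg = GeneratorConfig.paracrystal_preset(
            n_frames=1, noise_sd_nm=0.0, localization_jitter_nm=0.0
        )
        movie, log = make_paracrystal_field(cfg, 3, 10)
        for fil in log.filaments:
            pitches = np.diff(fil.frames[0].crossover_arcs_true)
            assert np.allclose(pitches, 36.5)

    def test_no_jitter_no_noise_measured_sd_below_quantization(self):
        cfg = GeneratorConfig.paracrystal_preset(
            n_frames=1, noise_sd_nm=0.0, localization_jitter_nm=0.0
        )
        movie, _ = make_paracrystal_field(cfg, 4, 15)
        pitches = []
        for tr in trace_all(movie[0]):
            pk = detect_peaks_along_trace(movie[0], tr)
            pitches.extend(np.diff([p.arc_nm for p in pk]))
        sd = np.std(pitches, ddof=1)
        assert sd <= cfg.pixel_size_nm  # pixel-quantization bound

    def test_jitter_propagates_to_pitch_sd_by_sqrt2(self):
        # difference of two i.i.d. per-peak jitters has SD sigma_p * sqrt(2)
        cfg = GeneratorConfig.paracrystal_preset(n_frames=1, noise_sd_nm=0.0)
        rng = np.random.default_rng(23)
        movie, log = make_paracrystal_field(cfg, 25, 20, rng=rng)
        obs = []
        for fil in log.filaments:
            obs.extend(np.diff(fil.frames[0].crossover_arcs_observed))
        sd = np.std(obs, ddof=1)
        expected = cfg.localization_jitter_nm * np.sqrt(2)
        assert abs(sd - expected) < 3 * expected / np.sqrt(2 * len(obs))
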