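"""Simulator contracts: determinism, rendering physics, ground truth."""

from dataclasses import replace

import numpy as np
import pytest

import kymotrace as kt
from kymotrace.simulate import _transient_kernel


class TestTransportStream:
    def test_empty_scene_equals_background(self, straight_path_cfg):
        stream, tracks = kt.simulate_transport_stream(straight_path_cfg)
        assert tracks == []
        assert np.all(stream.frames == 10.0)

    def test_frame_count_matches_regime(self):
        cfg = kt.TransportSimConfig(duration_s=50.0, frame_interval_s=0.1, n_vesicles=0)
        stream, _ = kt.simulate_transport_stream(cfg)
        assert stream.n_frames == 500

    def test_constant_velocity_displacement(self, straight_path_cfg):
        # +1 µm/s for 10 s at 0.1 µm/px: the spot ends 100 px from its entry
        cfg = replace(
            straight_path_cfg,
            vesicle_specs=(kt.VesicleSpec(entry_time_s=0.0, velocity_um_s=1.0),),
            pause_prob_per_frame=0.0,
            vesicle_amplitude=50.0,
        )
        stream, tracks = kt.simulate_transport_stream(cfg)
        track = tracks[0]
        finite = track.positions_um[np.isfinite(track.positions_um)]
        assert finite[-1] - 0.0 == pytest.approx(10.0, abs=1e-9)
        # oracle: argmax of the noiseless last frame vs the path entry point
        row, col = np.unravel_index(np.argmax(stream.frames[-1]), stream.frames[-1].shape)
        entry_col = cfg.path[0][1]
        assert abs((col - entry_col) - 100.0) <= 1.0

    def test_determinism_bit_identical(self):
        cfg = kt.TransportSimConfig(seed=42, duration_s=5.0)
        s1, t1 = kt.simulate_transport_stream(cfg)
        s2, t2 = kt.simulate_transport_stream(cfg)
        assert np.array_equal(s1.frames, s2.frames)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.positions_um, b.positions_um, equal_nan=True)

    def test_flux_conservation_per_frame(self, straight_path_cfg):
        # with noise off, the fluorescence a fully in-field spot adds per
        # frame is amplitude * 2*pi*sigma_px^2, constant along the run
        cfg = replace(
            straight_path_cfg,
            duration_s=8.0,
            vesicle_specs=(
                kt.VesicleSpec(entry_time_s=0.0, velocity_um_s=1.0, entry_pos_um=3.0),
            ),
            pause_prob_per_frame=0.0,
            vesicle_amplitude=40.0,
            vesicle_sigma_um=0.15,
        )
        stream, _ = kt.simulate_transport_stream(cfg)
        added = stream.frames.reshape(stream.n_frames, -1).sum(axis=1) - (
            10.0 * stream.frames[0].size
        )
        sigma_px = cfg.vesicle_sigma_um / cfg.pixel_size_um
        expected = cfg.vesicle_amplitude * 2 * np.pi * sigma_px**2
        assert np.all(np.abs(added / expected - 1.0) < 0.005)

    def test_bleach_contract(self, straight_path_cfg):
        cfg = replace(
            straight_path_cfg,
            bleach_factor=0.25,
            bleach_window_um=(3.0, 9.0),
            background_level=100.0,
        )
        stream, _ = kt.simulate_transport_stream(cfg)
        frame = stream.frames[0]
        path_row = 8
        cols = np.arange(frame.shape[1])
        pos_um = (cols - cfg.path[0][1]) * cfg.pixel_size_um
        inside = (pos_um >= 3.0) & (pos_um < 9.0)
        on_path = (cols >= cfg.path[0][1]) & (cols <= cfg.path[1][1])
        ratio = frame[path_row, inside & on_path].mean() / frame[
            path_row, ~inside & on_path
        ].mean()
        assert ratio == pytest.approx(0.25, rel=0.01)

    def test_moving_vesicles_not_bleached(self, straight_path_cfg):
        cfg = replace(
            straight_path_cfg,
            bleach_factor=0.1,
            bleach_window_um=(2.0, 12.0),
            vesicle_specs=(
                kt.VesicleSpec(entry_time_s=0.0, velocity_um_s=1.0, entry_pos_um=5.0),
            ),
            pause_prob_per_frame=0.0,
            vesicle_amplitude=50.0,
        )
        stream, tracks = kt.simulate_transport_stream(cfg)
        # spot sits inside the bleach window; its added amplitude is intact
        peak = stream.frames[0].max()
        assert peak == pytest.approx(0.1 * 10.0 + 50.0, rel=0.02)

    def test_crossing_count_monotone_in_n_vesicles(self):
        def mean_crossings(n):
            total = 0
            for seed in range(15):
                cfg = kt.TransportSimConfig(n_vesicles=n, seed=seed, shot_noise=False)
                _, tracks = kt.simulate_transport_stream(cfg)
                b0, b1 = cfg.bleach_window_um
                for tr in tracks:
                    p = tr.positions_um[np.isfinite(tr.positions_um)]
                    if p.size and np.any((p >= b0) & (p < b1)):
                        total += 1
            return total / 15

        means = [mean_crossings(n) for n in (2, 5, 10)]
        assert means[0] < means[1] < means[2]

    def test_config_validation(self):
        with pytest.raises(kt.ConfigurationError):
            kt.TransportSimConfig(path=((1.0, 1.0),))
        with pytest.raises(kt.ConfigurationError):
            kt.TransportSimConfig(bleach_factor=0.0)
        with pytest.raises(kt.ConfigurationError):
            kt.TransportSimConfig(velocity_range_um_s=(2.0, 1.0))
        with pytest.raises(kt.ConfigurationError):
            kt.TransportSimConfig(bleach_window_um=(0.0, 99.0))


class TestCalciumTrace:
    def test_paper_regime_sample_count(self):
        cfg = kt.CalciumSimConfig(duration_s=60.0, frame_interval_s=0.25)
        trace, _ = kt.simulate_calcium_trace(cfg)
        assert trace.n_samples == 240

    def test_silent_trace_is_flat_baseline(self):
        cfg = kt.CalciumSimConfig(
            n_transients=0, baseline_drift_amplitude=0.0, noise_sd=0.0
        )
        trace, truth = kt.simulate_calcium_trace(cfg)
        assert np.all(trace.fluorescence == cfg.baseline_level)
        assert truth.onset_times_s.size == 0

    def test_single_transient_peak_height(self):
        # kernel scaled to its drawn amplitude: max(trace) = (1 + a) * b
        cfg = kt.CalciumSimConfig(
            n_transients=1,
            transient_amplitude_range=(0.5, 0.5),
            baseline_drift_amplitude=0.0,
            noise_sd=0.0,
            baseline_level=80.0,
            frame_interval_s=0.01,  # dense grid to sample the true maximum
            seed=3,
        )
        trace, truth = kt.simulate_calcium_trace(cfg)
        assert truth.peak_amplitudes_dff[0] == pytest.approx(0.5)
        assert trace.fluorescence.max() == pytest.approx(1.5 * 80.0, rel=1e-4)

    def test_kernel_unit_maximum(self):
        t = np.linspace(0, 20, 200001)
        k = _transient_kernel(t, 1.0, 0.1, 0.6)
        assert k.max() == pytest.approx(1.0, rel=1e-6)
        assert np.all(k[t < 1.0] == 0.0)

    def test_determinism(self):
        cfg = kt.CalciumSimConfig(seed=11)
        a, _ = kt.simulate_calcium_trace(cfg)
        b, _ = kt.simulate_calcium_trace(cfg)
        assert np.array_equal(a.fluorescence, b.fluorescence)

    def test_onsets_strictly_increasing(self):
        for seed in range(10):
            _, truth = kt.simulate_calcium_trace(
                kt.CalciumSimConfig(n_transients=5, seed=seed)
            )
            assert np.all(np.diff(truth.onset_times_s) > 0)
            assert truth.onset_times_s[0] >= 0
            assert truth.onset_times_s[-1] <= 60.0

    def test_config_validation(self):
        with pytest.raises(kt.ConfigurationError):
            kt.CalciumSimConfig(baseline_level=0.0)
        with pytest.raises(kt.ConfigurationError):
            kt.CalciumSimConfig(rise_tau_s=0.7, decay_tau_s=0.6)
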