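"""Generator contracts: noiseless formula agreement, limits, determinism."""

import numpy as np
import pytest

from fadyn.errors import InvalidParameterError
from fadyn.motility import directionality_ratio, mean_velocity
from fadyn.sim import (
    FrapSimParams,
    LifetimeSimParams,
    SpotImageParams,
    TrackSimParams,
    simulate_adhesion_trace,
    simulate_frap_trace,
    simulate_spot_image,
    simulate_tracks,
)


class TestFrapGenerator:
    def test_noiseless_trace_follows_recovery_formula(self):
        p = FrapSimParams(noise_sd=0.0, bleach_depth=0.2, mobile_fraction=1.0, k=0.1)
        trace, truth = simulate_frap_trace(p)
        t = trace.frame_times[p.n_prebleach:] - trace.frame_times[p.n_prebleach]
        rfi = (trace.roi_intensity[p.n_prebleach:] - p.background_level) / p.prebleach_level
        expected = 0.2 + 0.8 * (1.0 - np.exp(-0.1 * t))
        np.testing.assert_allclose(rfi, expected, rtol=1e-12)
        # at t = ln2/k the recovery formula passes through 0.2 + 0.8 * 0.5
        t_half = np.log(2) / 0.1
        assert 0.2 + 0.8 * (1 - np.exp(-0.1 * t_half)) == pytest.approx(0.6)
        assert truth.params["t_half"] == pytest.approx(t_half)

    def test_prebleach_frames_at_prebleach_level(self):
        p = FrapSimParams(noise_sd=0.0)
        trace, _ = simulate_frap_trace(p)
        np.testing.assert_allclose(
            trace.roi_intensity[: p.n_prebleach], p.background_level + p.prebleach_level
        )

    def test_first_postbleach_frame_drops_to_bleach_depth(self):
        p = FrapSimParams(noise_sd=0.0, bleach_depth=0.3)
        trace, _ = simulate_frap_trace(p)
        assert trace.roi_intensity[p.n_prebleach] == pytest.approx(
            p.background_level + 0.3 * p.prebleach_level
        )

    def test_immobile_limit_stays_at_bleach_depth(self):
        p = FrapSimParams(noise_sd=0.0, mobile_fraction=0.0, bleach_depth=0.25)
        trace, _ = simulate_frap_trace(p)
        rfi = (trace.roi_intensity[p.n_prebleach:] - p.background_level) / p.prebleach_level
        np.testing.assert_allclose(rfi, 0.25, rtol=1e-12)

    def test_seed_determinism(self):
        p = FrapSimParams(noise_sd=30.0, seed=7)
        a, _ = simulate_frap_trace(p)
        b, _ = simulate_frap_trace(p)
        np.testing.assert_array_equal(a.roi_intensity, b.roi_intensity)
        np.testing.assert_array_equal(a.background_intensity, b.background_intensity)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(frame_interval=0.0),
            dict(k=-0.1),
            dict(bleach_depth=1.0),
            dict(mobile_fraction=1.5),
            dict(noise_sd=-1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            simulate_frap_trace(FrapSimParams(**bad))

    def test_acquisition_regime_dimensions(self):
        # 3 prebleach frames, 2-s interval, 5 min postbleach
        trace, _ = simulate_frap_trace(FrapSimParams())
        assert trace.n_prebleach == 3
        assert np.diff(trace.frame_times)[0] == pytest.approx(2.0)
        post = trace.frame_times[-1] - trace.frame_times[trace.n_prebleach]
        assert post == pytest.approx(300.0)


class TestAdhesionGenerator:
    def test_noiseless_max_is_plateau_within_grid(self):
        p = LifetimeSimParams(noise_sd=0.0)
        trace, _ = simulate_adhesion_trace(p)
        assert np.max(trace.intensity_bgsub) == pytest.approx(p.plateau_intensity, rel=0.01)

    def test_zero_dwell_peak_is_last_assembly_frame(self):
        p = LifetimeSimParams(dwell_time=0.0, noise_sd=0.0)
        trace, truth = simulate_adhesion_trace(p)
        i_pk = int(np.argmax(trace.intensity_bgsub))
        # the raw maximum sits at the disassembly onset, the last frame on the rise
        assert trace.frame_times[i_pk] == pytest.approx(truth.params["disassembly_onset"])
        assert np.all(np.diff(trace.intensity_bgsub[: i_pk + 1]) > 0)
        assert np.all(np.diff(trace.intensity_bgsub[i_pk:]) < 0)

    def test_seed_determinism(self):
        p = LifetimeSimParams(noise_sd=40.0, seed=3)
        a, _ = simulate_adhesion_trace(p)
        b, _ = simulate_adhesion_trace(p)
        np.testing.assert_array_equal(a.intensity_raw, b.intensity_raw)

    def test_ground_truth_lifetime_definition(self):
        p = LifetimeSimParams(noise_sd=0.0)
        _, truth = simulate_adhesion_trace(p)
        expected = (
            truth.params["disassembly_onset"]
            + np.log(2) / p.disassembly_rate_true
            - p.assembly_midpoint
        )
        assert truth.params["lifetime"] == pytest.approx(expected)

    def test_invalid_rates_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_adhesion_trace(LifetimeSimParams(assembly_rate_true=0.0))
        with pytest.raises(InvalidParameterError):
            simulate_adhesion_trace(LifetimeSimParams(dwell_time=-1.0))


class TestTrackGenerator:
    def test_full_persistence_gives_straight_lines(self):
        p = TrackSimParams(n_cells=5, persistence=1.0, bias_strength=0.0,
                           positional_noise_sd=0.0, seed=1)
        tracks, _ = simulate_tracks(p)
        for tr in tracks:
            _, _, ratio = directionality_ratio(tr)
            assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_zero_speed_gives_stationary_tracks(self):
        p = TrackSimParams(n_cells=3, speed_mean=0.0, seed=2)
        tracks, _ = simulate_tracks(p)
        for tr in tracks:
            assert np.all(tr.positions == tr.positions[0])

    def test_full_bias_aligns_mean_step_direction_with_wound(self):
        # oracle: average of per-step displacement directions over all steps
        p = TrackSimParams(n_cells=60, n_frames=40, bias_strength=1.0,
                           persistence=0.3, wound_direction=(0.0, 1.0), seed=5)
        tracks, _ = simulate_tracks(p)
        steps = np.concatenate([np.diff(tr.positions, axis=0) for tr in tracks])
        dirs = steps / np.linalg.norm(steps, axis=1, keepdims=True)
        mean_dir = dirs.mean(axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        # Monte-Carlo error at ~2400 steps is far below 0.05
        assert mean_dir @ np.array([0.0, 1.0]) > 0.95

    def test_mean_speed_recovered_across_cells(self):
        p = TrackSimParams(n_cells=200, n_frames=21, speed_mean=5.0, seed=11)
        tracks, truth = simulate_tracks(p)
        velocities = [mean_velocity(tr) for tr in tracks]
        assert np.mean(velocities) == pytest.approx(5.0, rel=0.05)
        # per-cell ground truth matches the observed per-cell velocity
        np.testing.assert_allclose(
            velocities, truth.params["per_cell_mean_speed"], rtol=1e-9
        )

    def test_too_few_frames_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_tracks(TrackSimParams(n_frames=1))

    def test_seed_determinism(self):
        p = TrackSimParams(n_cells=4, seed=9)
        a, _ = simulate_tracks(p)
        b, _ = simulate_tracks(p)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)


class TestSpotImageGenerator:
    def test_single_spot_brightest_pixel_at_center(self):
        p = SpotImageParams(image_shape=(64, 64), spots=((20.0, 31.0, 100.0, 2.0),), noise_sd=0.0)
        img, _ = simulate_spot_image(p)
        assert np.unravel_index(np.argmax(img), img.shape) == (20, 31)

    def test_zero_spots_flat_background(self):
        p = SpotImageParams(image_shape=(16, 16), spots=(), background_level=7.0, noise_sd=0.0)
        img, _ = simulate_spot_image(p)
        np.testing.assert_allclose(img, 7.0)

    def test_seed_determinism(self):
        p = SpotImageParams(spots=((10, 10, 50, 1.5),), noise_sd=2.0, seed=4)
        a, _ = simulate_spot_image(p)
        b, _ = simulate_spot_image(p)
        np.testing.assert_array_equal(a, b)

    def test_center_outside_image_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_spot_image(SpotImageParams(image_shape=(32, 32), spots=((40.0, 10.0, 50.0, 2.0),)))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_spot_image(SpotImageParams(spots=((10.0, 10.0, 50.0, 0.0),)))


def test_every_generator_attaches_one_ground_truth_record():
    _, g1 = simulate_frap_trace(FrapSimParams())
    _, g2 = simulate_adhesion_trace(LifetimeSimParams())
    _, g3 = simulate_tracks(TrackSimParams(n_cells=2))
    _, g4 = simulate_spot_image(SpotImageParams())
    for g in (g1, g2, g3, g4):
        assert g.object_id
        assert "model" in g.params
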