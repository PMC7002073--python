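"""Generators: closed-form checks, determinism, and ground-truth bookkeeping."""

import numpy as np
import pytest

from murodyn import synthetic
from murodyn.containers import (
    CellGeometry,
    GeometryError,
    ParameterError,
    TwoStateParams,
)


def _all_jumps(ts):
    return np.concatenate(
        [np.linalg.norm(np.diff(t.positions, axis=0), axis=1) for t in ts if len(t) > 1]
    )


class TestTwoStateTracks:
    def test_immobile_noiseless_displacements_are_zero(self):
        p = TwoStateParams(f_bound=1.0, d_free=0.0, d_bound=0.0, sigma_loc=0.0, dt=0.06)
        ts, _ = synthetic.simulate_two_state_tracks(p, n_tracks=50, seed=0)
        assert np.all(_all_jumps(ts) == 0.0)

    def test_free_diffusion_msd_matches_4_d_dt(self):
        p = TwoStateParams(f_bound=0.0, d_free=0.075, sigma_loc=0.0, dt=0.06)
        ts, _ = synthetic.simulate_two_state_tracks(
            p, n_tracks=15000, mean_track_len=9, seed=1
        )
        jumps = _all_jumps(ts)
        assert len(jumps) >= 1e5
        msd = np.mean(jumps**2)
        expected = 4 * 0.075 * 0.06  # 0.018 um^2
        se = np.std(jumps**2) / np.sqrt(len(jumps))
        assert abs(msd - expected) < 3 * se

    def test_same_seed_bitwise_identical(self, near_wt_params):
        a, _ = synthetic.simulate_two_state_tracks(near_wt_params, n_tracks=30, seed=7)
        b, _ = synthetic.simulate_two_state_tracks(near_wt_params, n_tracks=30, seed=7)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.positions, tb.positions)
            assert np.array_equal(ta.frames, tb.frames)

    def test_bound_label_fraction_converges(self, near_wt_params):
        n = 20000
        _, gt = synthetic.simulate_two_state_tracks(near_wt_params, n_tracks=n, seed=3)
        frac = sum(1 for s in gt.states if s == "bound") / n
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < 3 * se

    def test_track_lengths_geometric_minimum_two(self, near_wt_params):
        ts, _ = synthetic.simulate_two_state_tracks(
            near_wt_params, n_tracks=5000, mean_track_len=8, seed=4
        )
        lengths = np.array([len(t) for t in ts])
        assert lengths.min() >= 2
        assert abs(lengths.mean() - 8) < 3 * lengths.std() / np.sqrt(len(lengths))

    def test_confinement_keeps_true_positions_in_rod(self, near_wt_params):
        geom = CellGeometry(length=3.0, diameter=0.9, center=(5.0, 2.0))
        _, gt = synthetic.simulate_two_state_tracks(
            near_wt_params, n_tracks=200, geometry=geom, seed=5
        )
        for pos in gt.true_positions:
            rel = pos - np.asarray(geom.center)
            assert np.all(np.abs(rel[:, 0]) <= geom.length / 2 + 1e-9)
            assert np.all(np.abs(rel[:, 1]) <= geom.diameter / 2 + 1e-9)

    def test_ground_truth_maps_every_track(self, near_wt_params):
        ts, gt = synthetic.simulate_two_state_tracks(near_wt_params, n_tracks=40, seed=6)
        assert len(gt.states) == len(ts) == len(gt.true_positions)
        for t, true in zip(ts, gt.true_positions):
            assert true.shape == t.positions.shape

    def test_geometry_smaller_than_step_scale_rejected(self):
        p = TwoStateParams(f_bound=0.0, d_free=5.0, sigma_loc=0.0, dt=0.06)
        # step scale sqrt(2*5*0.06) ~ 0.77 um > 0.5 um diameter
        with pytest.raises(GeometryError):
            synthetic.simulate_two_state_tracks(
                p, n_tracks=5, geometry=CellGeometry(length=1.0, diameter=0.5), seed=0
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            TwoStateParams(f_bound=1.2, d_free=0.1)
        with pytest.raises(ParameterError):
            TwoStateParams(f_bound=0.5, d_free=0.01, d_bound=0.05)
        with pytest.raises(ParameterError):
            synthetic.simulate_two_state_tracks(
                TwoStateParams(f_bound=0.5, d_free=0.1), n_tracks=0
            )


class TestDirectedTracks:
    def test_noiseless_steps_exactly_speed_times_interval(self, rod_geometry):
        # 10 nm/s * 2 s = 20 nm per step; short tracks stay clear of the walls
        ts, _ = synthetic.simulate_directed_tracks(
            10.0, 2.0, 20, 5, 0.0, CellGeometry(length=100.0, diameter=100.0), seed=0
        )
        for t in ts:
            steps = np.linalg.norm(np.diff(t.positions, axis=0), axis=1)
            np.testing.assert_allclose(steps, 0.020, rtol=1e-12)

    def test_zero_speed_tracks_are_stationary(self, rod_geometry):
        ts, _ = synthetic.simulate_directed_tracks(0.0, 2.0, 10, 8, 0.0, rod_geometry, seed=1)
        for t in ts:
            assert np.all(t.positions == t.positions[0])

    def test_noise_inflates_mean_step_by_folded_normal_amount(self):
        """With localization noise the apparent per-step displacement
        exceeds the true one; a Monte-Carlo oracle for the 2-D
        noisy-step magnitude gives the expected inflation."""
        speed, interval, sigma = 10.0, 2.0, 0.02
        step = speed * 1e-3 * interval
        oracle_rng = np.random.default_rng(99)
        n = 10**6
        # jump = (step + dx, dy), dx, dy ~ N(0, 2 sigma^2) (two endpoints)
        noisy = np.hypot(
            step + oracle_rng.normal(0, np.sqrt(2) * sigma, n),
            oracle_rng.normal(0, np.sqrt(2) * sigma, n),
        )
        expected_mean = noisy.mean()
        oracle_se = noisy.std() / np.sqrt(n)

        geom = CellGeometry(length=20.0, diameter=16.0)
        ts, _ = synthetic.simulate_directed_tracks(speed, interval, 3000, 12, sigma, geom, seed=2)
        steps = np.concatenate(
            [np.linalg.norm(np.diff(t.positions, axis=0), axis=1) for t in ts]
        )
        se = steps.std() / np.sqrt(len(steps)) + oracle_se
        assert steps.mean() > step  # strictly inflated
        assert abs(steps.mean() - expected_mean) < 3 * se

    def test_short_track_rejected(self, rod_geometry):
        with pytest.raises(ParameterError):
            synthetic.simulate_directed_tracks(10.0, 2.0, 5, 1, 0.0, rod_geometry)


class TestRenderSpotMovie:
    def test_empty_trackset_gives_flat_background(self):
        from murodyn.containers import TrackSet

        movie = synthetic.render_spot_movie(
            TrackSet(tracks=[]), background=100.0, noise_model="none", shape=(3, 16, 16)
        )
        assert np.all(movie.pixels == 100.0)

    def test_static_spot_peak_at_integer_pixel(self):
        from murodyn.containers import Track, TrackSet

        px = 0.065
        # pixel (7, 9): centre at x=(9+0.5)*px, y=(7+0.5)*px
        t = Track(id=0, frames=[0, 1], positions=[[9.5 * px, 7.5 * px]] * 2)
        movie = synthetic.render_spot_movie(
            TrackSet(tracks=[t], pixel_size=px),
            psf_sigma=1.2,
            amplitude=50.0,
            background=10.0,
            noise_model="none",
            shape=(2, 16, 16),
        )
        frame = movie.pixels[0]
        assert np.unravel_index(np.argmax(frame), frame.shape) == (7, 9)
        assert frame[7, 9] == pytest.approx(60.0, abs=1e-6)

    def test_integrated_signal_matches_gaussian_integral(self):
        from murodyn.containers import Track, TrackSet

        px = 0.065
        sigma, amp = 1.5, 80.0
        t = Track(id=0, frames=[0, 1], positions=[[32.5 * px, 32.5 * px]] * 2)
        movie = synthetic.render_spot_movie(
            TrackSet(tracks=[t], pixel_size=px),
            psf_sigma=sigma,
            amplitude=amp,
            background=5.0,
            noise_model="none",
            shape=(2, 64, 64),
        )
        total = (movie.pixels[0] - 5.0).sum()
        assert total == pytest.approx(2 * np.pi * sigma**2 * amp, rel=0.01)

    def test_poisson_pixel_mean_matches_noiseless(self):
        from murodyn.containers import Track, TrackSet

        px = 0.065
        t = Track(id=0, frames=[0, 1], positions=[[8.0 * px, 8.0 * px]] * 2)
        ts = TrackSet(tracks=[t], pixel_size=px)
        clean = synthetic.render_spot_movie(
            ts, amplitude=40.0, background=20.0, noise_model="none", shape=(1, 16, 16)
        ).pixels[0]
        reps = np.stack(
            [
                synthetic.render_spot_movie(
                    ts,
                    amplitude=40.0,
                    background=20.0,
                    noise_model="poisson",
                    shape=(1, 16, 16),
                    seed=s,
                ).pixels[0]
                for s in range(1000)
            ]
        )
        se = np.sqrt(clean / len(reps))  # Poisson variance = mean
        assert np.all(np.abs(reps.mean(axis=0) - clean) < 4 * se + 1e-9)


class TestGrowthCurve:
    def test_pure_exponential_exact(self):
        times = np.arange(0.0, 120.0, 5.0)
        curve = synthetic.simulate_growth_curve(0.01, 30.0, times=times)
        np.testing.assert_allclose(curve.od, 0.01 * 2 ** (times / 30.0), rtol=1e-12)

    def test_stationary_cap(self):
        times = np.arange(0.0, 600.0, 10.0)
        curve = synthetic.simulate_growth_curve(0.01, 20.0, stationary_od=0.5, times=times)
        assert curve.od[-1] == 0.5

    def test_lag_phase_constant(self):
        times = np.arange(0.0, 100.0, 5.0)
        curve = synthetic.simulate_growth_curve(0.02, 30.0, lag=30.0, times=times)
        assert np.all(curve.od[times <= 30.0] == 0.02)

    def test_seed_determinism(self):
        a = synthetic.simulate_growth_curve(0.01, 30.0, noise_sd=0.01, seed=5)
        b = synthetic.simulate_growth_curve(0.01, 30.0, noise_sd=0.01, seed=5)
        np.testing.assert_array_equal(a.od, b.od)


class TestIncorporationSeries:
    def test_starts_at_zero(self):
        s = synthetic.simulate_incorporation_series(100.0, 0.01, 0.023, np.array([0.0, 10.0]))
        assert s.signal[0] == 0.0

    def test_plateau_is_kin_over_gamma_plus_kout(self):
        kin, kout, gamma = 150.0, 0.02, 0.023
        s = synthetic.simulate_incorporation_series(
            kin, kout, gamma, np.array([0.0, 1e5])
        )
        assert s.signal[-1] == pytest.approx(kin / (gamma + kout), rel=1e-9)

    def test_negative_rates_rejected(self):
        with pytest.raises(ParameterError):
            synthetic.simulate_incorporation_series(-1.0, 0.0, 0.02, np.array([0.0]))


class TestShockDimensions:
    def test_zero_sd_short_ratio_exactly_one(self):
        df = synthetic.simulate_shock_dimensions(100, mean_ext_short=1.0, sd=0.0, seed=0)
        np.testing.assert_allclose(df["post_short_um"] / df["pre_short_um"], 1.0, rtol=1e-12)

    def test_zero_sd_long_ratio_exact(self):
        df = synthetic.simulate_shock_dimensions(50, mean_ext_long=1.05, sd=0.0, seed=0)
        np.testing.assert_allclose(df["post_long_um"] / df["pre_long_um"], 1.05, rtol=1e-12)

    def test_ratio_mean_converges(self):
        n = 10**4
        df = synthetic.simulate_shock_dimensions(
            n, mean_ext_short=1.08, sd=0.05, seed=1
        )
        ratios = (df["post_short_um"] / df["pre_short_um"]).to_numpy()
        se = ratios.std() / np.sqrt(n)
        assert abs(ratios.mean() - 1.08) < 3 * se
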