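"""Growth fits, incorporation kinetics, shock statistics, cross-linking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from murodyn import kinetics, synthetic
from murodyn.containers import GrowthCurve, ParameterError
from murodyn.kinetics import KineticFitError, MuropeptideProfile


class TestDoublingTime:
    def test_noiseless_exponential_exact(self):
        times = np.arange(0.0, 200.0, 10.0)
        curve = synthetic.simulate_growth_curve(0.01, 30.0, times=times)
        fit = kinetics.fit_doubling_time(curve)
        assert fit.doubling_time == pytest.approx(30.0, abs=1e-9)

    def test_window_excludes_plateau(self):
        times = np.arange(0.0, 400.0, 10.0)
        curve = synthetic.simulate_growth_curve(0.01, 30.0, stationary_od=0.4, times=times)
        fit = kinetics.fit_doubling_time(curve)
        first_plateau = int(np.argmax(curve.od >= 0.4))
        assert fit.window[1] <= first_plateau + 2
        assert fit.doubling_time == pytest.approx(30.0, rel=0.05)

    def test_perfectly_autocorrelated_residuals_rejected(self):
        # concave (quadratic in log space) curve: residuals trend smoothly,
        # DW stays far below 1 on every window
        times = np.arange(0.0, 120.0, 10.0)
        od = 0.01 * np.exp(0.001 * times**2 / 30)
        with pytest.raises(KineticFitError):
            kinetics.fit_doubling_time(GrowthCurve(times=times, od=od), dw_min=1.9)

    def test_durbin_watson_of_constant_residuals_is_zero(self):
        assert kinetics.durbin_watson(np.full(10, 0.3)) == 0.0

    def test_noisy_recovery_within_two_percent(self):
        """Multiplicative noise (CV 2%): recovered doubling time within
        2% over 20 seeds."""
        times = np.arange(0.0, 300.0, 10.0)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            od = 0.01 * 2 ** (times / 30.0) * np.exp(rng.normal(0, 0.02, len(times)))
            fit = kinetics.fit_doubling_time(GrowthCurve(times=times, od=od))
            errs.append(abs(fit.doubling_time - 30.0) / 30.0)
        assert np.median(errs) < 0.02
        assert max(errs) < 0.05


class TestIncorporation:
    def test_noiseless_roundtrip_recovers_rates(self):
        kin, kout, gamma = 100.0, 0.01, np.log(2) / 30.0
        times = np.arange(0.0, 120.0, 5.0)
        series = synthetic.simulate_incorporation_series(kin, kout, gamma, times, label="c1")
        fit = kinetics.fit_incorporation_model([series])
        assert fit.kin["c1"] == pytest.approx(kin, rel=1e-6)
        assert fit.kout == pytest.approx(kout, rel=1e-6, abs=1e-8)

    def test_zero_turnover_limit(self):
        gamma = np.log(2) / 30.0
        times = np.arange(0.0, 180.0, 5.0)
        series = synthetic.simulate_incorporation_series(80.0, 0.0, gamma, times, label="c")
        fit = kinetics.fit_incorporation_model([series])
        assert fit.kout <= 1e-8
        assert fit.kin["c"] == pytest.approx(80.0, rel=1e-6)

    def test_joint_fit_shares_kout_across_cultures(self):
        gamma = np.log(2) / 25.0
        times = np.arange(0.0, 150.0, 5.0)
        s1 = synthetic.simulate_incorporation_series(120.0, 0.02, gamma, times, label="a")
        s2 = synthetic.simulate_incorporation_series(60.0, 0.02, gamma * 1.2, times, label="b")
        fit = kinetics.fit_incorporation_model([s1, s2])
        assert fit.kin["a"] == pytest.approx(120.0, rel=1e-5)
        assert fit.kin["b"] == pytest.approx(60.0, rel=1e-5)
        assert fit.kout == pytest.approx(0.02, rel=1e-4)

    def test_poisson_noise_recovery(self):
        """Counting noise at plateau ~1e4: kin within 5%, kout within
        15% (median over 20 seeds)."""
        gamma = np.log(2) / 30.0
        kout = gamma / 5.0
        kin = 1e4 * (gamma + kout)  # plateau 1e4 counts
        times = np.arange(0.0, 240.0, 10.0)
        kin_errs, kout_errs = [], []
        for seed in range(20):
            series = synthetic.simulate_incorporation_series(
                kin, kout, gamma, times, noise_model="poisson", seed=seed, label="c"
            )
            fit = kinetics.fit_incorporation_model([series])
            kin_errs.append(abs(fit.kin["c"] - kin) / kin)
            kout_errs.append(abs(fit.kout - kout) / kout)
        assert np.median(kin_errs) < 0.05
        assert np.median(kout_errs) < 0.15


class TestShockExtension:
    def test_no_change_gives_ratio_one(self):
        df = synthetic.simulate_shock_dimensions(20, 1.0, 1.0, sd=0.0, seed=0)
        ratios = kinetics.shock_extension(df)
        np.testing.assert_allclose(ratios["short_ratio"], 1.0, rtol=1e-12)
        np.testing.assert_allclose(ratios["long_ratio"], 1.0, rtol=1e-12)

    def test_five_percent_extension(self):
        df = synthetic.simulate_shock_dimensions(10, 1.05, 1.0, sd=0.0, seed=0)
        ratios = kinetics.shock_extension(df)
        np.testing.assert_allclose(ratios["short_ratio"], 1.05, rtol=1e-12)

    def test_incomplete_rows_dropped(self):
        df = synthetic.simulate_shock_dimensions(5, 1.05, 1.02, sd=0.01, seed=1)
        df.loc[2, "post_short_um"] = np.nan
        ratios = kinetics.shock_extension(df)
        assert len(ratios) == 4
        assert ratios.attrs["n_dropped"] == 1


class TestPermutationTest:
    def test_identical_groups_p_one(self):
        p = kinetics.permutation_test_median_diff([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_separated_groups_exhaustive(self):
        """Brute-force enumeration over all 70 splits of {1..4} vs
        {10..13}: four splits tie the observed statistic (the original
        labeling, its mirror, and the {1,2,3,10}-type swaps), so
        p = 4/70."""
        p = kinetics.permutation_test_median_diff([1, 2, 3, 4], [10, 11, 12, 13])
        assert p == pytest.approx(4 / 70, abs=1e-12)

    def test_monte_carlo_agrees_with_exhaustive(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.8, 1, 6)
        p_ex = kinetics.permutation_test_median_diff(a, b)
        n_perm = 10**4
        p_mc = kinetics.permutation_test_median_diff(
            a, b, n_perm=n_perm, seed=2, exhaustive_limit=1
        )
        se = np.sqrt(p_ex * (1 - p_ex) / n_perm)
        assert abs(p_mc - p_ex) < 3 * se + 2 / n_perm

    def test_type_i_error_calibrated_under_null(self):
        """Exhaustive mode, n = 6 + 6: rejection rate at alpha = 0.05 is
        0.05 within 3 binomial SE over 2000 null datasets."""
        rng = np.random.default_rng(77)
        n_data = 2000
        rejections = 0
        for _ in range(n_data):
            x = rng.normal(size=12)
            p = kinetics.permutation_test_median_diff(x[:6], x[6:])
            rejections += p <= 0.05
        rate = rejections / n_data
        se = np.sqrt(0.05 * 0.95 / n_data)
        assert abs(rate - 0.05) < 3 * se

    def test_small_n_perm_rejected(self):
        with pytest.raises(ParameterError):
            kinetics.permutation_test_median_diff(
                [1, 2], [3, 4], n_perm=50, exhaustive_limit=1
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            kinetics.permutation_test_median_diff([], [1.0])


class TestCrosslink:
    def test_all_monomers_zero(self):
        p, clipped = kinetics.crosslink_percentage(
            MuropeptideProfile(monomers=1.0, dimers=0.0, trimers=0.0)
        )
        assert p == 0.0 and not clipped

    def test_dimers_only(self):
        p, _ = kinetics.crosslink_percentage(
            MuropeptideProfile(monomers=0.55, dimers=0.45, trimers=0.0)
        )
        assert p == pytest.approx(45.0)

    def test_dimers_and_trimers(self):
        p, _ = kinetics.crosslink_percentage(
            MuropeptideProfile(monomers=0.65, dimers=0.30, trimers=0.05)
        )
        assert p == pytest.approx(40.0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ParameterError):
            MuropeptideProfile(monomers=0.5, dimers=0.2, trimers=0.0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    dimers=st.floats(min_value=0, max_value=0.5),
    trimers=st.floats(min_value=0, max_value=0.25),
)
def test_crosslink_linear_and_bounded(dimers, trimers):
    rest = 1.0 - dimers - trimers
    p, clipped = kinetics.crosslink_percentage(
        MuropeptideProfile(monomers=rest, dimers=dimers, trimers=trimers)
    )
    assert p == pytest.approx(100 * dimers + 200 * trimers, abs=1e-9)
    assert 0.0 <= p <= 100.0 or clipped


class TestNormalizeOdAtEvent:
    def test_identical_curves_unchanged(self):
        times = np.arange(0.0, 100.0, 10.0)
        a = synthetic.simulate_growth_curve(0.01, 30.0, times=times)
        b = synthetic.simulate_growth_curve(0.01, 30.0, times=times)
        out = kinetics.normalize_od_at_event([a, b], event_time=50.0)
        np.testing.assert_allclose(out[0].od, a.od, rtol=1e-12)

    def test_scaled_curve_matches_at_event(self):
        times = np.arange(0.0, 100.0, 10.0)
        a = synthetic.simulate_growth_curve(0.01, 30.0, times=times)
        b = GrowthCurve(times=times, od=2 * a.od)
        out = kinetics.normalize_od_at_event([a, b], event_time=60.0)
        va = np.interp(60.0, out[0].times, out[0].od)
        vb = np.interp(60.0, out[1].times, out[1].od)
        assert va == pytest.approx(vb, rel=1e-12)

    def test_scaling_preserves_doubling_time(self):
        times = np.arange(0.0, 200.0, 10.0)
        a = synthetic.simulate_growth_curve(0.01, 30.0, times=times)
        b = GrowthCurve(times=times, od=3 * a.od)
        out = kinetics.normalize_od_at_event([a, b], event_time=100.0)
        for c in out:
            fit = kinetics.fit_doubling_time(c)
            assert fit.doubling_time == pytest.approx(30.0, abs=1e-9)

    def test_event_outside_range_rejected(self):
        a = synthetic.simulate_growth_curve(0.01, 30.0, times=np.arange(0.0, 50.0, 10.0))
        with pytest.raises(ParameterError):
            kinetics.normalize_od_at_event([a], event_time=500.0)
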