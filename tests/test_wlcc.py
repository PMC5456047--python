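"""Windowed lagged cross-correlation: oracle equality and invariants."""

import numpy as np
import pytest

from dyadsync.core import (CoverageError, InputError, ParameterError,
                           RateMismatchError, UniformSeries)
from dyadsync.simulate import MovementSimParams, generate_movement_pair
from dyadsync.wlcc import (LagProfile, WlccParams, lag_bin_features,
                           lag_profile, summarize)
from oracles import wlcc_oracle


def smooth_series(rng, n=240, rate=6.0):
    x = np.cumsum(rng.normal(size=n))
    return UniformSeries(x, rate)


PARAMS = WlccParams()


class TestLagProfile:
    def test_self_pair_correlates_perfectly_at_lag_zero(self, rng):
        s = smooth_series(rng)
        prof = lag_profile(s, s, PARAMS)
        zero = np.flatnonzero(np.isclose(prof.lags_s, 0.0))[0]
        np.testing.assert_allclose(prof.r_by_window[:, zero], 1.0, atol=1e-12)
        assert prof.r_mean[zero] == pytest.approx(1.0)

    def test_constructed_shift_peaks_at_667_ms(self, rng):
        x = smooth_series(rng, n=400).values
        naive = UniformSeries(x, 6.0)
        da = UniformSeries(np.concatenate([np.zeros(4), x[:-4]]), 6.0)
        prof = lag_profile(da, naive, PARAMS)
        assert prof.argmax_lag_s() == pytest.approx(4 / 6)

    def test_every_window_matches_direct_pearson(self, rng):
        for _ in range(5):
            x = UniformSeries(rng.normal(size=200), 6.0)
            y = UniformSeries(rng.normal(size=200), 6.0)
            prof = lag_profile(x, y, PARAMS)
            expected = wlcc_oracle(x.values, y.values, window=60, step=60,
                                   max_lag=30, min_fraction=0.8)
            np.testing.assert_allclose(prof.r_by_window, expected,
                                       atol=1e-10, equal_nan=True)

    def test_swapping_series_mirrors_the_profile(self, rng):
        # use windows covering the series fully so truncation is symmetric
        x = UniformSeries(rng.normal(size=120), 6.0)
        y = UniformSeries(rng.normal(size=120), 6.0)
        p = WlccParams(window_s=20.0, window_step_s=20.0, max_lag_s=2.0,
                       min_window_fraction=0.5)
        ab = lag_profile(x, y, p)
        ba = lag_profile(y, x, p)
        np.testing.assert_allclose(ab.r_mean, ba.r_mean[::-1], atol=1e-10,
                                   equal_nan=True)

    def test_affine_transform_leaves_r_unchanged(self, rng):
        x = UniformSeries(rng.normal(size=240), 6.0)
        y = UniformSeries(rng.normal(size=240), 6.0)
        y2 = UniformSeries(3.5 * y.values - 11.0, 6.0)
        np.testing.assert_allclose(lag_profile(x, y, PARAMS).r_mean,
                                   lag_profile(x, y2, PARAMS).r_mean,
                                   atol=1e-10, equal_nan=True)

    def test_independent_white_noise_stays_inside_permutation_band(self, rng):
        x = UniformSeries(rng.normal(size=480 * 6), 6.0)
        y = UniformSeries(rng.normal(size=480 * 6), 6.0)
        observed = np.nanmax(np.abs(lag_profile(x, y, PARAMS).r_mean))
        # permutation null of the same statistic: shuffle one series
        null_max = [np.nanmax(np.abs(lag_profile(
            x, UniformSeries(rng.permutation(y.values), 6.0), PARAMS).r_mean))
            for _ in range(100)]
        assert observed <= np.percentile(null_max, 95)

    def test_rate_mismatch_and_short_span_raise(self, rng):
        a = UniformSeries(rng.normal(size=100), 6.0)
        with pytest.raises(RateMismatchError):
            lag_profile(a, UniformSeries(rng.normal(size=100), 3.0), PARAMS)
        with pytest.raises(InputError):
            lag_profile(UniformSeries(rng.normal(size=30), 6.0),
                        UniformSeries(rng.normal(size=30), 6.0), PARAMS)

    def test_lag_step_must_match_sample_period(self, rng):
        a = UniformSeries(rng.normal(size=100), 3.0)
        with pytest.raises(ParameterError):
            lag_profile(a, a, WlccParams(lag_step_s=1.0 / 6.0))


def profile_from_rmean(r_mean, rate=6.0):
    lags = np.arange(-len(r_mean) // 2 + 1, len(r_mean) // 2 + 1)
    return LagProfile(lags_s=lags / rate, r_by_window=r_mean[None, :],
                      r_mean=np.asarray(r_mean, float), rate_hz=rate)


class TestSummaries:
    def test_constant_profile_summarizes_to_the_constant(self):
        prof = profile_from_rmean(np.full(61, 0.37))
        s = summarize(prof)
        assert s.lag0 == pytest.approx(0.37)
        assert s.da_follows_1000 == pytest.approx(0.37)
        assert s.naive_follows_1000 == pytest.approx(0.37)

    def test_single_spike_at_667_ms_spreads_over_five_lags(self):
        r = np.zeros(61)
        r[30 + 4] = 0.6  # +4 samples = 667 ms
        s = summarize(profile_from_rmean(r))
        assert s.da_follows_1000 == pytest.approx(0.6 / 5)
        assert s.lag0 == pytest.approx(0.0)
        assert s.naive_follows_1000 == pytest.approx(0.0)

    def test_symmetric_profile_balances_followers(self, rng):
        half = rng.normal(size=30)
        r = np.concatenate([half[::-1], [rng.normal()], half])
        s = summarize(profile_from_rmean(r))
        assert s.da_follows_1000 == pytest.approx(s.naive_follows_1000)

    def test_insufficient_lag_coverage_raises(self):
        prof = profile_from_rmean(np.zeros(7))  # +/- 3 samples = 500 ms only
        with pytest.raises(CoverageError):
            summarize(prof)

    def test_missing_lag_mean_propagates_to_summary(self):
        r = np.full(61, 0.2)
        r[30] = np.nan
        assert np.isnan(summarize(profile_from_rmean(r)).lag0)


class TestLagBins:
    def test_seven_bins_cover_the_native_grid(self):
        r = np.arange(61, dtype=float) / 100
        prof = profile_from_rmean(r)
        bins = lag_bin_features(prof)
        assert sorted(bins) == [-3, -2, -1, 0, 1, 2, 3]
        ell = np.round(prof.lags_s * 6).astype(int)
        np.testing.assert_allclose(bins[0], r[np.abs(ell) <= 1].mean())
        np.testing.assert_allclose(bins[2], r[(ell >= 7) & (ell <= 12)].mean())
        np.testing.assert_allclose(bins[-3], r[(ell <= -13) & (ell >= -18)].mean())

    def test_bin_means_equal_brute_force_on_simulated_profile(self, rng):
        naive, da = generate_movement_pair(
            MovementSimParams(duration_s=120, seed=4))
        prof = lag_profile(da, naive, PARAMS)
        bins = lag_bin_features(prof)
        ell = np.round(prof.lags_s * 6).astype(int)
        for b in range(1, 4):
            lo, hi = max(2, (b - 1) * 6 + 1), b * 6
            manual = prof.r_mean[(ell >= lo) & (ell <= hi)].mean()
            assert bins[b] == pytest.approx(manual)
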