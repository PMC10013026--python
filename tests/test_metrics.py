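"""Interdaily stability, intradaily variability, cosinor, profiles, windows."""

import numpy as np
import pytest

from circastrain.metrics import (cosinor_fit, group_profile, individual_profile,
                                 interdaily_stability, intradaily_variability,
                                 window_median, zeitgeber_strength)
from conftest import make_window


def _oracle_is(X):
    """Brute-force double-sum evaluation of the IS variance ratio."""
    D, P = X.shape
    obs = [(d, b) for d in range(D) for b in range(P) if np.isfinite(X[d, b])]
    n = len(obs)
    grand = sum(X[d, b] for d, b in obs) / n
    num = 0.0
    for b in range(P):
        col = [X[d, b] for d in range(D) if np.isfinite(X[d, b])]
        if col:
            num += (sum(col) / len(col) - grand) ** 2
    den = sum((X[d, b] - grand) ** 2 for d, b in obs)
    return n * num / (P * den)


def _oracle_iv(s):
    obs = [v for v in s if np.isfinite(v)]
    n = len(obs)
    mean = sum(obs) / n
    den = sum((v - mean) ** 2 for v in obs)
    num = sum((s[i] - s[i - 1]) ** 2 for i in range(1, len(s))
              if np.isfinite(s[i]) and np.isfinite(s[i - 1]))
    return n * num / ((n - 1) * den)


class TestInterdailyStability:
    def test_perfectly_repeating_day_is_one(self, rng):
        day = rng.uniform(0, 100, 144)
        window = make_window(np.tile(day, (7, 1)))
        is_raw, is_scaled = interdaily_stability(window)
        assert is_raw == pytest.approx(1.0)
        assert is_scaled == pytest.approx(100.0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            interdaily_stability(make_window(np.full((3, 144), 7.0)))

    def test_two_day_toy_matches_double_sum_oracle(self):
        X = np.array([[1.0, 5.0, 1.0, 5.0], [3.0, 7.0, 3.0, 7.0]])
        is_raw, _ = interdaily_stability(make_window(X))
        assert is_raw == pytest.approx(_oracle_is(X), rel=1e-12)

    def test_missing_bins_match_oracle(self, rng):
        X = rng.uniform(0, 10, (4, 24))
        X[rng.random((4, 24)) < 0.2] = np.nan
        is_raw, _ = interdaily_stability(make_window(X))
        assert is_raw == pytest.approx(_oracle_is(X), rel=1e-9)

    def test_affine_invariance(self, rng):
        X = rng.uniform(0, 10, (3, 48))
        base, _ = interdaily_stability(make_window(X))
        scaled, _ = interdaily_stability(make_window(3.5 * X + 11.0))
        assert scaled == pytest.approx(base, rel=1e-9)


class TestIntradailyVariability:
    def test_alternating_series_is_four(self):
        X = np.tile([2.0, 8.0], (2, 72))  # strictly alternating, even length
        assert intradaily_variability(make_window(X)) == pytest.approx(4.0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            intradaily_variability(make_window(np.full((2, 144), 3.0)))

    def test_iid_noise_near_two(self, rng):
        X = rng.normal(size=(70, 144))  # N = 10,080
        iv = intradaily_variability(make_window(X))
        assert 1.9 <= iv <= 2.1

    def test_missing_pairs_dropped_matches_oracle(self, rng):
        X = rng.uniform(0, 10, (3, 48))
        X[rng.random((3, 48)) < 0.15] = np.nan
        got = intradaily_variability(make_window(X))
        assert got == pytest.approx(_oracle_iv(X.ravel()), rel=1e-9)

    def test_affine_invariance(self, rng):
        X = rng.uniform(0, 10, (2, 144))
        base = intradaily_variability(make_window(X))
        scaled = intradaily_variability(make_window(0.25 * X + 3.0))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_day_boundaries_are_not_breaks(self, rng):
        # IV over 2 days equals IV of the same 288-bin continuous series
        X = rng.uniform(0, 10, (2, 144))
        got = intradaily_variability(make_window(X))
        flat = intradaily_variability(make_window(X.reshape(1, 288),
                                                  epoch_minutes=5))
        assert got == pytest.approx(flat, rel=1e-12)


def _grid_search_acrophase(t, y, period=24.0):
    """Dense brute-force search over (acrophase, amplitude) pairs."""
    best, best_sse = None, np.inf
    for phi in np.arange(0, period, 0.02):
        c = np.cos(2 * np.pi * (t - phi) / period)
        A = np.column_stack([np.ones_like(t), c])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = np.sum((y - A @ coef) ** 2)
        if sse < best_sse and coef[1] >= 0:
            best, best_sse = phi, sse
    return best


class TestCosinor:
    def test_pure_cosine_recovered_exactly(self):
        t = np.arange(7 * 144) * 10.0 / 60.0
        y = 100 + 50 * np.cos(2 * np.pi * (t - 15.0) / 24.0)
        fit = cosinor_fit(make_window(y.reshape(7, 144)))
        assert fit.mesor == pytest.approx(100.0)
        assert fit.amplitude == pytest.approx(50.0)
        assert fit.acrophase_hours == pytest.approx(15.0)

    def test_constant_input_flagged(self):
        fit = cosinor_fit(make_window(np.full((2, 144), 7.3)))
        assert fit.mesor == 7.3 and fit.amplitude == 0.0
        assert not fit.acrophase_defined

    def test_noisy_cosine_matches_grid_search_oracle(self, rng):
        t = np.arange(7 * 144) * 10.0 / 60.0
        y = 10 + 4 * np.cos(2 * np.pi * (t - 9.5) / 24.0) + rng.normal(0, 1, t.size)
        fit = cosinor_fit(make_window(y.reshape(7, 144)))
        oracle = _grid_search_acrophase(t, y)
        assert abs(fit.acrophase_hours - oracle) < 0.1

    def test_rank_deficient_design_rejected(self):
        # observations at a single clock time only
        X = np.full((3, 144), np.nan)
        X[:, 60] = [1.0, 2.0, 3.0]
        with pytest.raises(ValueError, match="rank-deficient"):
            cosinor_fit(make_window(X))

    def test_acrophase_equivariant_under_circular_shift(self, rng):
        day = 50 + 30 * np.cos(2 * np.pi * (np.arange(144) / 6.0 - 14.0) / 24.0) \
            + rng.normal(0, 2, 144)
        X = np.tile(day, (7, 1))
        base = cosinor_fit(make_window(X)).acrophase_hours
        shift_bins = 18  # +3 h
        shifted = cosinor_fit(make_window(np.roll(X, shift_bins, axis=1))).acrophase_hours
        assert shifted == pytest.approx((base + 3.0) % 24.0, abs=1e-6)

    def test_amplitude_bounded_by_range(self):
        t = np.arange(2 * 144) / 6.0
        y = 5 + 2 * np.cos(2 * np.pi * t / 24.0)
        fit = cosinor_fit(make_window(y.reshape(2, 144)))
        assert fit.amplitude <= (y.max() - y.min()) + 1e-9

    def test_mask_and_sentinel_missing_equivalent(self, rng):
        from circastrain.actigraphy import ActimetryRecording, exclude_days
        from conftest import MIDNIGHT

        vals = rng.uniform(0, 10, 288)
        miss = rng.random(288) < 0.2
        as_nan = np.where(miss, np.nan, vals)
        r_nan = ActimetryRecording("T0", "A", "activity", MIDNIGHT, 10.0, as_nan)
        # same data, missingness encoded only via the mask (values left in)
        r_mask = ActimetryRecording("T0", "A", "activity", MIDNIGHT, 10.0,
                                    vals.copy(), missing=miss)
        w1 = exclude_days(r_nan, max_missing_hours=24.0)
        w2 = exclude_days(r_mask, max_missing_hours=24.0)
        assert intradaily_variability(w1) == pytest.approx(
            intradaily_variability(w2), rel=1e-12)
        assert interdaily_stability(w1)[0] == pytest.approx(
            interdaily_stability(w2)[0], rel=1e-12)
        assert cosinor_fit(w1).acrophase_hours == pytest.approx(
            cosinor_fit(w2).acrophase_hours, rel=1e-12)


class TestProfiles:
    def test_single_day_profile_is_that_day(self, rng):
        day = rng.uniform(0, 10, 144)
        prof = individual_profile(make_window(day.reshape(1, 144)))
        np.testing.assert_allclose(prof.values, day)

    def test_two_day_median_is_midpoint(self):
        X = np.vstack([np.full(144, 100.0), np.full(144, 300.0)])
        prof = individual_profile(make_window(X))
        assert set(prof.values.tolist()) == {200.0}

    def test_profile_matches_sort_and_pick_oracle(self, rng):
        X = rng.uniform(0, 50, (7, 144))
        prof = individual_profile(make_window(X))
        for b in range(0, 144, 17):
            col = sorted(X[:, b])
            assert prof.values[b] == pytest.approx(col[3])  # odd count median

    def test_group_of_identical_profiles_has_zero_iqr(self, rng):
        day = rng.uniform(0, 10, 144)
        profs = [individual_profile(make_window(day.reshape(1, 144)))
                 for _ in range(4)]
        grp = group_profile(profs)
        np.testing.assert_allclose(grp.values, day)
        np.testing.assert_allclose(grp.q3 - grp.q1, 0.0)

    def test_two_subject_median_uses_midpoint_convention(self):
        p1 = individual_profile(make_window(np.full((1, 144), 10.0)))
        p2 = individual_profile(make_window(np.full((1, 144), 20.0)))
        grp = group_profile([p1, p2])
        assert set(grp.values.tolist()) == {15.0}

    def test_five_subject_group_matches_quantile_oracle(self, rng):
        days = [rng.uniform(0, 10, 144) for _ in range(5)]
        profs = [individual_profile(make_window(d.reshape(1, 144))) for d in days]
        grp = group_profile(profs)
        stack = np.vstack(days)
        np.testing.assert_allclose(grp.values, np.percentile(stack, 50, axis=0))
        np.testing.assert_allclose(grp.q1, np.percentile(stack, 25, axis=0))
        np.testing.assert_allclose(grp.q3, np.percentile(stack, 75, axis=0))


class TestClockWindows:
    def test_constant_light_every_window(self):
        w = make_window(np.full((2, 144), 1000.0), channel="light")
        for cw in [(7, 17), (8, 10), (13, 15), (20, 25)]:
            assert window_median(w, cw) == pytest.approx(1000.0)

    def test_night_window_spans_thirty_bins_per_day(self):
        # mark the bins whose start lies in [20:00, 1:00) and count them
        day = np.zeros(144)
        w = make_window(day.reshape(1, 144) + np.arange(144), channel="light")
        clock = np.arange(144) / 6.0
        in_window = ((clock - 20.0) % 24.0) < 5.0
        assert in_window.sum() == 30
        vals = np.arange(144.0)[in_window]
        assert window_median(w, (20, 25)) == pytest.approx(np.median(vals))

    def test_stepped_day_matches_selection_oracle(self, rng):
        X = rng.uniform(0, 100, (3, 144))
        w = make_window(X, channel="light")
        clock = np.arange(144) / 6.0
        sel = (clock >= 8) & (clock < 10)
        assert window_median(w, (8, 10)) == pytest.approx(np.median(X[:, sel]))

    def test_empty_window_is_nan_with_warning(self):
        X = np.full((1, 144), np.nan)
        X[0, :6] = 1.0
        w = make_window(X, channel="light")
        with pytest.warns(UserWarning, match="no observed bins"):
            assert np.isnan(window_median(w, (8, 10)))


class TestZeitgeberStrength:
    def test_bright_morning_dim_evening(self):
        clock = np.arange(144) / 6.0
        day = np.where((clock >= 6) & (clock < 18), 1000.0, 10.0)
        w = make_window(np.tile(day, (2, 1)), channel="light")
        assert zeitgeber_strength(w) == pytest.approx(100.0)

    def test_flat_light_gives_unity(self):
        w = make_window(np.full((2, 144), 250.0), channel="light")
        assert zeitgeber_strength(w) == pytest.approx(1.0)

    def test_zero_evening_flagged_not_infinite(self):
        clock = np.arange(144) / 6.0
        day = np.where((clock >= 6) & (clock < 18), 1000.0, 0.0)
        w = make_window(np.tile(day, (2, 1)), channel="light")
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(zeitgeber_strength(w))

    def test_composition_with_window_median(self, rng):
        X = rng.uniform(1, 500, (3, 144))
        w = make_window(X, channel="light")
        expected = window_median(w, (8, 10)) / window_median(w, (20, 25))
        assert zeitgeber_strength(w) == pytest.approx(expected, rel=1e-12)
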