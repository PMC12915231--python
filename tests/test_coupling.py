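"""Coupling statistics: correlation, phase lag, amplitudes, sum-dFF QC."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from fipcouple import (
    cross_correlogram,
    peak_amplitude,
    phase_lag,
    plateau_amplitude,
    sliding_correlation,
    static_correlation,
    sum_dff,
    trial_coupling,
)
from fipcouple.coupling import DegenerateTraceError

FS = 40.0


def _smooth(n, seed, sigma=4.0):
    return gaussian_filter1d(np.random.default_rng(seed).standard_normal(n), sigma)


def oracle_phase_lag(a, b, fs, max_lag):
    """Independent exhaustive lag scan using scipy.stats.pearsonr."""
    L = round(max_lag * fs)
    best = (np.inf, np.inf, -np.inf)  # (|tau|, tau, |r|) with custom order
    best_tau = None
    for k in sorted(range(-L, L + 1), key=lambda k: (abs(k), k)):
        if k > 0:
            aa, bb = a[k:], b[: a.size - k]
        elif k < 0:
            aa, bb = a[: a.size + k], b[-k:]
        else:
            aa, bb = a, b
        if aa.std() == 0 or bb.std() == 0:
            continue
        r = abs(pearsonr(aa, bb).statistic)
        if best_tau is None or r > best[2]:
            best = (abs(k), k, r)
            best_tau = k
    return best_tau / fs


class TestStaticCorrelation:
    def test_identical_traces_r_one(self, smooth_pair):
        a, b = smooth_pair
        assert static_correlation(a, b, FS, "digging") == pytest.approx(1.0)

    def test_negated_trace_r_minus_one(self, smooth_pair):
        a, _ = smooth_pair
        assert static_correlation(a, -a, FS, "digging") == pytest.approx(-1.0)

    def test_affine_invariance_exact(self, smooth_pair):
        a, _ = smooth_pair
        b = _smooth(a.size, seed=5)
        r0 = static_correlation(a, b, FS, "turning", filtered=True)
        r1 = static_correlation(3.5 * a + 2.0, 0.25 * b - 7.0, FS, "turning",
                                filtered=True)
        assert r1 == pytest.approx(r0, abs=1e-12)
        # and through the filtering path (linear, so still invariant)
        r2 = static_correlation(3.5 * a + 2.0, 0.25 * b - 7.0, FS, "turning")
        assert r2 == pytest.approx(static_correlation(a, b, FS, "turning"), abs=1e-9)

    def test_trim_applied_only_for_digging_licking(self, smooth_pair):
        a, _ = smooth_pair
        b = _smooth(a.size, seed=6)
        # corrupt the first second: changes r only when edges are kept
        b2 = b.copy()
        b2[:40] += 5.0
        r_turn = static_correlation(a, b2, FS, "turning", filtered=True)
        r_dig = static_correlation(a, b2, FS, "digging", filtered=True)
        r_ref = static_correlation(a, b, FS, "digging", filtered=True)
        assert r_dig == pytest.approx(r_ref)
        assert r_turn != pytest.approx(r_ref)

    def test_zero_variance_excluded(self, smooth_pair):
        a, _ = smooth_pair
        with pytest.raises(DegenerateTraceError):
            static_correlation(a, np.zeros_like(a), FS, "turning", filtered=True)

    def test_population_correlation_recovered(self):
        """Mean trial r recovers the generating population correlation."""
        from fipcouple import simulate_correlated_pair

        rho = 0.6
        rs = [static_correlation(*simulate_correlated_pair(rho, 400, seed=s),
                                 FS, "digging") for s in range(200)]
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert np.mean(rs) == pytest.approx(rho, abs=3 * se)


class TestSlidingCorrelation:
    @pytest.mark.parametrize("T,expected", [(4, 1), (6, 5), (10, 13), (30, 53)])
    def test_window_count(self, T, expected):
        n = round(T * FS)
        a, b = _smooth(n, 1, 2.0), _smooth(n, 2, 2.0)
        assert sliding_correlation(a, b, FS).shape[0] == expected

    def test_identical_traces_all_one(self):
        a = _smooth(400, 3)
        r = sliding_correlation(a, a.copy(), FS)[:, 1]
        np.testing.assert_allclose(r, 1.0)

    def test_full_epoch_window_equals_static(self):
        a, b = _smooth(400, 4), _smooth(400, 5)
        rows = sliding_correlation(a, b, FS, window=10.0)
        assert rows.shape[0] == 1
        assert rows[0, 1] == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_short_trace_empty_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = sliding_correlation(np.zeros(100), np.zeros(100), FS)
        assert out.shape == (0, 2)


class TestPhaseLag:
    def test_identical_traces_zero_lag(self):
        a = _smooth(400, 8)
        assert phase_lag(a, a.copy(), FS) == 0.0

    def test_pure_shift_sign_convention(self):
        # dff_b(t) = dff_a(t - 0.25 s): A precedes B -> tau = -0.25 s
        a = _smooth(2000, 9)
        k = 10
        b = np.roll(a, k)
        assert phase_lag(a[100:-100], b[100:-100], FS) == pytest.approx(-0.25)

    def test_b_leading_positive_lag(self):
        a = _smooth(2000, 10)
        b = np.roll(a, -10)  # b(t) = a(t + 0.25): B precedes A
        assert phase_lag(a[100:-100], b[100:-100], FS) == pytest.approx(+0.25)

    def test_anticorrelated_shift_found_via_absolute_value(self):
        a = _smooth(2000, 11)
        b = -np.roll(a, 4)
        assert phase_lag(a[100:-100], b[100:-100], FS) == pytest.approx(-0.1)

    def test_max_lag_bound_enforced(self):
        a = _smooth(400, 12)
        for lag in np.linspace(-2, 2, 9):
            assert abs(phase_lag(a, np.roll(a, 3), FS, max_lag=2.0)) <= 2.0
        with pytest.raises(ValueError):
            phase_lag(a, a, FS, max_lag=6.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracle(self, seed):
        """Argmax agrees exactly with an independent exhaustive scan."""
        rng = np.random.default_rng(seed)
        a = gaussian_filter1d(rng.standard_normal(600), rng.uniform(2, 8))
        b = gaussian_filter1d(rng.standard_normal(600), rng.uniform(2, 8)) \
            + 0.5 * np.roll(a, rng.integers(-30, 30))
        assert phase_lag(a, b, FS) == oracle_phase_lag(a, b, FS, 2.0)


class TestCrossCorrelogram:
    def test_zero_lag_equals_static_pearson(self):
        a, b = _smooth(600, 13), _smooth(600, 14)
        lags, c = cross_correlogram(a, b, FS)
        i0 = np.argwhere(lags == 0).item()
        assert c[i0] == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_autocorrelation_symmetric(self):
        a = _smooth(600, 15)
        lags, c = cross_correlogram(a, a.copy(), FS)
        np.testing.assert_allclose(c, c[::-1], atol=1e-12)

    def test_bounded_in_unit_interval(self):
        a, b = _smooth(600, 16), _smooth(600, 17)
        _, c = cross_correlogram(a, b, FS)
        assert np.nanmax(np.abs(c)) <= 1.0 + 1e-12

    def test_white_noise_null_level(self):
        rng = np.random.default_rng(18)
        _, c = cross_correlogram(rng.standard_normal(10_000),
                                 rng.standard_normal(10_000), FS)
        assert np.nanmax(np.abs(c)) < 0.05


class TestAmplitudes:
    def test_constant_plateau(self):
        dff = np.full(400, 0.3)
        assert plateau_amplitude(dff, FS) == pytest.approx(0.3)

    def test_ramp_closed_form(self):
        # linear ramp 0 -> 1 over a [0, 5] s window; mean over [1, 2) s
        n = 200
        dff = np.arange(n) / n
        expected = np.mean(np.arange(40, 80)) / n  # arithmetic-series mean
        assert plateau_amplitude(dff, FS, window_start=0.0) == pytest.approx(expected)
        assert plateau_amplitude(dff, FS, window_start=0.0) == pytest.approx(0.3, abs=0.01)

    def test_constant_peak(self):
        assert peak_amplitude(np.full(400, 0.2), FS) == pytest.approx(0.2)

    def test_impulse_peak_single_sample(self):
        dff = np.zeros(400)
        dff[200 + 10] = 1.0  # t = +0.25 s in a (-5, 5) window
        assert peak_amplitude(dff, FS) == pytest.approx(1.0 / 20.0)

    def test_zero_trace(self):
        assert peak_amplitude(np.zeros(400), FS) == 0.0

    def test_window_too_short(self):
        with pytest.raises(ValueError):
            plateau_amplitude(np.zeros(40), FS, window_start=-5.0)

    def test_synthetic_plateau_recovery(self, default_session):
        from fipcouple import extract_trial

        session, events, truth = default_session
        vals = []
        for ev in events:
            tw = extract_trial(session, ev.onset, "region_a_raw",
                               "region_b_raw", "digging")
            vals.append(plateau_amplitude(tw.dff_a, FS))
        assert np.mean(vals) == pytest.approx(truth.true_plateau[0], abs=0.01)


class TestSumDff:
    def test_constant_bin_excluded(self):
        F = np.concatenate([np.full(320, 10.0), 10.0 + np.arange(320) * 0.01])
        out = sum_dff(F, FS)
        assert out.n_bins == 2
        assert out.n_excluded_bins == 1
        assert out.excluded_bins[0][0] == 0

    def test_increasing_bin_retained_r_one(self):
        F = 10.0 + np.arange(320) * 0.01
        out = sum_dff(F, FS)
        assert out.n_excluded_bins == 0
        F0 = np.percentile(F, 20)
        assert out.sum_dff == pytest.approx(np.sum((F - F0) / F0))

    def test_partial_final_bin_dropped(self):
        F = 10.0 + np.arange(900) * 0.01  # 22.5 s -> 2 complete 8 s bins
        assert sum_dff(F, FS).n_bins == 2

    def test_corrupted_bin_excluded_exactly(self):
        """A sign-flipped processed bin fails the dFF-vs-raw QC; others pass."""
        rng = np.random.default_rng(20)
        raw = 10.0 + gaussian_filter1d(rng.standard_normal(5 * 320), 8.0) * 2.0
        processed = raw.copy()
        sl = slice(2 * 320, 3 * 320)
        processed[sl] = 2 * processed[sl].mean() - processed[sl]  # mirror bin 2
        out = sum_dff(processed, FS, raw_reference=raw)
        assert out.n_bins == 5
        assert [b for b, _ in out.excluded_bins] == [2]

    def test_nonpositive_f0_bin_excluded(self):
        F = np.concatenate([np.full(320, -1.0) + np.arange(320) * 1e-4,
                            10.0 + np.arange(320) * 0.01])
        out = sum_dff(F, FS)
        assert out.n_excluded_bins == 1
        assert "F0" in out.excluded_bins[0][1]


class TestTrialCoupling:
    def test_all_metrics_on_synthetic_trial(self, default_session):
        from fipcouple import extract_trial

        session, events, truth = default_session
        tw = extract_trial(session, events[0].onset, "region_a_raw",
                           "region_b_raw", "digging")
        m = trial_coupling(tw.dff_a, tw.dff_b, FS, "digging")
        assert m.correlation == pytest.approx(1.0, abs=1e-6)  # noiseless, shared
        assert m.phase_lag == 0.0
        assert m.plateau_a == pytest.approx(truth.true_plateau[0], abs=0.01)
        assert m.sliding_r.shape[0] == 9  # 8 s trimmed epoch
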