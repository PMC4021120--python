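import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nrffit.events import EventStream
from nrffit.nrf import (Bounds, DEFAULT_PRF_BOUNDS, build_drive,
                        latent_to_natural, natural_to_latent, nrf_weights,
                        tuning_metrics)


def freq_events(freqs):
    freqs = np.asarray(freqs, dtype=float)
    return EventStream(np.arange(freqs.size, dtype=float) * 2.0,
                       np.zeros(freqs.size, dtype=int), freqs)


def lag_events(lags, conds=None):
    lags = np.asarray(lags, dtype=float)
    conds = np.zeros(lags.size, dtype=int) if conds is None else conds
    return EventStream(np.arange(lags.size, dtype=float) * 2.0, conds, lags)


class TestWeights:
    def test_exp_lag_zero_decay_gives_beta(self):
        w = nrf_weights(lag_events([0, 1, 5]), "exp_lag",
                        {"beta": [2.5], "a": [0.0]})
        np.testing.assert_allclose(w, 2.5)

    def test_exp_lag_scalar_value(self):
        w = nrf_weights(lag_events([2.0]), "exp_lag",
                        {"beta": [1.0], "a": [0.5]})
        np.testing.assert_allclose(w, np.exp(-1.0), atol=5e-6)
        assert w[0] == pytest.approx(0.36788, abs=1e-5)

    def test_gaussian_peak_and_one_sigma_point(self):
        ev = freq_events([1000.0, 1500.0])
        w = nrf_weights(ev, "gaussian", {"mu": 1000.0, "sigma": 500.0,
                                         "beta": 1.0})
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(0.60653, abs=1e-5)

    def test_mexican_hat_zero_crossing_at_one_sigma(self):
        ev = freq_events([500.0, 1500.0, 1000.0])
        w = nrf_weights(ev, "mexican_hat", {"mu": 1000.0, "sigma": 500.0,
                                            "beta": 3.0})
        np.testing.assert_allclose(w[:2], 0.0, atol=1e-12)
        assert w[2] == pytest.approx(3.0)

    def test_categorical_maps_condition_betas(self):
        ev = lag_events([0, 0, 0], conds=np.array([0, 2, 1]))
        w = nrf_weights(ev, "categorical", {"beta": [1.0, 2.0, 3.0]})
        np.testing.assert_allclose(w, [1.0, 3.0, 2.0])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            nrf_weights(freq_events([100.0]), "gaussian",
                        {"mu": 100.0, "sigma": 0.0, "beta": 1.0})

    def test_missing_covariates_rejected(self):
        ev = EventStream(np.array([0.0]), np.array([0]))
        with pytest.raises(ValueError):
            nrf_weights(ev, "exp_lag", {"beta": [1.0], "a": [0.1]})

    def test_gaussian_weights_positive_max_at_center(self):
        f = np.linspace(10.0, 8000.0, 301)
        w = nrf_weights(freq_events(f), "gaussian",
                        {"mu": 2000.0, "sigma": 700.0, "beta": 4.0})
        assert np.all(w > 0) and np.all(w <= 4.0)
        assert f[np.argmax(w)] == pytest.approx(2000.0, abs=30.0)

    def test_ricker_shape_integrates_to_zero(self):
        # unit-amplitude Ricker over (-8, 8) sigma units: the positive
        # center cancels the negative surround to ~0 (peak is 1)
        u = np.linspace(-8.0, 8.0, 200_001)
        w = (1 - u ** 2) * np.exp(-0.5 * u ** 2)
        assert abs(np.trapezoid(w, u)) < 1e-6

    def test_mexican_hat_is_negative_gaussian_second_derivative(self):
        # w(u) = -(d^2/du^2) exp(-u^2/2), checked by central differences
        u = np.linspace(-4.0, 4.0, 81)
        h = 1e-4
        g = lambda x: np.exp(-0.5 * x ** 2)
        d2 = (g(u + h) - 2 * g(u) + g(u - h)) / h ** 2
        np.testing.assert_allclose((1 - u ** 2) * g(u), -d2, atol=1e-6)


class TestLatentTransform:
    def test_midpoint(self):
        assert latent_to_natural(0.0, Bounds(0.0, 20000.0)) == \
            pytest.approx(10000.0)
        assert latent_to_natural(0.0, Bounds(1.0, 5000.0)) == \
            pytest.approx(2500.5)

    def test_asymptotes_never_attained(self):
        b = Bounds(0.0, 20.0)
        assert latent_to_natural(8.0, b) < 20.0
        assert latent_to_natural(-8.0, b) > 0.0
        assert latent_to_natural(8.0, b) == pytest.approx(20.0, abs=1e-9)

    def test_strictly_monotone(self):
        b = DEFAULT_PRF_BOUNDS["sigma"]
        x = np.linspace(-5, 5, 101)
        y = latent_to_natural(x, b)
        assert np.all(np.diff(y) > 0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-5.0, 5.0))
    def test_round_trip(self, theta):
        b = Bounds(1.0, 5000.0)
        assert natural_to_latent(latent_to_natural(theta, b), b) == \
            pytest.approx(theta, abs=1e-10)

    def test_nonfinite_latent_rejected(self):
        with pytest.raises(ValueError):
            latent_to_natural(np.nan, Bounds(0.0, 1.0))

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            Bounds(5.0, 5.0)


class TestBuildDrive:
    def test_empty_drive_is_zero(self):
        ev = EventStream(np.array([]), np.array([], dtype=int))
        d = build_drive(ev, np.array([]), 0.0, 0.1, 10.0)
        assert np.all(d.values == 0.0) and d.values.size == 100

    def test_single_event_single_bin(self):
        ev = EventStream(np.array([0.0]), np.array([0]))
        d = build_drive(ev, np.array([1.0]), 0.0, 0.1, 10.0)
        assert np.count_nonzero(d.values) == 1
        assert d.values[0] == 1.0

    def test_coincident_events_superpose(self):
        ev = EventStream(np.array([5.0, 5.0]), np.array([0, 1]))
        d = build_drive(ev, np.array([0.3, 0.7]), 0.0, 0.1, 10.0)
        assert d.values[50] == pytest.approx(1.0)
        assert np.count_nonzero(d.values) == 1

    def test_linearity_over_event_union(self, rng):
        onsets_a = np.sort(rng.uniform(0, 9.9, 5))
        onsets_b = np.sort(rng.uniform(0, 9.9, 7))
        wa, wb = rng.normal(size=5), rng.normal(size=7)
        ev_a = EventStream(onsets_a, np.zeros(5, dtype=int))
        ev_b = EventStream(onsets_b, np.zeros(7, dtype=int))
        union = np.concatenate([onsets_a, onsets_b])
        w_union = np.concatenate([wa, wb])
        order = np.argsort(union)
        ev_ab = EventStream(union[order], np.zeros(12, dtype=int))
        da = build_drive(ev_a, wa, 0.0, 0.05, 10.0)
        db = build_drive(ev_b, wb, 0.0, 0.05, 10.0)
        dab = build_drive(ev_ab, w_union[order], 0.0, 0.05, 10.0)
        np.testing.assert_allclose(dab.values, da.values + db.values,
                                   atol=1e-12)

    def test_baseline_added_everywhere(self):
        ev = EventStream(np.array([]), np.array([], dtype=int))
        d = build_drive(ev, np.array([]), 0.25, 0.1, 1.0)
        np.testing.assert_allclose(d.values, 0.25)

    def test_event_beyond_duration_rejected(self):
        ev = EventStream(np.array([10.0]), np.array([0]))
        with pytest.raises(ValueError):
            build_drive(ev, np.array([1.0]), 0.0, 0.1, 10.0)


class TestTuningMetrics:
    def test_fwhm_closed_form(self):
        fwhm, _ = tuning_metrics(2000.0, 1000.0)
        assert fwhm == pytest.approx(2354.82, abs=0.01)

    def test_tuning_value(self):
        _, w = tuning_metrics(2000.0, 1000.0)
        assert w == pytest.approx(0.84932, abs=1e-5)

    def test_zero_center_zero_tuning(self):
        assert tuning_metrics(0.0, 500.0)[1] == 0.0

    def test_narrower_sigma_larger_w(self):
        assert tuning_metrics(1000.0, 200.0)[1] > \
            tuning_metrics(1000.0, 400.0)[1]

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            tuning_metrics(1000.0, 0.0)
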