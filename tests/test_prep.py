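"""EEG conditioning: zero-phase filters, EOG regression, synchronization."""

import numpy as np
import pytest
from scipy.signal import correlate

from readrhythm import (
    EEGRecording,
    eog_gaze_correlation,
    notch_filter,
    regress_eog,
    synchronize,
    zero_phase_highpass,
)
from readrhythm.prep import ClockMap


def _rec(data, rate=500.0, kinds=None, labels=None):
    data = np.atleast_2d(data)
    n = data.shape[0]
    return EEGRecording(
        data=data, rate_hz=rate,
        channel_labels=labels or [f"c{i}" for i in range(n)],
        channel_kinds=kinds or ["scalp"] * n)


def _lag_of_max_xcorr(a, b):
    c = correlate(a, b, mode="full")
    return int(np.argmax(c)) - (len(b) - 1)


def _amp(x):
    return np.sqrt(2.0) * x.std()


class TestHighpass:
    def test_dc_rejected(self):
        rec = _rec(np.full((1, 20000), 7.3))
        out = zero_phase_highpass(rec, 0.1, order=4000)
        assert abs(out.data.mean()) < 1e-6 * 7.3

    def test_passband_amplitude_and_zero_lag(self):
        t = np.arange(20000) / 500.0
        x = np.sin(2 * np.pi * 5.0 * t)
        out = zero_phase_highpass(_rec(x), 0.1, order=4000).data[0]
        mid = slice(4000, 16000)
        assert _amp(out[mid]) == pytest.approx(1.0, rel=0.01)
        assert _lag_of_max_xcorr(out[mid], x[mid]) == 0

    def test_stopband_attenuation(self):
        """0.01 Hz is deep in the stopband of a 0.1 Hz high-pass."""
        rate = 50.0
        t = np.arange(60000) / rate
        x = np.sin(2 * np.pi * 0.01 * t)
        out = zero_phase_highpass(_rec(x, rate=rate), 0.1, order=20000).data[0]
        mid = slice(25000, 35000)
        assert _amp(out[mid]) < 0.1

    def test_order_must_fit_signal(self):
        with pytest.raises(ValueError, match="order"):
            zero_phase_highpass(_rec(np.zeros((1, 100))), 0.1, order=200)


class TestNotch:
    def test_line_frequency_suppressed_20db(self):
        t = np.arange(20000) / 500.0
        x = np.sin(2 * np.pi * 50.0 * t)
        out = notch_filter(_rec(x), 50.0, 3.0).data[0]
        assert _amp(out[2000:18000]) < 0.1  # > 20 dB

    def test_neighbor_frequency_preserved(self):
        t = np.arange(20000) / 500.0
        x = np.sin(2 * np.pi * 10.0 * t)
        out = notch_filter(_rec(x), 50.0, 3.0).data[0]
        mid = slice(2000, 18000)
        assert _amp(out[mid]) == pytest.approx(1.0, rel=0.01)
        assert _lag_of_max_xcorr(out[mid], x[mid]) == 0

    def test_zero_in_zero_out(self):
        out = notch_filter(_rec(np.zeros((2, 5000))), 50.0, 3.0)
        assert np.allclose(out.data, 0.0)


class TestEOGRegression:
    def test_exact_linear_removal(self, rng):
        n = 5000
        eog = rng.standard_normal(n)
        s = np.sin(2 * np.pi * 5 * np.arange(n) / 500.0)
        rec = _rec(np.vstack([2.0 * eog + s, eog]), kinds=["scalp", "eog"])
        cleaned, removed = regress_eog(rec)
        resid = cleaned.data[0]
        assert abs(np.corrcoef(resid, eog)[0, 1]) < 1e-10
        assert removed["c0"] > 0

    def test_zero_eog_is_identity_for_zero_mean_data(self, rng):
        x = rng.standard_normal((2, 4000))
        x -= x.mean(axis=1, keepdims=True)
        rec = _rec(np.vstack([x, np.zeros((1, 4000))]),
                   kinds=["scalp", "scalp", "eog"])
        cleaned, _ = regress_eog(rec)
        np.testing.assert_allclose(cleaned.data[:2], x, atol=1e-10)

    def test_projection_idempotent(self, rng):
        data = rng.standard_normal((4, 3000))
        rec = _rec(data, kinds=["scalp"] * 3 + ["eog"])
        once, _ = regress_eog(rec)
        twice, _ = regress_eog(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)

    def test_removed_variance_rank_orders_planted_gains(self, rng):
        n = 8000
        eog = rng.standard_normal(n)
        gains = [3.0, 1.0, 0.3, 0.0]
        scalp = np.vstack([g * eog + 0.5 * rng.standard_normal(n) for g in gains])
        rec = _rec(np.vstack([scalp, eog]), kinds=["scalp"] * 4 + ["eog"])
        _, removed = regress_eog(rec)
        vals = [removed[f"c{i}"] for i in range(4)]
        assert vals == sorted(vals, reverse=True)

    def test_no_eog_channel_rejected(self):
        with pytest.raises(ValueError, match="EOG"):
            regress_eog(_rec(np.zeros((2, 100))))


class TestSynchronize:
    def _events(self, offset, drift, times=(0.0, 10_000.0, 60_000.0, 120_000.0)):
        eye = [(f"m{i}", t) for i, t in enumerate(times)]
        eeg = [(f"m{i}", int(round((offset + drift * t) / 2.0)))  # 500 Hz samples
               for i, t in enumerate(times)]
        return eeg, eye

    def test_offset_recovered_within_one_sample(self):
        eeg, eye = self._events(1000.0, 1.0)
        m = synchronize(eeg, eye, 500.0)
        assert abs(m.offset_ms - 1000.0) < 2.0
        assert m.drift == pytest.approx(1.0, abs=1e-5)

    def test_drift_recovered(self):
        eeg, eye = self._events(500.0, 1.001)
        m = synchronize(eeg, eye, 500.0)
        assert m.drift == pytest.approx(1.001, abs=1e-5)

    def test_identity_clocks(self):
        eeg, eye = self._events(0.0, 1.0)
        m = synchronize(eeg, eye, 500.0)
        assert abs(m.offset_ms) < 2.0 and m.drift == pytest.approx(1.0, abs=1e-5)

    def test_roundtrip_is_identity(self):
        eeg, eye = self._events(750.0, 1.0005)
        m = synchronize(eeg, eye, 500.0)
        t = np.linspace(0, 100000, 7)
        np.testing.assert_allclose(m.to_eye_ms(m.to_eeg_ms(t)), t, atol=1e-6)

    def test_too_few_shared_events_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            synchronize([("a", 0)], [("a", 0.0), ("b", 1.0)], 500.0)


class TestGazeCorrelation:
    def _identity_map(self):
        return ClockMap(offset_ms=0.0, drift=1.0, max_residual_ms=0.0, n_shared=2)

    def test_perfect_linear_relation(self, rng):
        g = rng.standard_normal(4000)
        rec = _rec(np.vstack([3.0 * g, 2.0 * g]), kinds=["eog", "eog"],
                   labels=["hEOG", "vEOG"])
        rep = eog_gaze_correlation(rec, g, g, 500.0, self._identity_map())
        assert rep.r_horizontal == pytest.approx(1.0, abs=1e-12)
        assert rep.r_vertical == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_near_zero(self, rng):
        n = 10000
        rec = _rec(rng.standard_normal((2, n)), kinds=["eog", "eog"],
                   labels=["hEOG", "vEOG"])
        rep = eog_gaze_correlation(rec, rng.standard_normal(n),
                                   rng.standard_normal(n), 500.0, self._identity_map())
        assert abs(rep.r_horizontal) < 3.0 / np.sqrt(n)

    def test_attenuation_matches_closed_form(self, rng):
        """h = a*g + noise: r should equal a*sd_g / sqrt(a^2 sd_g^2 + sigma^2)."""
        n = 50000
        a, sigma = 2.0, 1.5
        g = rng.standard_normal(n)
        h = a * g + sigma * rng.standard_normal(n)
        rec = _rec(np.vstack([h, h]), kinds=["eog", "eog"], labels=["hEOG", "vEOG"])
        rep = eog_gaze_correlation(rec, g, g, 500.0, self._identity_map())
        expected = a / np.hypot(a, sigma)
        assert rep.r_horizontal == pytest.approx(expected, abs=0.05)

    def test_missing_gaze_samples_ignored(self, rng):
        g = rng.standard_normal(3000)
        g[::7] = np.nan
        rec = _rec(np.vstack([g, g]), kinds=["eog", "eog"], labels=["hEOG", "vEOG"])
        rec.data[np.isnan(rec.data)] = 0.0
        rep = eog_gaze_correlation(rec, g, g, 500.0, self._identity_map())
        assert rep.r_horizontal == pytest.approx(1.0, abs=1e-12)
        assert rep.n_samples < 3000
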