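"""Welch PSD, surrogate construction, and group-level inference."""

import numpy as np
import pytest
from scipy.signal import periodogram

from readrhythm import (
    EyeSeries,
    FixationEvent,
    build_fixdiff_series,
    group_psd_test,
    surrogate_fixdiff,
    surrogate_saccade_train,
    welch_psd,
)


def _series(values, rate=500.0, kind="fixdiff", mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.ones(len(values), bool) if mask is None else mask
    return EyeSeries(values=values, rate_hz=rate, t0_ms=0.0, kind=kind,
                     defined_mask=mask)


class TestWelch:
    def test_sinusoid_peak_at_nearest_grid_frequency(self):
        t = np.arange(int(60 * 500)) / 500.0
        s = _series(np.sin(2 * np.pi * 5.0 * t))
        freqs, power = welch_psd(s, 4096.0, 2048.0)
        grid_nearest = freqs[np.argmin(np.abs(freqs - 5.0))]
        assert freqs[np.argmax(power)] == pytest.approx(grid_nearest)

    def test_single_segment_equals_direct_periodogram(self, rng):
        x = rng.standard_normal(2048)
        s = _series(x)
        freqs, power = welch_psd(s, 2048 / 500 * 1000, 0.0)
        f_ref, p_ref = periodogram(x, fs=500.0, window="hamming", detrend="constant")
        np.testing.assert_allclose(power, p_ref, rtol=1e-12)
        np.testing.assert_allclose(freqs, f_ref)

    def test_zero_series_zero_power(self):
        _, power = welch_psd(_series(np.zeros(4096)), 1000.0, 0.0)
        assert np.allclose(power, 0.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            welch_psd(_series(np.zeros(100)), 4096.0, 2048.0)

    def test_segments_drawn_only_from_defined_stretches(self, rng):
        x = rng.standard_normal(3000)
        mask = np.ones(3000, bool)
        mask[1000:1500] = False
        x[1000:1500] = 1e6  # poisoned undefined stretch must never be touched
        s = _series(x, mask=mask)
        _, power = welch_psd(s, 1000.0, 0.0)
        assert power.max() < 1e4


class TestSurrogates:
    def test_fixdiff_surrogates_preserve_onsets_and_count(self):
        fixes = [FixationEvent(onset_ms=250.0 * i, duration_ms=200.0 + 10 * i,
                               sentence_id=0, word_idx=i) for i in range(20)]
        obs = build_fixdiff_series(fixes, 1000.0)
        surr = surrogate_fixdiff(fixes, 1000.0, 5, seed=0)
        assert len(surr) == 5
        for s in surr:
            assert np.array_equal(s.defined_mask, obs.defined_mask)
            assert s.t0_ms == obs.t0_ms

    def test_single_unique_duration_gives_zero_surrogates(self):
        fixes = [FixationEvent(onset_ms=250.0 * i, duration_ms=200.0,
                               sentence_id=0, word_idx=i) for i in range(10)]
        for s in surrogate_fixdiff(fixes, 1000.0, 3, seed=0):
            assert np.allclose(s.values[s.defined_mask], 0.0)

    def test_fixed_seed_reproducible(self):
        fixes = [FixationEvent(onset_ms=250.0 * i, duration_ms=200.0 + 7 * (i % 5),
                               sentence_id=0, word_idx=i) for i in range(15)]
        a = surrogate_fixdiff(fixes, 1000.0, 4, seed=9)
        b = surrogate_fixdiff(fixes, 1000.0, 4, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)

    def test_train_surrogates_conserve_event_count(self, rng):
        v = np.zeros(2000)
        v[rng.choice(2000, 40, replace=False)] = 1.0
        s = _series(v, kind="saccade_train")
        for sur in surrogate_saccade_train(s, 10, seed=1):
            assert sur.values.sum() == 40

    def test_length_one_series_unchanged(self):
        s = _series([1.0], kind="saccade_train")
        (sur,) = surrogate_saccade_train(s, 1, seed=0)
        assert np.array_equal(sur.values, s.values)

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            surrogate_saccade_train(_series([0.0, 0.5, 1.0], kind="saccade_train"), 1, 0)

    def test_surrogate_spectrum_flat_for_shuffled_rhythmic_train(self):
        """Shuffling destroys the rhythm: the surrogate mean PSD is close to
        the flat spectrum of a white point process, while the observed
        rhythmic train keeps a pronounced peak."""
        rng = np.random.default_rng(7)
        onsets = np.cumsum(rng.gamma(10, 22.5, 400))  # ~4.4 Hz rhythm, ms
        v = np.zeros(int(onsets[-1]) + 10)
        v[np.round(onsets).astype(int)] = 1.0
        s = _series(v, rate=1000.0, kind="saccade_train")
        freqs, obs = welch_psd(s, 4096.0, 2048.0, fmax_hz=20.0)
        surr = surrogate_saccade_train(s, 20, seed=3)
        mean_surr = np.mean([welch_psd(x, 4096.0, 2048.0, fmax_hz=20.0)[1]
                             for x in surr], axis=0)
        low = (freqs > 0.2) & (freqs < 1.0)
        peak = (freqs > 3.5) & (freqs < 6.0)
        # rhythmic renewal train: suppressed slow fluctuations, elevated peak band
        assert obs[peak].mean() / obs[low].mean() > 3.0
        # shuffled train: flat white-point-process spectrum
        band = freqs > 0.2
        assert mean_surr[band].max() / mean_surr[band].mean() < 1.3
        assert mean_surr[peak].mean() / mean_surr[low].mean() == pytest.approx(1.0, abs=0.15)


class TestSparseTrainPSD:
    def test_sparse_direct_dft_equals_dense_welch(self, rng):
        """The event-position DFT used for surrogate trains must equal the
        dense Welch estimate exactly."""
        from readrhythm.spectral import _SparseTrainPSD

        v = np.zeros(9000)
        ones = rng.choice(9000, 60, replace=False)
        v[ones] = 1.0
        mask = np.ones(9000, bool)
        mask[4000:4500] = False
        v[4000:4500] = 0.0
        s = _series(v, rate=1000.0, kind="saccade_train", mask=mask)
        freqs, dense = welch_psd(s, 2048.0, 1024.0, fmax_hz=15.0)
        helper = _SparseTrainPSD(s, 2048, 1024, 15.0)
        sparse = helper.psd_of_positions(np.flatnonzero(v > 0))
        np.testing.assert_allclose(sparse, dense, rtol=1e-9, atol=1e-15)
        np.testing.assert_allclose(helper.freqs, freqs)


class TestVectorisedFixdiffSurrogates:
    def test_matches_event_level_rebuild(self):
        """The vectorised surrogate ensemble must equal Welch PSDs of the
        series rebuilt event-by-event from the same shuffles."""
        from readrhythm.spectral import psd_with_surrogates, surrogate_fixdiff

        rng = np.random.default_rng(0)
        fixes = []
        t = 0.0
        for i in range(60):
            t += float(rng.gamma(10, 25))
            fixes.append(FixationEvent(onset_ms=t, duration_ms=float(rng.uniform(100, 400)),
                                       sentence_id=0, word_idx=i))
        span = (fixes[0].onset_ms, fixes[-1].onset_ms)
        freqs, _, surr = psd_with_surrogates(
            "fixdiff", 1000.0, 2048.0, 1024.0, 4, seed=7, fmax_hz=20.0,
            fixations=fixes, span_ms=span)
        ref_series = surrogate_fixdiff(fixes, 1000.0, 4, seed=7, span_ms=span)
        for i, s in enumerate(ref_series):
            f_ref, p_ref = welch_psd(s, 2048.0, 1024.0, fmax_hz=20.0)
            np.testing.assert_allclose(surr[i], p_ref, rtol=1e-9, atol=1e-15)


class TestGroupInference:
    def test_rank_p_value_formula(self):
        freqs = np.array([1.0, 2.0])
        observed = np.array([[10.0, 1.0]])
        surr = np.ones((1, 100, 2))
        surr[0, :, 0] = np.linspace(0.1, 5.0, 100)  # all below observed at f0
        inf = group_psd_test(freqs, observed, surr)
        assert inf.p_per_freq[0] == pytest.approx(1.0 / 101.0)

    def test_observed_at_surrogate_median_not_significant(self, rng):
        freqs = np.arange(5.0)
        surr = rng.standard_normal((3, 200, 5)) ** 2
        observed = np.median(surr.mean(axis=0), axis=0)[None, :] * np.ones((3, 1))
        inf = group_psd_test(freqs, observed, surr)
        assert not inf.fdr_mask.any()

    def test_bh_fdr_matches_hand_enumeration(self):
        """p = [.001, .02, .04, .5] at q = .05: the step-up rule rejects
        exactly the two smallest (hand check: .001<=.0125, .02<=.025,
        .04>.0375, .5>.05)."""
        targets = np.array([0.001, 0.02, 0.04, 0.5])
        n_perm = 999
        counts = np.round(targets * (n_perm + 1) - 1).astype(int)
        freqs = np.arange(4.0)
        surr = np.tile(np.arange(1.0, n_perm + 1)[None, :, None], (1, 1, 4))
        observed = (n_perm - counts + 0.5)[None, :]
        inf = group_psd_test(freqs, observed, surr, q=0.05)
        np.testing.assert_allclose(inf.p_per_freq, targets)
        # independent hand-applied Benjamini-Hochberg ordering rule
        order = np.argsort(inf.p_per_freq)
        thresh = 0.05 * (np.arange(1, 5)) / 4
        passed = inf.p_per_freq[order] <= thresh
        k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
        expected = np.zeros(4, bool)
        expected[order[:k]] = True
        np.testing.assert_array_equal(inf.fdr_mask, expected)
        assert inf.fdr_mask.tolist() == [True, True, False, False]

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            group_psd_test(np.arange(3.0), np.zeros((2, 4)), np.zeros((2, 5, 4)))
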