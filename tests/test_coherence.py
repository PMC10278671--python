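"""Morlet TFR, ISPC, nontarget baseline, cluster permutation, multitaper coherence."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import t as t_dist

from readrhythm import (
    cluster_permutation_test,
    channel_adjacency_from_layout,
    ispc,
    morlet_tfr,
    multitaper_sentence_coherence,
    nontarget_baseline,
    saccade_locked_ispc,
)

FREQS = np.arange(0.5, 10.01, 0.5)


class TestMorlet:
    def test_sinusoid_power_peaks_at_its_frequency(self):
        t = np.arange(30000) / 500.0
        tfr = morlet_tfr(np.sin(2 * np.pi * 5.0 * t), 500.0, FREQS)
        mid = slice(*tfr.valid_range())
        mean_amp = np.abs(tfr.coeffs[0][:, mid]).mean(axis=1)
        assert FREQS[np.argmax(mean_amp)] == pytest.approx(5.0)

    def test_cosine_phase_zero_at_peak(self):
        t = np.arange(30000) / 500.0
        tfr = morlet_tfr(np.cos(2 * np.pi * 2.0 * t), 500.0, np.array([2.0]))
        peak = int(round(10.0 * 500))  # t = 10 s is a cosine peak
        assert abs(np.angle(tfr.coeffs[0, 0, peak])) < 0.05

    def test_linearity(self, rng):
        x = rng.standard_normal(12000)
        y = rng.standard_normal(12000)
        fa = np.array([2.0, 5.0])
        ta = morlet_tfr(x, 500.0, fa).coeffs
        tb = morlet_tfr(y, 500.0, fa).coeffs
        tc = morlet_tfr(2.0 * x - 0.5 * y, 500.0, fa).coeffs
        np.testing.assert_allclose(tc, 2.0 * ta - 0.5 * tb, atol=1e-6)

    def test_matches_mne_reference(self, rng):
        from mne.time_frequency import tfr_array_morlet

        x = rng.standard_normal((2, 16000))
        ours = morlet_tfr(x, 500.0, FREQS, n_cycles=5.0, dtype=np.complex128)
        ref = tfr_array_morlet(x[None], 500.0, FREQS, n_cycles=5.0,
                               output="complex", zero_mean=True, verbose="error")[0]
        mid = slice(*ours.valid_range())
        err = np.abs(ours.coeffs[:, :, mid] - ref[:, :, mid]).max()
        assert err < 1e-4 * np.abs(ref[:, :, mid]).max()

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="wavelet"):
            morlet_tfr(np.zeros(1000), 500.0, FREQS)


class TestISPC:
    @pytest.mark.parametrize(
        "phases, expected",
        [
            (np.zeros(10), 1.0),
            (np.array([0.0, np.pi]), 0.0),
            (np.array([0.0, np.pi / 2]), np.sqrt(2) / 2),
        ],
    )
    def test_known_phase_sets(self, phases, expected):
        assert ispc(phases) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(min_value=-np.pi, max_value=np.pi),
                    min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_equals_brute_force_complex_mean(self, phases):
        phases = np.array(phases)
        brute = abs(sum(np.cos(p) + 1j * np.sin(p) for p in phases) / len(phases))
        assert ispc(phases) == pytest.approx(brute, abs=1e-12)
        assert 0.0 <= ispc(phases) <= 1.0 + 1e-12

    def test_chance_level_decays_with_epoch_count(self, rng):
        rs = [np.mean([ispc(rng.uniform(-np.pi, np.pi, n)) for _ in range(200)])
              for n in (25, 100, 400)]
        # expected scaling ~ 1/sqrt(n): each doubling of sqrt(n) halves ISPC
        assert rs[0] / rs[1] == pytest.approx(2.0, rel=0.2)
        assert rs[1] / rs[2] == pytest.approx(2.0, rel=0.2)

    def test_saccade_locked_epochs_respect_validity_mask(self):
        t = np.arange(30000) / 500.0
        tfr = morlet_tfr(np.cos(2 * np.pi * 5.0 * t), 500.0, FREQS)
        lo, hi = tfr.valid_range()
        onsets = np.array([10, lo + 300, lo + 900, 15000, 29990])
        res = saccade_locked_ispc(tfr, onsets, window_ms=200.0, lag_step=10)
        assert res.n_epochs == 3  # the two edge onsets are dropped
        assert res.values.shape == (1, len(FREQS), len(res.lags_ms))
        assert res.values.max() <= 1.0 + 1e-9

    def test_too_few_epochs_rejected(self):
        t = np.arange(30000) / 500.0
        tfr = morlet_tfr(np.cos(2 * np.pi * 5.0 * t), 500.0, FREQS)
        with pytest.raises(ValueError, match="epochs"):
            saccade_locked_ispc(tfr, np.array([2]), 200.0)


class TestBaseline:
    def test_leave_one_out_mean(self):
        vals = np.array([[0.2, 0.4, 0.6]])
        np.testing.assert_allclose(nontarget_baseline(vals), [[0.5, 0.4, 0.3]])

    def test_constant_values_zero_difference(self):
        vals = np.full((3, 5), 0.37)
        np.testing.assert_allclose(nontarget_baseline(vals), vals)

    def test_single_elevated_frequency(self):
        vals = np.array([[0.1, 0.1, 0.8, 0.1]])
        diff = vals - nontarget_baseline(vals)
        assert diff[0, 2] > 0
        assert (diff[0, [0, 1, 3]] < 0).all()

    def test_single_frequency_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            nontarget_baseline(np.ones((2, 1)))


class TestClusterPermutation:
    def test_tiny_instance_matches_full_enumeration(self, rng):
        """3 participants x 2 adjacent cells: cluster sums and p equal the
        brute-force enumeration over all 8 sign patterns."""
        diffs = rng.normal(1.0, 0.3, size=(3, 1, 2))  # one channel, two freqs
        clusters = cluster_permutation_test(diffs, None, cluster_alpha=0.05, n_perm=8)
        assert clusters, "strong common effect should form a cluster"

        # --- independent oracle: enumerate the 8 sign patterns by hand ----
        X = diffs.reshape(3, 2)
        thresh = t_dist.ppf(0.95, 2)

        def tstat(d):
            return d.mean(0) / (d.std(0, ddof=1) / np.sqrt(3))

        def max_cluster_sum(tv):
            m = tv > thresh
            best, cur = 0.0, 0.0
            for ti, mi in zip(tv, m):  # 1-D adjacency: a run is a cluster
                cur = cur + ti if mi else 0.0
                best = max(best, cur)
            return best

        t_obs = tstat(X)
        obs_sums = []
        m = t_obs > thresh
        i = 0
        while i < 2:
            if m[i]:
                j = i
                while j < 2 and m[j]:
                    j += 1
                obs_sums.append(t_obs[i:j].sum())
                i = j
            else:
                i += 1
        null = [max_cluster_sum(tstat(np.array(s)[:, None] * X))
                for s in itertools.product((1, -1), repeat=3)]
        expected = sorted(
            ((s, sum(1 for v in null if v >= s - 1e-12) / 8.0) for s in obs_sums),
            key=lambda c: -c[0])
        got = [(c.sum_t, c.p) for c in clusters]
        for (es, ep), (gs, gp) in zip(expected, got):
            assert gs == pytest.approx(es)
            assert gp == pytest.approx(ep)

    def test_single_strong_cell_exhaustive_p(self, rng):
        """12 participants, one cell far above threshold: exhaustive sign-flip
        null gives p = 1/4096."""
        diffs = rng.normal(0.0, 0.05, size=(12, 4, 3))
        diffs[:, 1, 1] += 5.0
        clusters = cluster_permutation_test(diffs, None, 0.05, n_perm=4096)
        top = clusters[0]
        assert top.p == pytest.approx(1.0 / 4096.0)
        assert (1, 1) in set(zip(top.cells[0], top.cells[1]))

    def test_all_zero_differences_no_clusters(self):
        assert cluster_permutation_test(np.zeros((4, 2, 3)), None, 0.05, 64) == []

    def test_matches_mne_reference(self, rng):
        from mne.stats import permutation_cluster_1samp_test

        from scipy import sparse

        diffs = rng.normal(0.15, 0.5, size=(6, 5, 4))
        thresh = float(t_dist.ppf(0.95, 5))
        # chain adjacency over axis 0 reproduces mne's lattice connectivity
        chain = sparse.diags([1, 1], [-1, 1], shape=(5, 5), format="csr")
        ours = cluster_permutation_test(diffs, chain, 0.05, n_perm=64)
        _, mne_clusters, mne_p, h0 = permutation_cluster_1samp_test(
            diffs, threshold=thresh, tail=1, n_permutations=128,
            adjacency=None, seed=0, out_type="mask", verbose="error")
        assert len(h0) == 64  # exhaustive enumeration in both implementations
        tv = diffs.mean(0) / (diffs.std(0, ddof=1) / np.sqrt(6))
        mne_sums = [tv[m].sum() for m in mne_clusters]
        assert sorted(round(c.sum_t, 6) for c in ours) == sorted(
            round(s, 6) for s in mne_sums)
        # mne additionally prepends the observed max to the enumerated null,
        # counting the identity pattern twice; its p is ours + 1/2^n
        ours_by_sum = {round(c.sum_t, 6): c.p for c in ours}
        for s, p in zip(mne_sums, mne_p):
            assert ours_by_sum[round(s, 6)] == pytest.approx(p - 1.0 / 64.0)

    def test_channel_adjacency_joins_neighbouring_sensors(self):
        layout = {"a": (0.0, 0.0), "b": (1.0, 0.0), "c": (10.0, 0.0)}
        adj = channel_adjacency_from_layout(layout, ["a", "b", "c"])
        a = adj.toarray()
        assert a[0, 1] and not a[0, 2]


class TestMultitaperCoherence:
    def test_identical_epochs_full_coherence(self, rng):
        eps = [rng.standard_normal(1400) for _ in range(6)]
        res = multitaper_sentence_coherence(
            [e[None, :] for e in eps], eps, 500.0, FREQS)
        np.testing.assert_allclose(res.values, 1.0, atol=1e-9)

    def test_independent_noise_near_zero(self, rng):
        n_ep = 60
        eeg = [rng.standard_normal((1, 1100)) for _ in range(n_ep)]
        eye = [rng.standard_normal(1100) for _ in range(n_ep)]
        res = multitaper_sentence_coherence(eeg, eye, 500.0, FREQS)
        assert res.values.mean() < 3.0 / np.sqrt(n_ep)

    def test_planted_common_component_peaks_at_its_frequency(self, rng):
        n_ep = 30
        eeg, eye = [], []
        for _ in range(n_ep):
            n = int(rng.integers(1100, 2500))
            t = np.arange(n) / 500.0
            phase = rng.uniform(0, 2 * np.pi)
            common = np.cos(2 * np.pi * 1.0 * t + phase)
            eeg.append((common + rng.standard_normal(n))[None, :])
            eye.append(common + rng.standard_normal(n))
        res = multitaper_sentence_coherence(eeg, eye, 500.0, FREQS)
        assert FREQS[np.argmax(res.values[0])] == pytest.approx(1.0)

    def test_mismatched_epoch_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="identical lengths"):
            multitaper_sentence_coherence(
                [rng.standard_normal((1, 1000))], [rng.standard_normal(1001)],
                500.0, FREQS)
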