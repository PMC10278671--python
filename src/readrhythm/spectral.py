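"""Welch PSD of the eye series, surrogate nulls, and group-level inference.

The spectral test asks whether either eye series carries more power at a
given frequency than expected under a null in which the temporal structure
is destroyed while everything else is preserved:

* the fixdiff null shuffles the raw fixation durations over the fixed
  fixation onset times and rebuilds the difference series exactly as for
  the observed data, so the sampling pattern and the marginal duration
  distribution are conserved;
* the saccade-train null shuffles the binary vector in time (within its
  defined support), conserving the event count.

Observed and surrogate spectra are averaged over participants (pairing
surrogates by permutation index); the per-frequency p-value is the add-one
rank of the observed group mean in the surrogate group means, and a
Benjamini-Hochberg FDR mask controls the rate across frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window
from statsmodels.stats.multitest import multipletests

from .events import FixationEvent
from .eye_series import EyeSeries, build_fixdiff_series

__all__ = [
    "SpectrumInference",
    "welch_psd",
    "surrogate_fixdiff",
    "surrogate_saccade_train",
    "group_psd_test",
    "psd_with_surrogates",
]


@dataclass
class SpectrumInference:
    freqs_hz: np.ndarray
    observed_group_mean: np.ndarray
    surrogate_group_means: np.ndarray  # (n_perm, n_freq)
    p_per_freq: np.ndarray
    fdr_mask: np.ndarray
    params: dict

    @property
    def significant_freqs_hz(self) -> np.ndarray:
        return self.freqs_hz[self.fdr_mask]


def _taper_periodogram(segs: np.ndarray, fs: float, taper: str) -> tuple[np.ndarray, np.ndarray]:
    """One-sided density periodograms of mean-detrended, tapered segments.

    Matches ``scipy.signal.periodogram(..., window=taper, detrend="constant")``
    bit-for-bit but without the short-time-FFT machinery, so large segment
    batches stay cheap.
    """
    n = segs.shape[-1]
    win = get_window(taper, n)
    x = (segs - segs.mean(axis=-1, keepdims=True)) * win
    spec = np.fft.rfft(x, axis=-1)
    pxx = (spec.real**2 + spec.imag**2) / (fs * (win * win).sum())
    pxx[..., 1:] *= 2.0
    if n % 2 == 0:
        pxx[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, pxx


def _segments(series: EyeSeries, nperseg: int, noverlap: int) -> np.ndarray:
    """Stack Welch segments drawn from fully defined stretches."""
    step = nperseg - noverlap
    if step <= 0:
        raise ValueError("overlap must be smaller than the window")
    segs = []
    v = series.values
    for run in series.defined_runs():
        length = run.stop - run.start
        for start in range(0, length - nperseg + 1, step):
            segs.append(v[run.start + start: run.start + start + nperseg])
    if not segs:
        raise ValueError(
            f"no defined stretch of the series is as long as one window "
            f"({nperseg} samples)")
    return np.asarray(segs)


def welch_psd(
    series: EyeSeries,
    window_ms: float,
    overlap_ms: float,
    fmax_hz: float | None = None,
    taper: str = "hamming",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density over the defined support of a series.

    Mean of tapered, mean-detrended segment periodograms; the frequency
    resolution is ``rate / nperseg``.
    """
    rate = series.rate_hz
    nperseg = int(round(window_ms * rate / 1000.0))
    noverlap = int(round(overlap_ms * rate / 1000.0))
    segs = _segments(series, nperseg, noverlap)
    freqs, pxx = _taper_periodogram(segs, rate, taper)
    power = pxx.mean(axis=0)
    if fmax_hz is not None:
        keep = freqs <= fmax_hz
        freqs, power = freqs[keep], power[keep]
    return freqs, power


def surrogate_fixdiff(
    fixations: list[FixationEvent],
    rate_hz: float,
    n_perm: int,
    seed: int,
    span_ms: tuple[float, float] | None = None,
) -> list[EyeSeries]:
    """Surrogates that shuffle raw durations over the fixed onset times.

    ``fixations`` must already be filtered and post-regression-excluded;
    each surrogate rebuilds the difference series exactly as the observed one.
    """
    return list(_iter_surrogate_fixdiff(fixations, rate_hz, n_perm, seed, span_ms))


def _iter_surrogate_fixdiff(fixations, rate_hz, n_perm, seed, span_ms=None):
    import dataclasses

    rng = np.random.default_rng(seed)
    durations = np.array([f.duration_ms for f in fixations])
    for _ in range(n_perm):
        perm = rng.permutation(durations)
        shuffled = [dataclasses.replace(f, duration_ms=float(d))
                    for f, d in zip(fixations, perm)]
        yield build_fixdiff_series(shuffled, rate_hz, span_ms)


def _iter_surrogate_train_values(series: EyeSeries, n_perm: int, seed: int):
    """Fast path: yields raw shuffled value arrays (shared mask)."""
    defined = series.defined_mask
    vals = series.values[defined]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("saccade-train surrogates require a binary series")
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        v = series.values.copy()
        v[defined] = rng.permutation(vals)
        yield v


def surrogate_saccade_train(
    series: EyeSeries, n_perm: int, seed: int
) -> list[EyeSeries]:
    """Surrogates that shuffle the binary vector in time (defined support only)."""
    return list(_iter_surrogate_train(series, n_perm, seed))


def _iter_surrogate_train(series: EyeSeries, n_perm: int, seed: int):
    import dataclasses

    for v in _iter_surrogate_train_values(series, n_perm, seed):
        yield dataclasses.replace(series, values=v,
                                  defined_mask=series.defined_mask.copy())


class _SparseTrainPSD:
    """Welch PSD of binary trains evaluated directly from event positions.

    A mean-detrended, tapered segment of a binary train has the DFT
    ``sum_ones win[j] e^{-2 pi i j k / n} - mean * DFT(win)[k]``, so with a
    few hundred ones per segment and only the low-frequency bins kept, a
    direct DFT over the ones is far cheaper than a full FFT — and exactly
    equal to it. Used for the surrogate ensemble, where hundreds of
    shuffles of the same train are needed.
    """

    def __init__(self, series: EyeSeries, nperseg: int, noverlap: int, fmax_hz: float):
        rate = series.rate_hz
        step = nperseg - noverlap
        starts = []
        for run in series.defined_runs():
            length = run.stop - run.start
            starts.extend(run.start + s for s in range(0, length - nperseg + 1, step))
        if not starts:
            raise ValueError("no defined stretch as long as one window")
        self.starts = np.asarray(starts)
        self.n_seg = len(starts)
        self.nperseg = nperseg
        self.rate = rate
        freqs = np.fft.rfftfreq(nperseg, 1.0 / rate)
        self.keep = freqs <= fmax_hz
        self.freqs = freqs[self.keep]
        bins = np.flatnonzero(self.keep)
        win = get_window("hamming", nperseg)
        E = np.exp(-2j * np.pi * np.outer(np.arange(nperseg), bins) / nperseg)
        self.WE = win[:, None] * E  # (nperseg, n_bins)
        self.dft_win = win @ E
        self.scale = np.where(bins == 0, 1.0, 2.0) / (rate * (win * win).sum())
        if nperseg % 2 == 0 and bins[-1] == nperseg // 2:
            self.scale[-1] /= 2.0
        # membership of every sample in (up to two, with 50% overlap) segments
        n = len(series.values)
        pos = np.arange(n)
        j = np.searchsorted(self.starts, pos, side="right") - 1
        self.membership = []
        for j_off in (0, 1):
            jj = j - j_off
            valid = (jj >= 0) & (pos >= self.starts[np.clip(jj, 0, None)]) & (
                pos - self.starts[np.clip(jj, 0, None)] < nperseg)
            seg = np.where(valid, jj, -1)
            off = np.where(valid, pos - self.starts[np.clip(jj, 0, None)], 0)
            self.membership.append((seg, off))

    def psd_of_positions(self, ones_pos: np.ndarray) -> np.ndarray:
        F = np.zeros((self.n_seg, len(self.freqs)), dtype=complex)
        counts = np.zeros(self.n_seg)
        for seg_map, off_map in self.membership:
            seg = seg_map[ones_pos]
            sel = seg >= 0
            if not sel.any():
                continue
            np.add.at(F, seg[sel], self.WE[off_map[ones_pos][sel]])
            counts += np.bincount(seg[sel], minlength=self.n_seg)
        F -= (counts / self.nperseg)[:, None] * self.dft_win[None, :]
        pxx = (F.real**2 + F.imag**2) * self.scale[None, :]
        return pxx.mean(axis=0)


def _train_surrogate_psds(
    series: EyeSeries, nperseg: int, noverlap: int, n_perm: int, seed: int,
    fmax_hz: float,
) -> tuple[np.ndarray, np.ndarray]:
    helper = _SparseTrainPSD(series, nperseg, noverlap, fmax_hz)
    defined_pos = np.flatnonzero(series.defined_mask)
    vals = series.values[defined_pos]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("saccade-train surrogates require a binary series")
    n_ones = int(vals.sum())
    rng = np.random.default_rng(seed)
    surr = np.empty((n_perm, len(helper.freqs)))
    for i in range(n_perm):
        picks = rng.choice(len(defined_pos), size=n_ones, replace=False, shuffle=False)
        surr[i] = helper.psd_of_positions(defined_pos[picks])
    return helper.freqs, surr


def _fixdiff_surrogate_psds(
    fixations: list[FixationEvent],
    series: EyeSeries,
    nperseg: int,
    noverlap: int,
    n_perm: int,
    seed: int,
    fmax_hz: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Surrogate PSD ensemble for the duration-difference series, vectorised.

    The onset times — hence the anchor times, interpolation grid and Welch
    segment layout — are identical for every surrogate; only the duration
    values permute. Each surrogate's series is therefore a fixed linear
    gather of its permuted duration differences, which reproduces
    ``build_fixdiff_series`` on the shuffled events exactly.
    """
    from .eye_series import fixdiff_anchors

    rate = series.rate_hz
    t_anchor, _, b_anchor = fixdiff_anchors(fixations)
    if len(t_anchor) < 2:
        raise ValueError("need at least two anchors for surrogate spectra")
    # consecutive fixation pairs within a block, in anchor order
    pair_lo, pair_hi = [], []
    k = 0
    for j in range(len(fixations) - 1):
        if fixations[j + 1].block_id == fixations[j].block_id:
            pair_lo.append(j)
            pair_hi.append(j + 1)
            k += 1
    pair_lo = np.asarray(pair_lo)
    pair_hi = np.asarray(pair_hi)

    step = nperseg - noverlap
    starts = []
    for run in series.defined_runs():
        length = run.stop - run.start
        starts.extend(run.start + s for s in range(0, length - nperseg + 1, step))
    if not starts:
        raise ValueError("no defined stretch as long as one window")
    idx = np.asarray(starts)[:, None] + np.arange(nperseg)[None, :]

    # linear-interpolation gather for every defined sample
    t_samples = series.t0_ms + np.arange(len(series.values)) * (1000.0 / rate)
    defined = np.flatnonzero(series.defined_mask)
    i0 = np.clip(np.searchsorted(t_anchor, t_samples[defined], side="right") - 1,
                 0, len(t_anchor) - 2)
    dt = t_anchor[i0 + 1] - t_anchor[i0]
    w = np.where(dt > 0, (t_samples[defined] - t_anchor[i0]) / np.where(dt > 0, dt, 1.0), 0.0)
    # anchors may straddle a block boundary only outside defined samples
    same_block = b_anchor[i0] == b_anchor[i0 + 1]
    w = np.where(same_block, w, 0.0)

    durations = np.array([f.duration_ms for f in fixations])
    rng = np.random.default_rng(seed)
    freqs_full = np.fft.rfftfreq(nperseg, 1.0 / rate)
    keep = freqs_full <= fmax_hz if fmax_hz is not None else np.ones_like(freqs_full, bool)
    surr = np.empty((n_perm, int(keep.sum())))
    template = np.zeros_like(series.values)
    chunk = 50
    for c0 in range(0, n_perm, chunk):
        c1 = min(c0 + chunk, n_perm)
        perms = np.stack([rng.permutation(durations) for _ in range(c1 - c0)])
        diffs = perms[:, pair_hi] - perms[:, pair_lo]  # (chunk, n_anchor)
        sample_vals = diffs[:, i0] * (1.0 - w) + diffs[:, i0 + 1] * w
        values = np.tile(template, (c1 - c0, 1))
        values[:, defined] = sample_vals
        segs = values[:, idx]
        _, pxx = _taper_periodogram(segs, rate, "hamming")
        surr[c0:c1] = pxx.mean(axis=1)[:, keep]
    return freqs_full[keep], surr


def psd_with_surrogates(
    kind: str,
    rate_hz: float,
    window_ms: float,
    overlap_ms: float,
    n_perm: int,
    seed: int,
    fmax_hz: float | None = None,
    series: EyeSeries | None = None,
    fixations: list[FixationEvent] | None = None,
    span_ms: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed PSD plus the surrogate PSD ensemble for one participant.

    Streams over surrogates so that only spectra are retained. Returns
    ``(freqs, observed_power, surrogate_power[n_perm, n_freq])``.
    """
    if kind == "fixdiff":
        if fixations is None:
            raise ValueError("fixdiff surrogates need the fixation list")
        if series is None:
            series = build_fixdiff_series(fixations, rate_hz, span_ms)
        nperseg = int(round(window_ms * rate_hz / 1000.0))
        noverlap = int(round(overlap_ms * rate_hz / 1000.0))
        freqs, observed = welch_psd(series, window_ms, overlap_ms, fmax_hz)
        f_surr, surr = _fixdiff_surrogate_psds(fixations, series, nperseg,
                                               noverlap, n_perm, seed, fmax_hz)
        assert np.allclose(f_surr, freqs)
        return freqs, observed, surr
    elif kind == "saccade_train":
        if series is None:
            raise ValueError("saccade surrogates need the observed series")
        if fmax_hz is not None:
            # sparse direct-DFT path: exact and much faster for binary trains
            nperseg = int(round(window_ms * rate_hz / 1000.0))
            noverlap = int(round(overlap_ms * rate_hz / 1000.0))
            freqs, observed = welch_psd(series, window_ms, overlap_ms, fmax_hz)
            f_surr, surr = _train_surrogate_psds(series, nperseg, noverlap,
                                                 n_perm, seed, fmax_hz)
            assert np.allclose(f_surr, freqs)
            return freqs, observed, surr
        sur_iter = _iter_surrogate_train_values(series, n_perm, seed)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    freqs, observed = welch_psd(series, window_ms, overlap_ms, fmax_hz)

    # all surrogates share the observed mask, so the Welch segment layout is
    # fixed; batching surrogate periodograms cuts per-call overhead
    rate = series.rate_hz
    nperseg = int(round(window_ms * rate / 1000.0))
    noverlap = int(round(overlap_ms * rate / 1000.0))
    step = nperseg - noverlap
    starts = []
    for run in series.defined_runs():
        length = run.stop - run.start
        starts.extend(run.start + s for s in range(0, length - nperseg + 1, step))
    idx = np.asarray(starts)[:, None] + np.arange(nperseg)[None, :]
    keep = None
    surr = np.empty((n_perm, len(freqs)))
    chunk_vals, chunk_pos = [], []
    for i, vals in enumerate(sur_iter):
        chunk_vals.append(vals)
        chunk_pos.append(i)
        if len(chunk_vals) == 50 or i == n_perm - 1:
            segs = np.asarray(chunk_vals)[:, idx]  # (chunk, n_seg, nperseg)
            f, pxx = _taper_periodogram(segs, rate, "hamming")
            if keep is None:
                keep = f <= fmax_hz if fmax_hz is not None else slice(None)
            surr[chunk_pos] = pxx.mean(axis=1)[:, keep]
            chunk_vals, chunk_pos = [], []
    return freqs, observed, surr


def group_psd_test(
    freqs_hz: np.ndarray,
    observed: np.ndarray,
    surrogates: np.ndarray,
    q: float = 0.05,
    params: dict | None = None,
) -> SpectrumInference:
    """Group-level per-frequency test of observed vs surrogate power.

    ``observed`` is (n_participants, n_freq); ``surrogates`` is
    (n_participants, n_perm, n_freq) with surrogates paired across
    participants by permutation index.
    """
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    surrogates = np.asarray(surrogates, dtype=float)
    if surrogates.ndim == 2:
        surrogates = surrogates[None]
    if observed.shape[1] != len(freqs_hz) or surrogates.shape[2] != len(freqs_hz):
        raise ValueError("frequency grids of observed and surrogates must match")
    if observed.shape[0] != surrogates.shape[0]:
        raise ValueError("participant counts of observed and surrogates must match")
    group_obs = observed.mean(axis=0)
    group_surr = surrogates.mean(axis=0)  # (n_perm, n_freq)
    n_perm = group_surr.shape[0]
    p = (1.0 + (group_surr >= group_obs[None, :]).sum(axis=0)) / (1.0 + n_perm)
    mask = multipletests(p, alpha=q, method="fdr_bh")[0]
    return SpectrumInference(
        freqs_hz=np.asarray(freqs_hz, dtype=float),
        observed_group_mean=group_obs,
        surrogate_group_means=group_surr,
        p_per_freq=p,
        fdr_mask=mask,
        params=dict(params or {}, n_perm=n_perm, q=q),
    )
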