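"""EEG conditioning: zero-phase filtering, EOG regression, clock
synchronization, and the EOG-gaze validation check.

All filters here are zero-phase: the FIR high-pass and notch use symmetric
(linear-phase) kernels applied with centred convolution, so passband
components come out with zero lag. Ocular artifact removal is plain least
squares: each scalp channel is replaced by its residual after projection
onto the EOG channels (plus intercept). Eye-tracker and EEG clocks are
related by an affine map (offset + drift) fitted to shared event markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import firwin, fftconvolve

from .eeg import EEGRecording

__all__ = [
    "zero_phase_highpass",
    "notch_filter",
    "regress_eog",
    "ClockMap",
    "synchronize",
    "eog_gaze_correlation",
]

logger = logging.getLogger(__name__)

# reference filter orders at a 500 Hz sampling rate; scaled for other rates
HIGHPASS_ORDER_500 = 16500
NOTCH_ORDER_500 = 826


def _zero_phase_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Centred (group-delay-compensated) FIR filtering with reflect padding."""
    half = (len(taps) - 1) // 2
    pad = min(half, data.shape[-1] - 1)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = fftconvolve(padded, taps[np.newaxis, :] if data.ndim == 2 else taps,
                      mode="same", axes=-1)
    return out[..., pad: data.shape[-1] + pad]


def _resolve_order(order: int | None, reference: int, rate_hz: float, n_samples: int) -> int:
    if order is None:
        order = int(round(reference * rate_hz / 500.0))
        order = min(order, 2 * ((n_samples - 2) // 2))
    if order % 2:
        order += 1
    if order >= n_samples:
        raise ValueError(f"filter order {order} must be below signal length {n_samples}")
    if order < 2:
        raise ValueError("filter order too small")
    return order


def zero_phase_highpass(
    eeg: EEGRecording, cutoff_hz: float = 0.1, order: int | None = None
) -> EEGRecording:
    """Zero-phase FIR high-pass of all channels; DC is removed exactly."""
    if cutoff_hz >= eeg.rate_hz / 2:
        raise ValueError("cutoff must be below Nyquist")
    order = _resolve_order(order, HIGHPASS_ORDER_500, eeg.rate_hz, eeg.n_samples)
    taps = firwin(order + 1, cutoff_hz, window="hamming", pass_zero=False, fs=eeg.rate_hz)
    demeaned = eeg.data - eeg.data.mean(axis=1, keepdims=True)
    return eeg.copy_with(_zero_phase_fir(demeaned, taps))


def notch_filter(
    eeg: EEGRecording, center_hz: float = 50.0, half_width_hz: float = 3.0,
    order: int | None = None,
) -> EEGRecording:
    """Zero-phase Hamming-windowed FIR band-stop around ``center_hz``."""
    if center_hz + half_width_hz >= eeg.rate_hz / 2:
        raise ValueError("stopband must be below Nyquist")
    order = _resolve_order(order, NOTCH_ORDER_500, eeg.rate_hz, eeg.n_samples)
    taps = firwin(order + 1, [center_hz - half_width_hz, center_hz + half_width_hz],
                  window="hamming", pass_zero=True, fs=eeg.rate_hz)
    return eeg.copy_with(_zero_phase_fir(eeg.data, taps))


def regress_eog(eeg: EEGRecording) -> tuple[EEGRecording, dict[str, float]]:
    """Remove ocular activity by least-squares regression of EOG channels.

    Each scalp channel is replaced by its residual after projection onto the
    EOG channels plus an intercept. Returns the cleaned recording and a map
    of per-channel variance removed (the topography of removed activity).
    """
    eog_idx = eeg.eog_indices
    if len(eog_idx) == 0:
        raise ValueError("recording has no EOG channels")
    scalp_idx = eeg.scalp_indices
    E = eeg.data[eog_idx].T  # (n_samples, n_eog)
    design = np.column_stack([np.ones(E.shape[0]), E])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning("EOG design rank-deficient (%d < %d); collinear columns dropped",
                       rank, design.shape[1])
    X = eeg.data[scalp_idx].T
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    cleaned = eeg.data.copy()
    cleaned[scalp_idx] = resid.T
    removed = X.var(axis=0) - resid.var(axis=0)
    removed_map = {eeg.channel_labels[ch]: float(r) for ch, r in zip(scalp_idx, removed)}
    return eeg.copy_with(cleaned), removed_map


@dataclass(frozen=True)
class ClockMap:
    """Affine map from the eye-tracker clock (ms) to the EEG clock (ms)."""

    offset_ms: float
    drift: float
    max_residual_ms: float
    n_shared: int

    def to_eeg_ms(self, t_eye_ms):
        return self.offset_ms + self.drift * np.asarray(t_eye_ms)

    def to_eye_ms(self, t_eeg_ms):
        return (np.asarray(t_eeg_ms) - self.offset_ms) / self.drift

    def to_eeg_sample(self, t_eye_ms, rate_hz: float):
        return np.floor(self.to_eeg_ms(t_eye_ms) * rate_hz / 1000.0 + 0.5).astype(int)


def synchronize(
    eeg_events: list[tuple[str, int]],
    eye_events: list[tuple[str, float]],
    eeg_rate_hz: float,
) -> ClockMap:
    """Fit the affine eye-to-EEG clock map from shared labelled events."""
    eeg_ms = {label: idx * 1000.0 / eeg_rate_hz for label, idx in eeg_events}
    shared = [(t, eeg_ms[label]) for label, t in eye_events if label in eeg_ms]
    if len(shared) < 2:
        raise ValueError(f"need >= 2 shared events, got {len(shared)}")
    x = np.array([s[0] for s in shared])
    y = np.array([s[1] for s in shared])
    drift, offset = np.polyfit(x, y, 1)
    resid = y - (offset + drift * x)
    return ClockMap(offset_ms=float(offset), drift=float(drift),
                    max_residual_ms=float(np.abs(resid).max()), n_shared=len(shared))


@dataclass(frozen=True)
class GazeCorrelationReport:
    r_horizontal: float
    r_vertical: float
    n_samples: int


def eog_gaze_correlation(
    eeg: EEGRecording,
    gaze_x: np.ndarray,
    gaze_y: np.ndarray,
    gaze_rate_hz: float,
    clock_map: ClockMap,
    heog_label: str = "hEOG",
    veog_label: str = "vEOG",
) -> GazeCorrelationReport:
    """Pearson correlation of the EOG channels with the matching gaze axis.

    Gaze traces live on the eye-tracker clock; they are brought onto the EEG
    sample grid through the clock map. Samples where the tracker lost the
    eye (NaN gaze) are removed before correlating.
    """
    t_eye = clock_map.to_eye_ms(np.arange(eeg.n_samples) * 1000.0 / eeg.rate_hz)
    src_idx = np.floor(t_eye * gaze_rate_hz / 1000.0 + 0.5).astype(int)
    valid = (src_idx >= 0) & (src_idx < len(gaze_x))
    gx = np.full(eeg.n_samples, np.nan)
    gy = np.full(eeg.n_samples, np.nan)
    gx[valid] = gaze_x[src_idx[valid]]
    gy[valid] = gaze_y[src_idx[valid]]
    h = eeg.pick([heog_label])[0]
    v = eeg.pick([veog_label])[0]

    def _corr(a, b):
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
            logger.warning("zero-variance input; correlation undefined")
            return float("nan"), int(ok.sum())
        return float(np.corrcoef(a[ok], b[ok])[0, 1]), int(ok.sum())

    rh, n = _corr(h, gx)
    rv, _ = _corr(v, gy)
    return GazeCorrelationReport(r_horizontal=rh, r_vertical=rv, n_samples=n)
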