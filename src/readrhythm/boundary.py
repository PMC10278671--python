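"""Delta-band phase clustering at sentence boundaries.

Sentence-final words carry a behavioural wrap-up signature; if slow
oscillatory activity paces the grouping of words into multi-word chunks,
its phase should cluster at sentence-final word onsets. The test:

1. low-pass the signal of interest (EEG channel or fixdiff series) at
   2.5 Hz with a two-pass Butterworth filter (zero net phase);
2. take the Hilbert analytic phase;
3. read the phase at each sentence-final fixation onset and compute the
   Rayleigh statistic z = n * Rbar^2 per participant;
4. compare the participant-mean z with a surrogate distribution built from
   draws of non-sentence-final fixation onsets (per participant, as many as
   that participant's final count, sampled without replacement), using an
   add-one one-sided rank p; when several electrodes are tested the p
   values are FDR-corrected (Benjamini-Hochberg).

Angles follow the cosine-phase convention: 0 at a signal peak, reported in
(-pi, pi].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy import fft as sfft
from statsmodels.stats.multitest import multipletests

__all__ = [
    "butter_lowpass_twopass",
    "hilbert_phase",
    "phases_at_events",
    "rayleigh_test",
    "BoundaryPhaseResult",
    "boundary_clustering_test",
]

logger = logging.getLogger(__name__)


def butter_lowpass_twopass(
    x: np.ndarray, rate_hz: float, cutoff_hz: float = 2.5, order: int = 8
) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero net phase)."""
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    if cutoff_hz >= rate_hz / 2:
        raise ValueError("cutoff must be below Nyquist")
    sos = butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return sosfiltfilt(sos, x, axis=-1)


def hilbert_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase (argument of the analytic signal)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    analytic = hilbert(x, N=sfft.next_fast_len(n), axis=-1)[..., :n]
    return np.angle(analytic)


def phases_at_events(
    phase: np.ndarray, event_times_ms: np.ndarray, rate_hz: float, t0_ms: float = 0.0
) -> np.ndarray:
    """Phase at the sample nearest each event onset; events outside the span
    are skipped with a warning."""
    idx = np.floor((np.asarray(event_times_ms, dtype=float) - t0_ms)
                   * rate_hz / 1000.0 + 0.5).astype(int)
    inside = (idx >= 0) & (idx < phase.shape[-1])
    if not inside.all():
        logger.warning("%d event(s) outside the series span skipped", int((~inside).sum()))
    return phase[..., idx[inside]]


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: z = n * Rbar**2.

    The p-value uses the standard small-sample series approximation.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n == 0:
        raise ValueError("Rayleigh test needs at least one angle")
    rbar = float(np.abs(np.exp(1j * angles).mean()))
    z = n * rbar**2
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - (rbar * n) ** 2)) - (1.0 + 2.0 * n))
    return z, min(p, 1.0)


def _rayleigh_z(angles: np.ndarray, axis: int = -1) -> np.ndarray:
    n = angles.shape[axis]
    return n * np.abs(np.exp(1j * angles).mean(axis=axis)) ** 2


@dataclass
class BoundaryPhaseResult:
    electrodes: list[str]
    observed_z: np.ndarray  # per electrode, participant-mean Rayleigh z
    surrogate_z: np.ndarray  # (n_electrodes, n_draw)
    p: np.ndarray
    fdr_mask: np.ndarray
    angles_per_participant: list[np.ndarray]  # (n_electrodes, n_final) each
    n_final: list[int]
    params: dict = field(default_factory=dict)


def boundary_clustering_test(
    final_angles: list[np.ndarray],
    nonfinal_angles: list[np.ndarray],
    electrodes: list[str] | None = None,
    n_draw: int = 1000,
    seed: int = 0,
    q: float = 0.05,
) -> BoundaryPhaseResult:
    """Participant-mean Rayleigh z at sentence-final onsets vs non-final draws.

    ``final_angles`` and ``nonfinal_angles`` hold, per participant, arrays of
    shape (n_electrodes, n_events). Each surrogate draw samples, for every
    participant, as many non-final onsets as that participant's final count
    (without replacement when possible), recomputes z per electrode, and
    averages over participants.
    """
    if not final_angles or len(final_angles) != len(nonfinal_angles):
        raise ValueError("need matching per-participant final and non-final angle lists")
    final_angles = [np.atleast_2d(a) for a in final_angles]
    nonfinal_angles = [np.atleast_2d(a) for a in nonfinal_angles]
    n_el = final_angles[0].shape[0]
    if electrodes is None:
        electrodes = [f"e{i}" for i in range(n_el)]
    rng = np.random.default_rng(seed)

    observed = np.mean([_rayleigh_z(a, axis=-1) for a in final_angles], axis=0)

    surr = np.zeros((len(final_angles), n_el, n_draw))
    for pi, (fin, non) in enumerate(zip(final_angles, nonfinal_angles)):
        n_fin, n_non = fin.shape[1], non.shape[1]
        if n_non < n_fin:
            logger.warning(
                "participant %d: only %d non-final fixations for %d finals; "
                "sampling with replacement", pi, n_non, n_fin)
            picks = rng.integers(0, n_non, size=(n_draw, n_fin))
        else:
            picks = np.array([rng.choice(n_non, size=n_fin, replace=False)
                              for _ in range(n_draw)])
        surr[pi] = _rayleigh_z(non[:, picks], axis=-1)  # (n_el, n_draw)
    surrogate_z = surr.mean(axis=0)  # (n_el, n_draw)

    p = (1.0 + (surrogate_z >= observed[:, None]).sum(axis=1)) / (1.0 + n_draw)
    if n_el > 1:
        mask = multipletests(p, alpha=q, method="fdr_bh")[0]
    else:
        mask = p <= q
    return BoundaryPhaseResult(
        electrodes=list(electrodes),
        observed_z=observed,
        surrogate_z=surrogate_z,
        p=p,
        fdr_mask=np.asarray(mask, dtype=bool),
        angles_per_participant=final_angles,
        n_final=[a.shape[1] for a in final_angles],
        params={"n_draw": n_draw, "seed": seed, "q": q},
    )
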