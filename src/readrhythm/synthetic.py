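"""Synthetic co-registered reading sessions with planted rhythmic structure.

The generator produces, for each participant, a temporally structured stream
of ocular events (saccades and fixations organised into sentences and
blocks) together with a multichannel EEG/EOG recording whose oscillatory
components are phase-coupled to those events in known, configurable ways:

* saccade onsets form a gamma renewal process with mean interval
  ``1/sacc_rhythm_hz`` (shape 1 reduces to a Poisson process);
* fixation durations carry a slow sinusoidal modulation
  (``fixdiff_amp_ms`` at ``fixdiff_rhythm_hz``) plus Gaussian noise,
  truncated to the plausible range [60, 1000] ms;
* a theta-band EEG component on designated posterior channels is
  phase-reset at saccade onsets with von Mises concentration
  ``theta_lock_kappa`` (kappa = 0 resets to uniform angles, i.e. no locking);
* a delta-band component on designated occipital channels shares the phase
  of the fixation-duration modulation with weight I1(k)/I0(k) at
  ``delta_lock_kappa``, and is additionally phase-concentrated at
  sentence-final word onsets when ``boundary_lock_kappa`` > 0;
* EOG channels follow a latent step-wise gaze trajectory (horizontal word
  position, vertical line position) and leak into scalp channels through a
  configurable mixing matrix.

Everything is deterministic given ``(config.seed, participant)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import i0, i1

from .config import SimulationConfig
from .eeg import EEGRecording
from .events import FixationEvent, SaccadeEvent, SentenceSpan

__all__ = [
    "ReadingSession",
    "simulate_eye_events",
    "simulate_eeg",
    "simulate_session",
    "default_layout",
]

_ROWS = ("F", "C", "P", "O")  # anterior -> posterior


def default_layout(n_channels: int) -> tuple[list[str], dict[str, tuple[float, float]]]:
    """Generic scalp montage: four anterior-to-posterior rows of channels."""
    per_row = int(math.ceil(n_channels / len(_ROWS)))
    labels: list[str] = []
    layout: dict[str, tuple[float, float]] = {}
    ys = {"F": 0.75, "C": 0.25, "P": -0.25, "O": -0.75}
    for i in range(n_channels):
        row = _ROWS[i // per_row]
        col = i % per_row
        label = f"{row}{col + 1}"
        labels.append(label)
        x = -0.75 + 1.5 * col / max(per_row - 1, 1)
        layout[label] = (x, ys[row])
    return labels, layout


@dataclass
class ReadingSession:
    """One participant's simulated session: events, EEG, gaze, and truth."""

    participant_id: int
    fixations: list[FixationEvent]
    saccades: list[SaccadeEvent]
    sentences: list[SentenceSpan]
    eeg: EEGRecording
    eye_markers: list[tuple[str, float]]  # (label, eye-clock ms)
    gaze_x: np.ndarray  # eye-clock gaze traces at eye_rate_hz (NaN = lost)
    gaze_y: np.ndarray
    gaze_rate_hz: float
    truth: dict[str, Any] = field(default_factory=dict)


def _rng(config: SimulationConfig, participant: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, participant, stream])


def _modulation_phase(config: SimulationConfig, participant: int) -> float:
    """Participant-specific phase of the slow fixation-duration modulation."""
    return float(_rng(config, participant, 2).uniform(0.0, 2.0 * np.pi))


def _von_mises(rng: np.random.Generator, kappa: float, size: int) -> np.ndarray:
    if kappa <= 0:
        return rng.uniform(-np.pi, np.pi, size)
    return rng.vonmises(0.0, kappa, size)


def simulate_eye_events(
    config: SimulationConfig, participant: int
) -> tuple[list[FixationEvent], list[SaccadeEvent], list[SentenceSpan], list[tuple[str, float]]]:
    """Generate one participant's ocular event stream.

    Returns ``(fixations, saccades, sentence_spans, shared_markers)``; the
    markers (block starts/ends on the eye-tracker clock) are the shared
    events used for EEG synchronization.
    """
    rng = _rng(config, participant, 0)
    phi_p = _modulation_phase(config, participant)

    mean_isi = 1000.0 / config.sacc_rhythm_hz
    shape = config.sacc_interval_shape
    # insertion probability chosen so the long-run backward fraction is
    # p_regression: each regression adds one extra (backward) visit, and only
    # words 2..n-2 are eligible (no regression into the first two or out of
    # the final word), hence the eligibility correction.
    if config.p_regression > 0:
        eligible = max(config.words_per_sentence_mean - 3.0, 1.0)
        q = (config.p_regression / (1.0 - config.p_regression)
             * config.words_per_sentence_mean / eligible)
    else:
        q = 0.0
    per_block = config.n_sentences // config.n_blocks

    fixations: list[FixationEvent] = []
    saccades: list[SaccadeEvent] = []
    spans: list[SentenceSpan] = []
    markers: list[tuple[str, float]] = []

    t = 1000.0  # eye-clock ms; leading margin before the first block
    sid = 0
    for b in range(config.n_blocks):
        markers.append((f"block{b}_start", t))
        for _ in range(per_block):
            n_words = int(np.clip(round(rng.normal(
                config.words_per_sentence_mean, config.words_per_sentence_sd)), 4, 90))
            # build the visit plan: forward visits with occasional inserted
            # regressions (backward saccade + flagged re-read fixation)
            visits: list[tuple[int, bool]] = []  # (word_idx, is_regression_visit)
            for w in range(n_words):
                visits.append((w, False))
                if 2 <= w < n_words - 1 and rng.uniform() < q:
                    visits.append((max(w - 2, 0), True))

            sent_fix: list[FixationEvent] = []
            prev_fix_onset = -np.inf
            for vi, (word, is_reg) in enumerate(visits):
                sacc_dur = float(np.clip(rng.normal(config.mean_sacc_ms, config.sd_sacc_ms),
                                         10.0, 79.0))
                if config.inject_long_saccades > 0 and rng.uniform() < config.inject_long_saccades:
                    sacc_dur = float(rng.uniform(81.0, 130.0))
                saccades.append(SaccadeEvent(onset_ms=t, duration_ms=sacc_dur,
                                             is_backward=is_reg, block_id=b))
                fix_onset = max(t + sacc_dur, prev_fix_onset + 1.0)
                prev_fix_onset = fix_onset
                is_final = vi == len(visits) - 1
                dur = (
                    config.mean_fix_ms
                    + config.fixdiff_amp_ms
                    * math.sin(2.0 * np.pi * config.fixdiff_rhythm_hz * fix_onset / 1000.0 + phi_p)
                    + rng.normal(0.0, config.sd_fix_ms)
                )
                if is_final:
                    dur += config.final_lengthening_ms
                dur = float(np.clip(dur, 60.0, 1000.0))
                if config.inject_long_fixations > 0 and rng.uniform() < config.inject_long_fixations:
                    dur = float(rng.uniform(1001.0, 1600.0))
                elif config.inject_short_fixations > 0 and rng.uniform() < config.inject_short_fixations:
                    dur = float(rng.uniform(20.0, 59.0))
                sent_fix.append(FixationEvent(
                    onset_ms=fix_onset, duration_ms=dur, sentence_id=sid, word_idx=word,
                    is_post_regression=is_reg, is_sentence_final=is_final, block_id=b))
                # next saccade onset: gamma renewal interval, kept clear of
                # the current saccade itself
                isi = rng.gamma(shape, mean_isi / shape) if shape != 1.0 else rng.exponential(mean_isi)
                # minimal anti-collision clamp only; a physiological refractory
                # floor would distort the exponential (Poisson) null condition
                t += max(isi, 2.0)

            fixations.extend(sent_fix)
            span_end = sent_fix[-1].onset_ms + sent_fix[-1].duration_ms
            spans.append(SentenceSpan(sentence_id=sid, block_id=b,
                                      t_start_ms=sent_fix[0].onset_ms,
                                      t_end_ms=span_end, n_words=n_words))
            # advance by the EXPECTED final duration: feeding the realized
            # (modulated) duration back into the clock would entrain sentence
            # onsets to the duration modulation (a circle-map attractor) and
            # plant a boundary phase effect even at zero boundary locking
            t = (sent_fix[-1].onset_ms + config.mean_fix_ms
                 + config.final_lengthening_ms + config.sentence_gap_ms)
            sid += 1
        markers.append((f"block{b}_end", t))
        t += config.block_gap_ms
    return fixations, saccades, spans, markers


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, sd: float) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, unit-free, scaled to sd."""
    white = rng.standard_normal(n)
    if exponent == 0 or sd == 0:
        return sd * white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    s = x.std()
    return sd * x / s if s > 0 else x


def _entrained_phase_trajectory(
    t_ms: np.ndarray, freq_hz: float, event_times_ms: np.ndarray, event_angles: np.ndarray,
) -> np.ndarray:
    """Smooth phase trajectory of an oscillator entrained to events.

    The instantaneous phase equals ``event_angles[k]`` (mod 2pi) exactly at
    ``event_times_ms[k]`` and advances continuously and monotonically in
    between, completing the number of cycles closest to ``freq_hz`` times
    the interval. This is frequency modulation rather than hard phase
    resets, so the signal stays narrowband around ``freq_hz``.
    """
    omega = 2.0 * np.pi * freq_hz / 1000.0
    if len(event_times_ms) == 0:
        return omega * t_ms
    # unwrap target angles into a monotone phase sequence
    unwrapped = np.empty(len(event_times_ms))
    unwrapped[0] = event_angles[0]
    for k in range(1, len(event_times_ms)):
        dt = event_times_ms[k] - event_times_ms[k - 1]
        delta = np.angle(np.exp(1j * (event_angles[k] - unwrapped[k - 1])))
        n_cycles = max(round((omega * dt - delta) / (2.0 * np.pi)), 1)
        unwrapped[k] = unwrapped[k - 1] + 2.0 * np.pi * n_cycles + delta
    phase = np.interp(t_ms, event_times_ms, unwrapped)
    before = t_ms < event_times_ms[0]
    phase[before] = unwrapped[0] + omega * (t_ms[before] - event_times_ms[0])
    after = t_ms > event_times_ms[-1]
    phase[after] = unwrapped[-1] + omega * (t_ms[after] - event_times_ms[-1])
    return phase


def _mixing_matrix(config: SimulationConfig, labels: list[str]) -> np.ndarray:
    """Per-scalp-channel EOG leakage gains, (n_scalp, n_eog)."""
    n_scalp = len(labels)
    spec = config.eog_mixing
    row_gain = {"F": 0.30, "C": 0.15, "P": 0.06, "O": 0.03}
    col_profile = np.array([1.0, 0.6][: config.n_eog] + [0.5] * max(config.n_eog - 2, 0))
    if spec is None or (isinstance(spec, (int, float)) and float(spec) == 0.0):
        return np.zeros((n_scalp, config.n_eog))
    if isinstance(spec, str) and spec == "gradient":
        scale = 1.0
    elif isinstance(spec, (int, float)):
        scale = float(spec)
    else:
        m = np.asarray(spec, dtype=float)
        if m.shape != (n_scalp, config.n_eog):
            raise ValueError(f"eog_mixing matrix must be {(n_scalp, config.n_eog)}, got {m.shape}")
        return m
    gains = np.array([row_gain[l[0]] for l in labels])
    return scale * gains[:, None] * col_profile[None, :]


def simulate_eeg(
    config: SimulationConfig,
    fixations: list[FixationEvent],
    saccades: list[SaccadeEvent],
    spans: list[SentenceSpan],
    markers: list[tuple[str, float]],
    participant: int,
) -> tuple[EEGRecording, np.ndarray, np.ndarray, dict[str, Any]]:
    """Generate the EEG/EOG recording coupled to an event stream.

    Returns ``(recording, gaze_x, gaze_y, truth)`` with gaze traces on the
    eye-tracker clock at ``eye_rate_hz``.
    """
    if not fixations or not saccades:
        raise ValueError("cannot simulate EEG without ocular events")
    rng = _rng(config, participant, 1)
    phi_p = _modulation_phase(config, participant)
    rate = config.eeg_rate_hz
    offset, drift = config.clock_offset_ms, config.clock_drift

    t_max_eye = max(fixations[-1].onset_ms + fixations[-1].duration_ms,
                    max(t for _, t in markers))
    n_samp = int(math.ceil((offset + drift * (t_max_eye + 2000.0)) / 1000.0 * rate))
    t_eeg_ms = np.arange(n_samp) * (1000.0 / rate)
    t_eye_ms = (t_eeg_ms - offset) / drift  # EEG samples mapped back to the eye clock

    labels, layout = default_layout(config.n_channels)
    theta_ch = (list(config.theta_channels) if config.theta_channels is not None
                else [l for l in labels if l[0] in ("P", "O")])
    delta_ch = (list(config.delta_channels) if config.delta_channels is not None
                else [l for l in labels if l[0] == "O"])

    data = np.empty((config.n_channels + config.n_eog, n_samp))
    for ci in range(config.n_channels):
        data[ci] = _pink_noise(rng, n_samp, config.noise_exponent, config.noise_sd)

    # --- theta component: one oscillator entrained to saccade onsets ------
    sacc_onsets = np.array([s.onset_ms for s in saccades])
    theta_angles = _von_mises(rng, config.theta_lock_kappa, len(sacc_onsets))
    theta_phase = _entrained_phase_trajectory(
        t_eye_ms, config.theta_freq_hz, sacc_onsets, theta_angles)
    theta_sig = config.theta_amp * np.cos(theta_phase)

    # --- delta component: coherent with the duration modulation ----------
    w = float(i1(config.delta_lock_kappa) / i0(config.delta_lock_kappa)) \
        if config.delta_lock_kappa > 0 else 0.0
    base_phase = 2.0 * np.pi * config.fixdiff_rhythm_hz * t_eye_ms / 1000.0 + phi_p
    corr = np.zeros(n_samp)
    final_onsets = np.array([f.onset_ms for f in fixations if f.is_sentence_final])
    boundary_angles = np.empty(0)
    if config.boundary_lock_kappa > 0 and len(final_onsets):
        lead_ms, relax_ms = 300.0, 1500.0
        boundary_angles = _von_mises(rng, config.boundary_lock_kappa, len(final_onsets))
        omega = 2.0 * np.pi * config.fixdiff_rhythm_hz / 1000.0
        for tf, ang in zip(final_onsets, boundary_angles):
            tr = tf - lead_ms
            i0_, i1_ = np.searchsorted(t_eye_ms, [tr, tr + relax_ms])
            if i0_ >= i1_:
                continue
            # phase the base trajectory would have at the reset time
            base_at = omega * tr + phi_p
            target = ang - omega * lead_ms  # so that phase(tf) == ang
            jump = np.angle(np.exp(1j * (target - base_at)))
            decay = 1.0 - (t_eye_ms[i0_:i1_] - tr) / relax_ms
            corr[i0_:i1_] = jump * decay
    # incoherent part: same centre frequency, slowly diffusing phase
    psi = np.cumsum(rng.normal(0.0, np.pi / math.sqrt(5.0 * rate), n_samp))
    psi += rng.uniform(0.0, 2.0 * np.pi)
    delta_sig = config.delta_amp * (
        w * np.cos(base_phase + corr) + math.sqrt(max(1.0 - w * w, 0.0)) * np.cos(base_phase + psi)
    )

    for ci, label in enumerate(labels):
        if label in theta_ch:
            data[ci] += theta_sig
        if label in delta_ch:
            data[ci] += delta_sig

    # --- gaze traces and EOG ---------------------------------------------
    gaze_x, gaze_y = _gaze_traces(config, fixations, spans, t_max_eye, rng)
    t_gaze_ms = np.arange(len(gaze_x)) * (1000.0 / config.eye_rate_hz)
    ok = ~np.isnan(gaze_x)
    gx_eeg = np.interp(t_eye_ms, t_gaze_ms[ok], gaze_x[ok])
    ok = ~np.isnan(gaze_y)
    gy_eeg = np.interp(t_eye_ms, t_gaze_ms[ok], gaze_y[ok])
    eog_labels = ["hEOG", "vEOG"][: config.n_eog] + [
        f"EOG{k}" for k in range(3, config.n_eog + 1)]
    eog_clean = np.vstack([config.eog_amp * gx_eeg, config.eog_amp * gy_eeg] +
                          [config.eog_amp * gx_eeg] * max(config.n_eog - 2, 0))[: config.n_eog]
    eog = eog_clean + rng.normal(0.0, config.eog_noise_sd, (config.n_eog, n_samp))
    data[config.n_channels:] = eog

    mixing = _mixing_matrix(config, labels)
    data[: config.n_channels] += mixing @ eog

    events = [(label, int(round((offset + drift * t) / 1000.0 * rate)))
              for label, t in markers]
    rec = EEGRecording(
        data=data,
        rate_hz=rate,
        channel_labels=labels + eog_labels,
        channel_kinds=["scalp"] * config.n_channels + ["eog"] * config.n_eog,
        events=events,
        layout=layout,
    )
    if rec.duration_ms < offset + drift * t_max_eye:
        raise ValueError("EEG recording shorter than the ocular event span")
    truth = {
        "phi_p": phi_p,
        "theta_channels": theta_ch,
        "delta_channels": delta_ch,
        "delta_coherent_weight": w,
        "theta_freq_hz": config.theta_freq_hz,
        "fixdiff_rhythm_hz": config.fixdiff_rhythm_hz,
        "eog_mixing_matrix": mixing.tolist(),
        "clock_offset_ms": offset,
        "clock_drift": drift,
        "n_boundary_resets": int(len(boundary_angles)),
    }
    return rec, gaze_x, gaze_y, truth


def _gaze_traces(
    config: SimulationConfig,
    fixations: list[FixationEvent],
    spans: list[SentenceSpan],
    t_max_eye: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Step-wise latent gaze: word position (x) and sentence line (y)."""
    rate = config.eye_rate_hz
    n = int(math.ceil((t_max_eye + 500.0) / 1000.0 * rate))
    gaze_x = np.zeros(n)
    gaze_y = np.zeros(n)
    n_words = {s.sentence_id: max(s.n_words, 1) for s in spans}
    onsets = np.array([f.onset_ms for f in fixations])
    idx = np.minimum((onsets / 1000.0 * rate).round().astype(int), n - 1)
    xs = np.array([2.0 * f.word_idx / n_words[f.sentence_id] - 1.0 for f in fixations])
    ys = np.array([2.0 * (f.sentence_id % 10) / 9.0 - 1.0 for f in fixations])
    start = 0
    for k in range(len(fixations)):
        stop = idx[k + 1] if k + 1 < len(fixations) else n
        gaze_x[max(idx[k], start):stop] = xs[k]
        gaze_y[max(idx[k], start):stop] = ys[k]
        start = max(idx[k], start)
    # ~1% of samples lost by the tracker
    lost = rng.uniform(size=n) < 0.01
    gaze_x[lost] = np.nan
    gaze_y[lost] = np.nan
    return gaze_x, gaze_y


def simulate_session(config: SimulationConfig, participant: int) -> ReadingSession:
    """Full co-registered session; deterministic given ``(config.seed, participant)``."""
    fixations, saccades, spans, markers = simulate_eye_events(config, participant)
    eeg, gaze_x, gaze_y, truth = simulate_eeg(
        config, fixations, saccades, spans, markers, participant)
    truth.update(config.to_dict())
    return ReadingSession(
        participant_id=participant,
        fixations=fixations,
        saccades=saccades,
        sentences=spans,
        eeg=eeg,
        eye_markers=markers,
        gaze_x=gaze_x,
        gaze_y=gaze_y,
        gaze_rate_hz=config.eye_rate_hz,
        truth=truth,
    )
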