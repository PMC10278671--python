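"""Pipeline driver: chains simulation, event filtering, series construction,
surrogate spectral inference, EEG conditioning, the two eye-EEG synchrony
analyses, and the boundary phase test, and emits a JSON-serializable run
report with every stage's parameters, seeds, and removal bookkeeping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from .boundary import (
    BoundaryPhaseResult,
    boundary_clustering_test,
    butter_lowpass_twopass,
    hilbert_phase,
    phases_at_events,
)
from .coherence import (
    PhaseCoherenceResult,
    channel_adjacency_from_layout,
    cluster_permutation_test,
    ispc_shift_null,
    multitaper_sentence_coherence,
    nontarget_baseline,
    saccade_locked_ispc,
)
from .config import RunConfig
from .eeg import EEGRecording, read_eeg, write_eeg
from .events import read_events, write_events
from .eye_series import (
    EyeSeries,
    build_fixdiff_series,
    build_saccade_train,
    downsample_fixdiff,
    exclude_post_regression,
    filter_fixations,
    filter_saccades,
)
from .prep import (
    ClockMap,
    eog_gaze_correlation,
    notch_filter,
    regress_eog,
    synchronize,
    zero_phase_highpass,
)
from .spectral import group_psd_test, psd_with_surrogates
from .synthetic import ReadingSession, simulate_session
from .tfr import morlet_tfr

logger = logging.getLogger(__name__)

__all__ = [
    "EyeStage",
    "prepare_eye",
    "group_spectra",
    "prep_eeg",
    "ispc_group",
    "coherence_group",
    "boundary_group",
    "run_pipeline",
    "save_session",
    "load_session",
]


# ---------------------------------------------------------------------------
# per-participant eye stage
# ---------------------------------------------------------------------------
@dataclass
class EyeStage:
    """Filtered events and derived series for one participant."""

    session: ReadingSession
    fixations: list  # duration-filtered
    fixations_clean: list  # additionally post-regression-excluded
    saccades: list
    train: EyeSeries
    fixdiff: EyeSeries
    report: dict


def _block_intervals(session: ReadingSession) -> list[tuple[float, float]]:
    starts = {int(l.split("_")[0][5:]): t for l, t in session.eye_markers if l.endswith("start")}
    ends = {int(l.split("_")[0][5:]): t for l, t in session.eye_markers if l.endswith("end")}
    return [(starts[b], ends[b]) for b in sorted(starts) if b in ends]


def prepare_eye(session: ReadingSession, cfg: RunConfig) -> EyeStage:
    fix_kept, fix_report = filter_fixations(session.fixations)
    sacc_kept, sacc_report = filter_saccades(session.saccades)
    fix_clean = exclude_post_regression(fix_kept)
    intervals = _block_intervals(session)
    t1 = max(s.onset_ms for s in sacc_kept) + 1000.0
    train = build_saccade_train(sacc_kept, cfg.train_rate_hz, (0.0, t1), intervals)
    fixdiff = build_fixdiff_series(fix_clean, cfg.fixdiff_rate_hz, (0.0, t1))
    n_reg = len(fix_kept) - len(fix_clean)
    return EyeStage(
        session=session,
        fixations=fix_kept,
        fixations_clean=fix_clean,
        saccades=sacc_kept,
        train=train,
        fixdiff=fixdiff,
        report={
            "fixations_removed_frac": fix_report.fraction,
            "saccades_removed_frac": sacc_report.fraction,
            "post_regression_frac": n_reg / len(fix_kept) if fix_kept else 0.0,
            "n_fixations": len(fix_kept),
            "n_saccades": len(sacc_kept),
        },
    )


# ---------------------------------------------------------------------------
# group spectral inference
# ---------------------------------------------------------------------------
def group_spectra(eye_stages: list[EyeStage], cfg: RunConfig, kind: str, seed: int):
    """Group PSD inference for one series kind across participants."""
    obs, surr, freqs = [], [], None
    for i, st in enumerate(eye_stages):
        if kind == "saccade_train":
            f, o, s = psd_with_surrogates(
                "saccade_train", cfg.train_rate_hz,
                cfg.welch_window_saccade_ms, cfg.welch_overlap_saccade_ms,
                cfg.n_surrogates, seed + 7919 * i + 1, cfg.psd_fmax_hz, series=st.train)
        else:
            f, o, s = psd_with_surrogates(
                "fixdiff", cfg.fixdiff_rate_hz,
                cfg.welch_window_fixdiff_ms, cfg.welch_overlap_fixdiff_ms,
                cfg.n_surrogates, seed + 7919 * i + 2, cfg.psd_fmax_hz,
                series=st.fixdiff, fixations=st.fixations_clean,
                span_ms=(st.fixdiff.t0_ms,
                         st.fixdiff.t0_ms + (len(st.fixdiff.values) - 1)
                         * 1000.0 / st.fixdiff.rate_hz))
        freqs = f
        obs.append(o)
        surr.append(s)
    return group_psd_test(freqs, np.array(obs), np.array(surr), q=cfg.fdr_q,
                          params={"kind": kind, "seed": seed})


# ---------------------------------------------------------------------------
# EEG conditioning
# ---------------------------------------------------------------------------
@dataclass
class PrepStage:
    eeg: EEGRecording
    clock_map: ClockMap
    removed_variance: dict[str, float]
    gaze_correlation: Any


def prep_eeg(session: ReadingSession, cfg: RunConfig) -> PrepStage:
    eeg = session.eeg
    eeg = zero_phase_highpass(eeg, cfg.highpass_hz, cfg.highpass_order)
    if cfg.notch_hz and cfg.notch_hz + cfg.notch_half_width_hz < eeg.rate_hz / 2:
        eeg = notch_filter(eeg, cfg.notch_hz, cfg.notch_half_width_hz, cfg.notch_order)
    eeg, removed = regress_eog(eeg)
    cmap = synchronize(eeg.events, session.eye_markers, eeg.rate_hz)
    corr = eog_gaze_correlation(eeg, session.gaze_x, session.gaze_y,
                                session.gaze_rate_hz, cmap)
    return PrepStage(eeg=eeg, clock_map=cmap, removed_variance=removed,
                     gaze_correlation=corr)


def _freq_grid(cfg: RunConfig) -> np.ndarray:
    return np.arange(cfg.freq_min_hz, cfg.freq_max_hz + cfg.freq_step_hz / 2,
                     cfg.freq_step_hz)


# ---------------------------------------------------------------------------
# saccade-locked ISPC
# ---------------------------------------------------------------------------
def ispc_group(
    eye_stages: list[EyeStage],
    preps: list[PrepStage],
    cfg: RunConfig,
    seed: int,
) -> tuple[list[PhaseCoherenceResult], list]:
    """Per-participant ISPC and the group cluster test on observed-baseline."""
    freqs = _freq_grid(cfg)
    results, diffs = [], []
    for st, pp in zip(eye_stages, preps):
        scalp = pp.eeg.scalp_indices
        tfr = morlet_tfr(pp.eeg.data[scalp], pp.eeg.rate_hz, freqs, cfg.n_cycles,
                         [pp.eeg.channel_labels[i] for i in scalp])
        onsets = pp.clock_map.to_eeg_sample(
            np.array([s.onset_ms for s in st.saccades]), pp.eeg.rate_hz)
        res = saccade_locked_ispc(tfr, onsets, cfg.ispc_window_ms, cfg.ispc_lag_step)
        floor = ispc_shift_null(tfr, onsets, cfg.ispc_window_ms, cfg.ispc_lag_step,
                                cfg.ispc_n_shift_null, seed)
        corrected = res.values - floor
        res.baseline = floor + nontarget_baseline(corrected, freq_axis=1)
        results.append(res)
        diffs.append(corrected - nontarget_baseline(corrected, freq_axis=1))
    eeg0 = preps[0].eeg
    labels = [eeg0.channel_labels[i] for i in eeg0.scalp_indices]
    adj = channel_adjacency_from_layout(eeg0.layout, labels)
    clusters = cluster_permutation_test(np.array(diffs), adj, cfg.cluster_alpha,
                                        cfg.n_cluster_perm, seed)
    return results, clusters


# ---------------------------------------------------------------------------
# sentence-epoch coherence
# ---------------------------------------------------------------------------
def _paired_sentence_epochs(
    st: EyeStage, pp: PrepStage, cfg: RunConfig
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """EEG and fixdiff epochs per sentence, sample-aligned at the combined rate."""
    fix500 = downsample_fixdiff(st.fixdiff, cfg.combined_rate_hz) \
        if st.fixdiff.rate_hz != cfg.combined_rate_hz else st.fixdiff
    scalp = pp.eeg.scalp_indices
    eeg_epochs, eye_epochs = [], []
    for span in st.session.sentences:
        if span.duration_ms < 1000.0 * cfg.min_sentence_s:
            continue
        i0 = int(fix500.sample_index(span.t_start_ms))
        i1 = int(fix500.sample_index(span.t_end_ms)) + 1
        i0, i1 = max(i0, 0), min(i1, len(fix500.values))
        m = fix500.defined_mask[i0:i1]
        if not m.any():
            continue
        first = i0 + int(np.argmax(m))
        last = i1 - int(np.argmax(m[::-1]))
        if (last - first) < cfg.min_sentence_s * cfg.combined_rate_hz:
            continue
        t_first = fix500.t0_ms + first * 1000.0 / fix500.rate_hz
        s0 = int(pp.clock_map.to_eeg_sample(t_first, pp.eeg.rate_hz))
        n = last - first
        if s0 < 0 or s0 + n > pp.eeg.n_samples:
            continue
        eye_epochs.append(fix500.values[first:last])
        eeg_epochs.append(pp.eeg.data[scalp, s0: s0 + n])
    return eeg_epochs, eye_epochs


def coherence_group(
    eye_stages: list[EyeStage],
    preps: list[PrepStage],
    cfg: RunConfig,
    seed: int,
) -> tuple[list[PhaseCoherenceResult], list]:
    freqs = _freq_grid(cfg)
    results, diffs = [], []
    for st, pp in zip(eye_stages, preps):
        eeg_eps, eye_eps = _paired_sentence_epochs(st, pp, cfg)
        scalp = pp.eeg.scalp_indices
        res = multitaper_sentence_coherence(
            eeg_eps, eye_eps, cfg.combined_rate_hz, freqs, cfg.mt_smoothing_hz,
            [pp.eeg.channel_labels[i] for i in scalp])
        res.baseline = nontarget_baseline(res.values, freq_axis=1)
        results.append(res)
        diffs.append(res.values - res.baseline)
    eeg0 = preps[0].eeg
    labels = [eeg0.channel_labels[i] for i in eeg0.scalp_indices]
    adj = channel_adjacency_from_layout(eeg0.layout, labels)
    clusters = cluster_permutation_test(np.array(diffs), adj, cfg.cluster_alpha,
                                        cfg.n_cluster_perm, seed)
    return results, clusters


# ---------------------------------------------------------------------------
# boundary phase clustering
# ---------------------------------------------------------------------------
def _default_boundary_electrodes(
    coh_results: list[PhaseCoherenceResult], clusters: list, cfg: RunConfig
) -> list[str]:
    """Electrodes of the strongest significant low-frequency coherence cluster;
    falls back to the channel with maximal low-frequency group coherence."""
    labels = coh_results[0].channel_labels
    freqs = coh_results[0].freqs_hz
    low = freqs <= cfg.boundary_cutoff_hz
    for cl in clusters:
        if cl.p <= 0.05:
            ch_idx, f_idx = cl.cells[0], cl.cells[1]
            in_low = low[f_idx]
            if in_low.any():
                return sorted({labels[i] for i in ch_idx[in_low]},
                              key=labels.index)
    group = np.mean([r.values for r in coh_results], axis=0)
    best = int(np.argmax(group[:, low].max(axis=1)))
    return [labels[best]]


def boundary_group(
    eye_stages: list[EyeStage],
    preps: list[PrepStage],
    cfg: RunConfig,
    electrodes: list[str],
    seed: int,
    include_fixdiff: bool = True,
) -> dict[str, BoundaryPhaseResult]:
    """Boundary phase test on EEG electrodes and (optionally) the fixdiff series."""
    fin_eeg, non_eeg, fin_eye, non_eye = [], [], [], []
    for st, pp in zip(eye_stages, preps):
        finals = np.array([f.onset_ms for f in st.fixations if f.is_sentence_final])
        nonfinals = np.array([f.onset_ms for f in st.fixations if not f.is_sentence_final])
        # EEG electrodes: low-pass, analytic phase, angles at event samples
        sig = pp.eeg.pick(electrodes)
        filt = butter_lowpass_twopass(sig, pp.eeg.rate_hz, cfg.boundary_cutoff_hz,
                                      cfg.boundary_order)
        ph = hilbert_phase(filt)
        fin_ms = pp.clock_map.to_eeg_ms(finals)
        non_ms = pp.clock_map.to_eeg_ms(nonfinals)
        fin_eeg.append(phases_at_events(ph, fin_ms, pp.eeg.rate_hz))
        non_eeg.append(phases_at_events(ph, non_ms, pp.eeg.rate_hz))
        if include_fixdiff:
            dm = st.fixdiff.defined_mask
            vals = st.fixdiff.values
            filt_e = butter_lowpass_twopass(vals, st.fixdiff.rate_hz,
                                            cfg.boundary_cutoff_hz, cfg.boundary_order)
            ph_e = hilbert_phase(filt_e)
            idx_ok = lambda ts: ts[(st.fixdiff.sample_index(ts) >= 0)
                                   & (st.fixdiff.sample_index(ts) < len(vals))
                                   & dm[np.clip(st.fixdiff.sample_index(ts), 0, len(vals) - 1)]]
            fin_eye.append(phases_at_events(ph_e[None, :], idx_ok(finals),
                                            st.fixdiff.rate_hz, st.fixdiff.t0_ms))
            non_eye.append(phases_at_events(ph_e[None, :], idx_ok(nonfinals),
                                            st.fixdiff.rate_hz, st.fixdiff.t0_ms))
    out = {
        "eeg": boundary_clustering_test(fin_eeg, non_eeg, electrodes,
                                        cfg.n_boundary_draws, seed, cfg.fdr_q)
    }
    if include_fixdiff:
        out["fixdiff"] = boundary_clustering_test(
            fin_eye, non_eye, ["fixdiff"], cfg.n_boundary_draws, seed + 1, cfg.fdr_q)
    return out


# ---------------------------------------------------------------------------
# session persistence
# ---------------------------------------------------------------------------
def save_session(session: ReadingSession, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = session.participant_id
    write_events(session.fixations, session.saccades,
                 out / f"p{p}_fixations.tsv", out / f"p{p}_saccades.tsv", p)
    write_eeg(session.eeg, out / f"p{p}_eeg")
    meta = {
        "participant": p,
        "sentences": [[s.sentence_id, s.block_id, s.t_start_ms, s.t_end_ms, s.n_words]
                      for s in session.sentences],
        "eye_markers": [[l, t] for l, t in session.eye_markers],
        "gaze_rate_hz": session.gaze_rate_hz,
        "truth": _jsonable(session.truth),
    }
    with open(out / f"p{p}_meta.json", "w") as fh:
        json.dump(meta, fh)
    np.savetxt(out / f"p{p}_gaze.csv",
               np.column_stack([session.gaze_x, session.gaze_y]),
               delimiter=",", header="gaze_x,gaze_y", comments="", fmt="%.5g")


def load_session(out_dir: str | Path, participant: int) -> ReadingSession:
    from .events import SentenceSpan

    out = Path(out_dir)
    p = participant
    fixations, saccades = read_events(out / f"p{p}_fixations.tsv",
                                      out / f"p{p}_saccades.tsv")
    eeg = read_eeg(out / f"p{p}_eeg")
    with open(out / f"p{p}_meta.json") as fh:
        meta = json.load(fh)
    gaze = np.loadtxt(out / f"p{p}_gaze.csv", delimiter=",", skiprows=1, ndmin=2)
    return ReadingSession(
        participant_id=p,
        fixations=fixations,
        saccades=saccades,
        sentences=[SentenceSpan(*row) for row in meta["sentences"]],
        eeg=eeg,
        eye_markers=[(l, float(t)) for l, t in meta["eye_markers"]],
        gaze_x=gaze[:, 0],
        gaze_y=gaze[:, 1],
        gaze_rate_hz=float(meta["gaze_rate_hz"]),
        truth=meta.get("truth", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------
def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every enabled stage on a simulated cohort; return the report."""
    report: dict[str, Any] = {"config": cfg.to_dict(), "seed": cfg.seed, "stages": {}}
    sim = cfg.simulation
    if not cfg.do_simulate:
        raise ValueError("run_pipeline currently drives simulated cohorts; "
                         "enable do_simulate")
    sessions = [simulate_session(sim, p) for p in range(sim.n_participants)]
    eye_stages = [prepare_eye(s, cfg) for s in sessions]
    report["stages"]["eye"] = {
        "per_participant": [st.report for st in eye_stages],
        "mean_fixations_removed_frac": float(np.mean(
            [st.report["fixations_removed_frac"] for st in eye_stages])),
        "mean_saccades_removed_frac": float(np.mean(
            [st.report["saccades_removed_frac"] for st in eye_stages])),
        "mean_post_regression_frac": float(np.mean(
            [st.report["post_regression_frac"] for st in eye_stages])),
    }

    if cfg.do_psd:
        for kind, key in (("saccade_train", "psd_saccade"), ("fixdiff", "psd_fixdiff")):
            inf = group_spectra(eye_stages, cfg, kind, cfg.seed)
            peak = float(inf.freqs_hz[int(np.argmax(
                inf.observed_group_mean / np.maximum(
                    inf.surrogate_group_means.mean(axis=0), 1e-30)))])
            report["stages"][key] = {
                "significant_freqs_hz": inf.significant_freqs_hz.tolist(),
                "peak_freq_hz": peak,
                "n_perm": inf.params["n_perm"],
                "seed": cfg.seed,
            }

    preps = None
    if cfg.do_prep or cfg.do_ispc or cfg.do_coherence or cfg.do_boundary:
        preps = [prep_eeg(s, cfg) for s in sessions]
        report["stages"]["prep"] = {
            "clock_offset_ms": [p.clock_map.offset_ms for p in preps],
            "clock_drift": [p.clock_map.drift for p in preps],
            "eog_gaze_r_horizontal": [p.gaze_correlation.r_horizontal for p in preps],
            "eog_gaze_r_vertical": [p.gaze_correlation.r_vertical for p in preps],
            "removed_variance_top": sorted(
                preps[0].removed_variance, key=preps[0].removed_variance.get,
                reverse=True)[:4],
        }

    if cfg.do_ispc:
        ispc_results, ispc_clusters = ispc_group(eye_stages, preps, cfg, cfg.seed)
        report["stages"]["ispc"] = _cluster_report(ispc_results, ispc_clusters)

    coh_results = coh_clusters = None
    if cfg.do_coherence:
        coh_results, coh_clusters = coherence_group(eye_stages, preps, cfg, cfg.seed)
        report["stages"]["coherence"] = _cluster_report(coh_results, coh_clusters)

    if cfg.do_boundary:
        if coh_results is not None:
            electrodes = _default_boundary_electrodes(coh_results, coh_clusters, cfg)
        else:
            electrodes = sessions[0].truth.get("delta_channels", ["O1"])
        bres = boundary_group(eye_stages, preps, cfg, electrodes, cfg.seed)
        report["stages"]["boundary"] = {
            "electrodes": electrodes,
            "eeg_mean_z": bres["eeg"].observed_z.tolist(),
            "eeg_p": bres["eeg"].p.tolist(),
            "eeg_fdr_significant": bres["eeg"].fdr_mask.tolist(),
            "fixdiff_mean_z": bres["fixdiff"].observed_z.tolist(),
            "fixdiff_p": bres["fixdiff"].p.tolist(),
            "n_final_per_participant": bres["eeg"].n_final,
            "seed": cfg.seed,
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
    return report


def _cluster_report(results, clusters) -> dict:
    group = np.mean([r.values for r in results], axis=0)
    labels = results[0].channel_labels
    freqs = results[0].freqs_hz
    flat = np.unravel_index(int(np.argmax(group)), group.shape)
    rep = {
        "n_epochs": [r.n_epochs for r in results],
        "peak_channel": labels[flat[0]],
        "peak_freq_hz": float(freqs[flat[1]]),
        "clusters": [
            {"sum_t": c.sum_t, "p": c.p, "n_cells": int(len(c.cells[0]))}
            for c in clusters
        ],
    }
    if results[0].lags_ms is not None and len(flat) > 2:
        rep["peak_lag_ms"] = float(results[0].lags_ms[flat[2]])
    return rep
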