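"""Configuration objects for the simulator and the pipeline driver."""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimulationConfig", "RunConfig"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic co-registered reading session generator.

    Defaults emulate a naturalistic-reading corpus: a dozen participants
    reading ~300 sentences in six blocks, eye-tracking and EEG both sampled
    at 500 Hz, fixations of ~220 ms (SD 25 ms), ~21% regressive saccades,
    and sentences read in ~7.4 s on average. Rhythmic structure is planted
    explicitly: a ~4.4 Hz saccadic rhythm (gamma renewal process), a ~1 Hz
    sinusoidal modulation of fixation durations, EEG theta/delta components
    phase-locked to those behavioral rhythms, and delta phase concentration
    at sentence-final word onsets.
    """

    # cohort / session structure
    n_participants: int = 12
    n_sentences: int = 300
    n_blocks: int = 6
    words_per_sentence_mean: float = 26.0
    words_per_sentence_sd: float = 9.0
    sentence_gap_ms: float = 400.0
    block_gap_ms: float = 5000.0

    # sampling rates
    eye_rate_hz: float = 500.0
    eeg_rate_hz: float = 500.0

    # ocular event model
    mean_fix_ms: float = 220.0
    sd_fix_ms: float = 25.0
    sacc_rhythm_hz: float = 4.4
    sacc_interval_shape: float = 10.0  # gamma shape; 1 -> Poisson (exponential) process
    mean_sacc_ms: float = 30.0
    sd_sacc_ms: float = 5.0
    fixdiff_rhythm_hz: float = 1.0
    fixdiff_amp_ms: float = 40.0
    p_regression: float = 0.21
    final_lengthening_ms: float = 60.0

    # EEG model
    n_channels: int = 16
    n_eog: int = 2
    theta_freq_hz: float = 5.0
    theta_amp: float = 1.0
    delta_amp: float = 1.0
    theta_lock_kappa: float = 4.0
    delta_lock_kappa: float = 4.0
    boundary_lock_kappa: float = 3.0
    theta_channels: tuple[str, ...] | None = None  # None -> posterior rows (P*, O*)
    delta_channels: tuple[str, ...] | None = None  # None -> occipital row (O*)
    eog_mixing: Any = "gradient"  # "gradient", scalar gain, 0, or full matrix
    eog_amp: float = 100.0
    eog_noise_sd: float = 20.0
    noise_exponent: float = 1.0
    noise_sd: float = 1.0

    # clock relation between eye-tracker and EEG
    clock_offset_ms: float = 1000.0
    clock_drift: float = 1.0

    # artifact injection for filter testing (fractions of events made out-of-range)
    inject_long_fixations: float = 0.0
    inject_short_fixations: float = 0.0
    inject_long_saccades: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("eye_rate_hz", "eeg_rate_hz", "sacc_rhythm_hz"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not math.isfinite(self.fixdiff_rhythm_hz) or self.fixdiff_rhythm_hz <= 0:
            raise ValueError("fixdiff_rhythm_hz must be finite and > 0")
        if self.sacc_rhythm_hz <= self.fixdiff_rhythm_hz:
            raise ValueError(
                "sacc_rhythm_hz must exceed fixdiff_rhythm_hz "
                f"({self.sacc_rhythm_hz} <= {self.fixdiff_rhythm_hz})"
            )
        if not (0.0 <= self.p_regression < 1.0):
            raise ValueError(f"p_regression must be in [0, 1), got {self.p_regression}")
        for name in ("theta_lock_kappa", "delta_lock_kappa", "boundary_lock_kappa"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in (
            "mean_fix_ms",
            "sd_fix_ms",
            "fixdiff_amp_ms",
            "final_lengthening_ms",
            "noise_sd",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_participants < 1 or self.n_sentences < 1 or self.n_blocks < 1:
            raise ValueError("counts must be >= 1")
        if self.n_sentences % self.n_blocks:
            raise ValueError("n_sentences must be divisible by n_blocks")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        kwargs = dict(d)
        for k in ("theta_channels", "delta_channels"):
            if kwargs.get(k) is not None:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


@dataclass
class RunConfig:
    """Full pipeline configuration.

    Stage parameter defaults follow the analysis conventions this package
    implements: Welch windows of 4096 ms (saccade train) and 8192 ms
    (fixation-duration differences) with half-window overlap, saccade-locked
    epochs of +/-200 ms, a 0.5-10 Hz wavelet/multitaper grid in 0.5 Hz steps
    with 0.5 Hz spectral smoothing, a 2.5 Hz low-pass for boundary phase,
    1000 spectral surrogates, 4096 cluster permutations, 1000 boundary
    draws, and a 2 s minimum sentence reading duration.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    # stage toggles
    do_simulate: bool = True
    do_psd: bool = True
    do_prep: bool = True
    do_ispc: bool = True
    do_coherence: bool = True
    do_boundary: bool = True

    # eye-series construction
    train_rate_hz: float = 1000.0
    fixdiff_rate_hz: float = 1000.0
    combined_rate_hz: float = 500.0

    # spectral inference
    welch_window_saccade_ms: float = 4096.0
    welch_overlap_saccade_ms: float = 2048.0
    welch_window_fixdiff_ms: float = 8192.0
    welch_overlap_fixdiff_ms: float = 4096.0
    n_surrogates: int = 1000
    fdr_q: float = 0.05
    psd_fmax_hz: float = 15.0

    # EEG prep
    highpass_hz: float = 0.1
    highpass_order: int | None = None  # None -> scaled to sampling rate
    notch_hz: float = 50.0
    notch_half_width_hz: float = 3.0
    notch_order: int | None = None

    # time-frequency / coherence
    freq_min_hz: float = 0.5
    freq_max_hz: float = 10.0
    freq_step_hz: float = 0.5
    n_cycles: float = 5.0
    ispc_window_ms: float = 200.0
    ispc_lag_step: int = 1
    ispc_n_shift_null: int = 16  # circular-shift surrogates for the ISPC floor
    mt_smoothing_hz: float = 0.5
    min_sentence_s: float = 2.0
    n_cluster_perm: int = 4096
    cluster_alpha: float = 0.05

    # boundary phase
    boundary_cutoff_hz: float = 2.5
    boundary_order: int = 8
    n_boundary_draws: int = 1000

    seed: int = 0
    out_dir: str = "readrhythm_out"

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs = dict(d)
        if "simulation" in kwargs and isinstance(kwargs["simulation"], dict):
            kwargs["simulation"] = SimulationConfig.from_dict(kwargs["simulation"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
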