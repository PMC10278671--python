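"""Multichannel EEG/EOG container and on-disk formats.

The native interchange format is a plain-text pair: a columnar CSV of samples
(one column per channel, in microvolts) plus a JSON sidecar holding the
sampling rate, channel labels and kinds, shared-event markers, and the 2-D
sensor layout used for cluster adjacency. EDF files are read through MNE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["EEGRecording", "read_eeg", "write_eeg"]


@dataclass
class EEGRecording:
    data: np.ndarray  # (n_channels, n_samples), microvolts
    rate_hz: float
    channel_labels: list[str]
    channel_kinds: list[str]  # "scalp" | "eog"
    events: list[tuple[str, int]] = field(default_factory=list)  # (label, sample idx)
    layout: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if len(self.channel_kinds) != self.data.shape[0]:
            raise ValueError("channel_kinds length must match data rows")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")
        n = self.data.shape[1]
        for label, idx in self.events:
            if not (0 <= idx < n):
                raise ValueError(f"event {label!r} at sample {idx} outside recording")

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.rate_hz

    @property
    def scalp_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.channel_kinds) == "scalp")

    @property
    def eog_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.channel_kinds) == "eog")

    def pick(self, labels: list[str]) -> np.ndarray:
        idx = [self.channel_labels.index(l) for l in labels]
        return self.data[idx]

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return replace(self, data=data, events=list(self.events), layout=dict(self.layout))


def write_eeg(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as ``<path>.csv`` + ``<path>.json``."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix else path
    np.savetxt(
        base.with_suffix(".csv"),
        rec.data.T,
        delimiter=",",
        header=",".join(rec.channel_labels),
        comments="",
        fmt="%.6g",
    )
    sidecar = {
        "rate_hz": rec.rate_hz,
        "channel_labels": rec.channel_labels,
        "channel_kinds": rec.channel_kinds,
        "events": [[label, int(idx)] for label, idx in rec.events],
        "layout": {k: list(v) for k, v in rec.layout.items()},
        "n_samples": rec.n_samples,
    }
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_eeg(path: str | Path) -> EEGRecording:
    """Read a recording from CSV+JSON (native) or EDF (via MNE)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    base = path.with_suffix("") if path.suffix else path
    with open(base.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    data = np.loadtxt(base.with_suffix(".csv"), delimiter=",", skiprows=1, ndmin=2).T
    if data.shape[1] != sidecar["n_samples"]:
        raise ValueError(
            f"sidecar declares {sidecar['n_samples']} samples, CSV has {data.shape[1]}"
        )
    return EEGRecording(
        data=data,
        rate_hz=float(sidecar["rate_hz"]),
        channel_labels=list(sidecar["channel_labels"]),
        channel_kinds=list(sidecar["channel_kinds"]),
        events=[(label, int(idx)) for label, idx in sidecar["events"]],
        layout={k: (float(v[0]), float(v[1])) for k, v in sidecar.get("layout", {}).items()},
    )


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    kinds = ["eog" if t == "eog" else "scalp" for t in raw.get_channel_types()]
    events = []
    if raw.annotations is not None:
        for ann in raw.annotations:
            events.append((str(ann["description"]), int(round(ann["onset"] * raw.info["sfreq"]))))
    return EEGRecording(
        data=raw.get_data() * 1e6,  # MNE uses volts internally
        rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        channel_kinds=kinds,
        events=events,
    )
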