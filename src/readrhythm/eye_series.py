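"""Event filtering and conversion of ocular events into analyzable time series.

Two series are derived from the event stream of one participant:

* a binary saccade train, 1 at the sample nearest each saccade onset;
* a fixation-duration-difference ("fixdiff") series: the value
  ``duration_n - duration_{n-1}`` anchored at the onset of fixation ``n`` and
  linearly interpolated between anchors.

Both carry a ``defined_mask``: samples outside the interpolation support
(or between recording blocks) are undefined rather than zero, so spectral
estimates never see artificial flat stretches. Differences are never taken
across block boundaries (recalibration gaps are non-reading time) but are
taken across sentence boundaries within a block.

Event filters follow fixed duration criteria: fixations shorter than 60 ms
or longer than 1000 ms and saccades longer than 80 ms are discarded
(boundary values are kept), and the first fixation after each backward
saccade is excluded before the difference series is formed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .events import FixationEvent, SaccadeEvent, SentenceSpan

__all__ = [
    "EyeSeries",
    "RemovalReport",
    "filter_fixations",
    "filter_saccades",
    "exclude_post_regression",
    "build_saccade_train",
    "build_fixdiff_series",
    "epoch_series_by_sentence",
    "downsample_fixdiff",
]

logger = logging.getLogger(__name__)

FIX_MIN_MS = 60.0
FIX_MAX_MS = 1000.0
SACC_MAX_MS = 80.0


@dataclass
class EyeSeries:
    """Uniformly sampled series derived from ocular events."""

    values: np.ndarray
    rate_hz: float
    t0_ms: float
    kind: str  # "saccade_train" | "fixdiff"
    defined_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("series must be a non-empty 1-D array")
        if self.defined_mask.shape != self.values.shape:
            raise ValueError("defined_mask must match values in shape")
        if self.kind not in ("saccade_train", "fixdiff"):
            raise ValueError(f"unknown series kind {self.kind!r}")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(len(self.values)) * (1000.0 / self.rate_hz)

    def defined_runs(self) -> list[slice]:
        """Maximal contiguous runs of defined samples."""
        m = self.defined_mask
        if not m.any():
            return []
        edges = np.flatnonzero(np.diff(m.astype(np.int8)))
        starts = np.concatenate([[0] if m[0] else [], edges[~m[edges]] + 1]).astype(int)
        stops = np.concatenate([edges[m[edges]] + 1, [len(m)] if m[-1] else []]).astype(int)
        return [slice(a, b) for a, b in zip(starts, stops)]

    def sample_index(self, t_ms: float | np.ndarray) -> np.ndarray:
        """Nearest-sample index for a time on the series clock; ties round up."""
        return np.floor((np.asarray(t_ms) - self.t0_ms) * self.rate_hz / 1000.0 + 0.5).astype(int)


@dataclass(frozen=True)
class RemovalReport:
    n_total: int
    n_removed: int

    @property
    def fraction(self) -> float:
        return self.n_removed / self.n_total if self.n_total else 0.0


def _check_ordered(events: Sequence[FixationEvent] | Sequence[SaccadeEvent]) -> None:
    onsets = [e.onset_ms for e in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("events must be time-ordered")


def filter_fixations(
    fixations: Sequence[FixationEvent],
) -> tuple[list[FixationEvent], RemovalReport]:
    """Drop implausibly short/long fixations (< 60 ms or > 1000 ms)."""
    _check_ordered(fixations)
    kept = [f for f in fixations if FIX_MIN_MS <= f.duration_ms <= FIX_MAX_MS]
    return kept, RemovalReport(len(fixations), len(fixations) - len(kept))


def filter_saccades(
    saccades: Sequence[SaccadeEvent],
) -> tuple[list[SaccadeEvent], RemovalReport]:
    """Drop saccades longer than 80 ms."""
    _check_ordered(saccades)
    kept = [s for s in saccades if s.duration_ms <= SACC_MAX_MS]
    return kept, RemovalReport(len(saccades), len(saccades) - len(kept))


def exclude_post_regression(fixations: Sequence[FixationEvent]) -> list[FixationEvent]:
    """Remove the first fixation after each backward saccade."""
    kept = [f for f in fixations if not f.is_post_regression]
    if fixations and not kept:
        logger.warning("all fixations flagged post-regression; nothing left")
    return kept


def build_saccade_train(
    saccades: Sequence[SaccadeEvent],
    rate_hz: float,
    span_ms: tuple[float, float],
    defined_intervals_ms: Sequence[tuple[float, float]] | None = None,
) -> EyeSeries:
    """Binary series with 1 at the sample nearest each saccade onset.

    ``defined_intervals_ms`` restricts the defined support (e.g. to reading
    blocks); by default the whole span is defined.
    """
    t0, t1 = span_ms
    if t1 <= t0:
        raise ValueError("span must have positive length")
    n = int(math.ceil((t1 - t0) * rate_hz / 1000.0)) + 1
    values = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    intervals = defined_intervals_ms if defined_intervals_ms is not None else [(t0, t1)]
    for a, b in intervals:
        ia = max(int(math.floor((a - t0) * rate_hz / 1000.0 + 0.5)), 0)
        ib = min(int(math.floor((b - t0) * rate_hz / 1000.0 + 0.5)) + 1, n)
        mask[ia:ib] = True
    for s in saccades:
        if not (t0 <= s.onset_ms <= t1):
            raise ValueError(f"saccade onset {s.onset_ms} ms outside span {span_ms}")
        idx = int(math.floor((s.onset_ms - t0) * rate_hz / 1000.0 + 0.5))
        if values[idx] == 1.0:
            raise ValueError(
                f"two saccade onsets map to sample {idx}; increase rate_hz")
        values[idx] = 1.0
    return EyeSeries(values=values, rate_hz=rate_hz, t0_ms=t0,
                     kind="saccade_train", defined_mask=mask)


def fixdiff_anchors(
    fixations: Sequence[FixationEvent],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Anchor points of the duration-difference series.

    Returns ``(onset_ms, diff_ms, block_id)`` for every consecutive fixation
    pair within the same block; the difference is assigned to the onset of
    the later fixation.
    """
    _check_ordered(fixations)
    ts, ds, bs = [], [], []
    for prev, cur in zip(fixations, fixations[1:]):
        if cur.block_id != prev.block_id:
            continue
        ts.append(cur.onset_ms)
        ds.append(cur.duration_ms - prev.duration_ms)
        bs.append(cur.block_id)
    return np.array(ts), np.array(ds), np.array(bs, dtype=int)


def build_fixdiff_series(
    fixations: Sequence[FixationEvent],
    rate_hz: float,
    span_ms: tuple[float, float] | None = None,
) -> EyeSeries:
    """Linearly interpolated duration-difference series.

    Fixations must already be filtered and post-regression-excluded. Within
    each block the series is defined from the first to the last anchor;
    everywhere else it is masked undefined.
    """
    t_anchor, d_anchor, b_anchor = fixdiff_anchors(fixations)
    if span_ms is None:
        if len(t_anchor) == 0:
            raise ValueError("need at least 2 fixations in some block")
        span_ms = (float(t_anchor[0]), float(t_anchor[-1]))
    t0, t1 = span_ms
    n = int(math.ceil((t1 - t0) * rate_hz / 1000.0)) + 1
    values = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    t_samples = t0 + np.arange(n) * (1000.0 / rate_hz)
    for b in np.unique(b_anchor):
        sel = b_anchor == b
        tb, db = t_anchor[sel], d_anchor[sel]
        if len(tb) < 1:
            continue
        if len(tb) == 1:
            logger.warning("block %d has a single fixdiff anchor; constant series", b)
        ia = int(np.searchsorted(t_samples, tb[0], side="left"))
        ib = int(np.searchsorted(t_samples, tb[-1], side="right"))
        ia, ib = max(ia, 0), min(ib, n)
        if ia >= ib:
            continue
        values[ia:ib] = np.interp(t_samples[ia:ib], tb, db)
        mask[ia:ib] = True
    if not mask.any():
        logger.warning("fixdiff series has no defined samples")
    return EyeSeries(values=values, rate_hz=rate_hz, t0_ms=t0,
                     kind="fixdiff", defined_mask=mask)


def epoch_series_by_sentence(
    series: EyeSeries,
    sentences: Sequence[SentenceSpan],
    min_duration_s: float = 2.0,
) -> list[tuple[int, np.ndarray]]:
    """Cut one variable-length epoch per sentence, restricted to defined samples.

    Sentences with reading duration below ``min_duration_s`` are dropped.
    Returns ``(sentence_id, values)`` pairs.
    """
    out: list[tuple[int, np.ndarray]] = []
    for span in sentences:
        if span.duration_ms < 1000.0 * min_duration_s:
            continue
        ia = int(np.clip(series.sample_index(span.t_start_ms), 0, len(series.values) - 1))
        ib = int(np.clip(series.sample_index(span.t_end_ms), 0, len(series.values) - 1)) + 1
        m = series.defined_mask[ia:ib]
        if not m.any():
            continue
        first = ia + int(np.argmax(m))
        last = ib - int(np.argmax(m[::-1]))
        out.append((span.sentence_id, series.values[first:last].copy()))
    if not out:
        logger.warning("no sentences survived epoching")
    return out


def downsample_fixdiff(series: EyeSeries, new_rate_hz: float) -> EyeSeries:
    """Decimate an interpolated series with an anti-alias FIR low-pass."""
    from scipy.signal import decimate

    if series.kind != "fixdiff":
        raise ValueError("decimation is only defined for interpolated series; "
                         "rebuild binary trains at the target rate instead")
    factor = series.rate_hz / new_rate_hz
    q = int(round(factor))
    if abs(factor - q) > 1e-9 or q < 1:
        raise ValueError(f"rate ratio must be an integer, got {factor}")
    if q == 1:
        return series
    vals = decimate(series.values, q, ftype="fir", zero_phase=True)
    mask = series.defined_mask[::q][: len(vals)]
    # samples whose anti-alias support touches undefined data are undefined
    return EyeSeries(values=vals, rate_hz=new_rate_hz, t0_ms=series.t0_ms,
                     kind="fixdiff", defined_mask=mask)
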