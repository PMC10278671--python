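"""Ocular event types and their TSV serialization.

Fixations and saccades are the two event classes produced by an eye-tracker's
online parser during reading. Only their temporal structure is represented
here (onsets and durations on the eye-tracker clock, in milliseconds);
2-D gaze coordinates are outside the scope of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FixationEvent",
    "SaccadeEvent",
    "SentenceSpan",
    "read_events",
    "write_events",
]


@dataclass(frozen=True)
class FixationEvent:
    """A single fixation.

    ``is_post_regression`` marks the first fixation after a backward saccade
    (a regression); such fixations are excluded from the duration-difference
    analysis. ``is_sentence_final`` marks fixations landing on the last word
    of a sentence, the anchor points of the boundary phase analysis.
    """

    onset_ms: float
    duration_ms: float
    sentence_id: int
    word_idx: int
    is_post_regression: bool = False
    is_sentence_final: bool = False
    block_id: int = 0

    def __post_init__(self) -> None:
        if self.onset_ms < 0:
            raise ValueError(f"fixation onset must be >= 0, got {self.onset_ms}")
        if self.duration_ms <= 0:
            raise ValueError(f"fixation duration must be > 0, got {self.duration_ms}")


@dataclass(frozen=True)
class SaccadeEvent:
    """A single saccade; ``is_backward`` marks regressions."""

    onset_ms: float
    duration_ms: float
    is_backward: bool = False
    block_id: int = 0

    def __post_init__(self) -> None:
        if self.onset_ms < 0:
            raise ValueError(f"saccade onset must be >= 0, got {self.onset_ms}")
        if self.duration_ms <= 0:
            raise ValueError(f"saccade duration must be > 0, got {self.duration_ms}")


@dataclass(frozen=True)
class SentenceSpan:
    """Temporal extent of one sentence: first fixation onset to last fixation offset."""

    sentence_id: int
    block_id: int
    t_start_ms: float
    t_end_ms: float
    n_words: int = 0

    @property
    def duration_ms(self) -> float:
        return self.t_end_ms - self.t_start_ms


_FIX_COLUMNS = [
    "participant",
    "block",
    "sentence_id",
    "word_idx",
    "onset_ms",
    "duration_ms",
    "is_regression",
    "is_sentence_final",
]
_SACC_COLUMNS = ["participant", "block", "onset_ms", "duration_ms", "is_backward"]


def write_events(
    fixations: Sequence[FixationEvent],
    saccades: Sequence[SaccadeEvent],
    fix_path: str | Path,
    sacc_path: str | Path,
    participant: int = 0,
) -> None:
    """Write fixation and saccade tables as TSV."""
    fix_df = pd.DataFrame(
        [
            {
                "participant": participant,
                "block": f.block_id,
                "sentence_id": f.sentence_id,
                "word_idx": f.word_idx,
                "onset_ms": f.onset_ms,
                "duration_ms": f.duration_ms,
                "is_regression": int(f.is_post_regression),
                "is_sentence_final": int(f.is_sentence_final),
            }
            for f in fixations
        ],
        columns=_FIX_COLUMNS,
    )
    sacc_df = pd.DataFrame(
        [
            {
                "participant": participant,
                "block": s.block_id,
                "onset_ms": s.onset_ms,
                "duration_ms": s.duration_ms,
                "is_backward": int(s.is_backward),
            }
            for s in saccades
        ],
        columns=_SACC_COLUMNS,
    )
    fix_df.to_csv(fix_path, sep="\t", index=False, float_format="%.17g")
    sacc_df.to_csv(sacc_path, sep="\t", index=False, float_format="%.17g")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_events(
    fix_path: str | Path, sacc_path: str | Path
) -> tuple[list[FixationEvent], list[SaccadeEvent]]:
    """Read fixation and saccade tables written by :func:`write_events`."""
    fix_df = pd.read_csv(fix_path, sep="\t", float_precision="round_trip")
    _require_columns(fix_df, _FIX_COLUMNS, fix_path)
    sacc_df = pd.read_csv(sacc_path, sep="\t", float_precision="round_trip")
    _require_columns(sacc_df, _SACC_COLUMNS, sacc_path)

    fixations = [
        FixationEvent(
            onset_ms=float(r.onset_ms),
            duration_ms=float(r.duration_ms),
            sentence_id=int(r.sentence_id),
            word_idx=int(r.word_idx),
            is_post_regression=bool(r.is_regression),
            is_sentence_final=bool(r.is_sentence_final),
            block_id=int(r.block),
        )
        for r in fix_df.itertuples(index=False)
    ]
    saccades = [
        SaccadeEvent(
            onset_ms=float(r.onset_ms),
            duration_ms=float(r.duration_ms),
            is_backward=bool(r.is_backward),
            block_id=int(r.block),
        )
        for r in sacc_df.itertuples(index=False)
    ]
    return fixations, saccades
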