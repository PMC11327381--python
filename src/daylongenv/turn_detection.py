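"""Conversational-turn detection over filtered segment streams.

A turn is a target-child clip and an adult clip adjacent in the
CHN/FAN/MAN-restricted stream with the second starting no more than the
configured gap (default 5 s, inclusive) after the first ends.  Adult–adult
and child–child adjacencies never count; overlapping child/adult clips
(negative gap) do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env_metrics import hourly_rate
from .segments_io import ADULT_TAGS, AnalysisConfig, Recording, SpeakerTag

__all__ = ["TurnEvent", "detect_turns", "turn_metrics", "turns_to_frame"]


@dataclass(frozen=True, slots=True)
class TurnEvent:
    """One child↔adult exchange detected from stream adjacency."""

    recording_id: str
    first_tag: SpeakerTag
    second_tag: SpeakerTag
    first_offset_ms: int
    second_onset_ms: int

    @property
    def gap_ms(self) -> int:
        return self.second_onset_ms - self.first_offset_ms


def detect_turns(
    recording: Recording, config: AnalysisConfig | None = None
) -> list[TurnEvent]:
    """Scan consecutive pairs of the CHN/FAN/MAN stream for turns.

    OTHER segments are dropped before adjacency is evaluated, so an
    intervening OTHER clip does not break a child/adult pair, but an
    intervening same-side clip does.  Each adjacency yields at most one
    event; a single clip can participate in at most two (as second of one
    pair and first of the next).
    """
    config = config or AnalysisConfig()
    stream = [
        s
        for s in recording.segments
        if s.speaker_tag is SpeakerTag.CHN or s.speaker_tag in ADULT_TAGS
    ]
    events: list[TurnEvent] = []
    for first, second in zip(stream, stream[1:]):
        first_child = first.speaker_tag is SpeakerTag.CHN
        second_child = second.speaker_tag is SpeakerTag.CHN
        if first_child == second_child:
            continue
        if second.onset_ms - first.offset_ms <= config.turn_max_gap_ms:
            events.append(
                TurnEvent(
                    recording_id=recording.recording_id,
                    first_tag=first.speaker_tag,
                    second_tag=second.speaker_tag,
                    first_offset_ms=first.offset_ms,
                    second_onset_ms=second.onset_ms,
                )
            )
    return events


def turn_metrics(
    turns: list[TurnEvent],
    recording: Recording,
    config: AnalysisConfig | None = None,
) -> tuple[float, float]:
    """(turns per hour, proportion of full epochs containing >=1 turn).

    An epoch counts if at least one turn's second-clip onset falls in it;
    the trailing partial epoch is dropped from the denominator.
    """
    config = config or AnalysisConfig()
    ctc_per_hr = hourly_rate(len(turns), recording.duration_ms)
    epoch_ms = config.epoch_unit_s * 1000
    n_epochs = recording.duration_ms // epoch_ms
    if n_epochs < 1:
        raise ValueError(
            f"{recording.recording_id}: recording shorter than one epoch"
        )
    hit = np.zeros(n_epochs, dtype=bool)
    for ev in turns:
        idx = ev.second_onset_ms // epoch_ms
        if idx < n_epochs:
            hit[idx] = True
    return ctc_per_hr, float(hit.sum()) / n_epochs


def turns_to_frame(turns: list[TurnEvent]) -> pd.DataFrame:
    """TurnEvents as a flat table (CSV-exportable)."""
    return pd.DataFrame(
        [
            {
                "recording_id": ev.recording_id,
                "first_tag": ev.first_tag.value,
                "second_tag": ev.second_tag.value,
                "first_offset_ms": ev.first_offset_ms,
                "second_onset_ms": ev.second_onset_ms,
                "gap_ms": ev.gap_ms,
            }
            for ev in turns
        ],
        columns=[
            "recording_id",
            "first_tag",
            "second_tag",
            "first_offset_ms",
            "second_onset_ms",
            "gap_ms",
        ],
    )
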