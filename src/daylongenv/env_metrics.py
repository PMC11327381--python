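"""Per-recording quantity and consistency measures, hourly normalized.

Quantity: adult words/hr, adult speech minutes (and seconds)/hr, child
vocalizations/hr.  Consistency: the proportion of fixed bins (minutes by
default) containing at least one qualifying event — a temporal-spread
measure independent of total quantity.  All rates normalize by the actual
recorded duration; trailing partial bins are dropped from consistency
denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segments_io import (
    ADULT_TAGS,
    AnalysisConfig,
    ChildMeta,
    Recording,
    SpeakerTag,
)

__all__ = [
    "EnvMetrics",
    "ConsistencyPredicate",
    "hourly_rate",
    "quantity_metrics",
    "consistency",
    "compute_env_metrics",
    "metrics_table",
    "hourly_long_table",
    "voc_duration_table",
]

MS_PER_HOUR = 3_600_000


class ConsistencyPredicate(Enum):
    ADULT_WORD = "adult_word"
    CHILD_VOC = "child_voc"


@dataclass(slots=True)
class EnvMetrics:
    """Speech-environment measures for one recording.

    ``ctc_per_hr`` and ``turn_consistency`` are populated by the turn
    detector; they stay None until then.
    """

    recording_id: str
    awc_per_hr: float = 0.0
    adult_min_per_hr: float = 0.0
    cvc_per_hr: float = 0.0
    voc_durations_ms: list[int] = field(default_factory=list)
    input_consistency: float | None = None
    output_consistency: float | None = None
    ctc_per_hr: float | None = None
    turn_consistency: float | None = None

    @property
    def adult_sec_per_hr(self) -> float:
        return 60.0 * self.adult_min_per_hr

    @property
    def voc_dur_mean_ms(self) -> float:
        return float(np.mean(self.voc_durations_ms)) if self.voc_durations_ms else float("nan")


def hourly_rate(total: float, duration_ms: int) -> float:
    """Normalize a per-recording total to a per-hour rate."""
    if duration_ms <= 0:
        raise ValueError(f"duration_ms must be positive, got {duration_ms}")
    return total / (duration_ms / MS_PER_HOUR)


def quantity_metrics(recording: Recording) -> EnvMetrics:
    """Compute the quantity fields of EnvMetrics from a filtered recording."""
    words = 0
    adult_ms = 0
    voc_durations: list[int] = []
    for seg in recording.segments:
        if seg.speaker_tag in ADULT_TAGS:
            words += seg.word_count
            adult_ms += seg.duration_ms
        elif seg.speaker_tag is SpeakerTag.CHN:
            voc_durations.append(seg.duration_ms)
    dur = recording.duration_ms
    return EnvMetrics(
        recording_id=recording.recording_id,
        awc_per_hr=hourly_rate(words, dur),
        adult_min_per_hr=hourly_rate(adult_ms / 60_000.0, dur),
        cvc_per_hr=hourly_rate(len(voc_durations), dur),
        voc_durations_ms=voc_durations,
    )


def _qualifies(seg, predicate: ConsistencyPredicate) -> bool:
    if predicate is ConsistencyPredicate.ADULT_WORD:
        return seg.speaker_tag in ADULT_TAGS and seg.word_count >= 1
    return seg.speaker_tag is SpeakerTag.CHN


def consistency(
    recording: Recording,
    unit_s: int,
    predicate: ConsistencyPredicate,
) -> float:
    """Proportion of full ``unit_s``-second bins overlapped by a qualifying segment.

    Bins are half-open intervals from recording start; the trailing partial
    bin (if any) is excluded from the denominator.  A bin qualifies if it
    overlaps at least one qualifying segment — clip-level word estimates
    carry no within-clip timing, so the whole clip carries its words.
    """
    if unit_s <= 0:
        raise ValueError("unit_s must be positive")
    unit_ms = unit_s * 1000
    n_bins = recording.duration_ms // unit_ms
    if n_bins < 1:
        raise ValueError(
            f"{recording.recording_id}: recording shorter than one "
            f"{unit_s}s bin"
        )
    hit = np.zeros(n_bins, dtype=bool)
    for seg in recording.segments:
        if not _qualifies(seg, predicate):
            continue
        first = seg.onset_ms // unit_ms
        last = (seg.offset_ms - 1) // unit_ms
        if first >= n_bins:
            continue
        hit[first : min(last, n_bins - 1) + 1] = True
    return float(hit.sum()) / n_bins


def compute_env_metrics(
    recording: Recording, config: AnalysisConfig | None = None
) -> EnvMetrics:
    """Quantity plus input/output consistency for one filtered recording."""
    config = config or AnalysisConfig()
    m = quantity_metrics(recording)
    m.input_consistency = consistency(
        recording, config.minute_unit_s, ConsistencyPredicate.ADULT_WORD
    )
    m.output_consistency = consistency(
        recording, config.minute_unit_s, ConsistencyPredicate.CHILD_VOC
    )
    return m


def metrics_table(
    cohort: Sequence[ChildMeta],
    recordings: Sequence[Recording],
    config: AnalysisConfig | None = None,
    with_turns: bool = True,
) -> pd.DataFrame:
    """One row per (filtered) recording: EnvMetrics joined with ChildMeta.

    Children whose hearing age falls below ``config.min_hearing_age_mo``
    are flagged ``hearing_age_excluded`` so hearing-age analyses can drop
    them without losing the rows elsewhere.
    """
    config = config or AnalysisConfig()
    meta_by_child = {c.child_id: c for c in cohort}
    rows = []
    for rec in recordings:
        meta = meta_by_child.get(rec.child_id)
        if meta is None:
            raise KeyError(
                f"recording {rec.recording_id}: child_id {rec.child_id!r} "
                "not in cohort table"
            )
        m = compute_env_metrics(rec, config)
        if with_turns:
            from .turn_detection import detect_turns, turn_metrics

            turns = detect_turns(rec, config)
            m.ctc_per_hr, m.turn_consistency = turn_metrics(turns, rec, config)
        ha = meta.hearing_age_mo
        rows.append(
            {
                "recording_id": rec.recording_id,
                "child_id": rec.child_id,
                "duration_hr": rec.duration_ms / MS_PER_HOUR,
                "awc_per_hr": m.awc_per_hr,
                "adult_min_per_hr": m.adult_min_per_hr,
                "adult_sec_per_hr": m.adult_sec_per_hr,
                "cvc_per_hr": m.cvc_per_hr,
                "voc_dur_mean_ms": m.voc_dur_mean_ms,
                "n_vocs": len(m.voc_durations_ms),
                "input_consistency": m.input_consistency,
                "output_consistency": m.output_consistency,
                "ctc_per_hr": m.ctc_per_hr,
                "turn_consistency": m.turn_consistency,
                "hearing_group": meta.hearing_group.value,
                "chrono_age_mo": meta.chrono_age_mo,
                "activation_age_mo": meta.activation_age_mo,
                "hearing_age_mo": ha,
                "maternal_ed": meta.maternal_ed,
                "gender": meta.gender,
                "hearing_age_excluded": bool(
                    ha is not None and ha < config.min_hearing_age_mo
                ),
            }
        )
    return pd.DataFrame(rows)


def hourly_long_table(recordings: Iterable[Recording]) -> pd.DataFrame:
    """Long-format per-hour totals for the mixed models.

    One row per (recording, full hour): adult word tokens, adult speech
    seconds, child vocalization count and seconds.  Segments are assigned
    to the hour containing their onset; the trailing partial hour is
    dropped, mirroring the consistency convention.
    """
    rows = []
    for rec in recordings:
        n_hours = rec.duration_ms // MS_PER_HOUR
        if n_hours < 1:
            raise ValueError(
                f"{rec.recording_id}: recording shorter than one hour"
            )
        words = np.zeros(n_hours)
        adult_sec = np.zeros(n_hours)
        vocs = np.zeros(n_hours)
        voc_sec = np.zeros(n_hours)
        for seg in rec.segments:
            h = seg.onset_ms // MS_PER_HOUR
            if h >= n_hours:
                continue
            if seg.speaker_tag in ADULT_TAGS:
                words[h] += seg.word_count
                adult_sec[h] += seg.duration_ms / 1000.0
            elif seg.speaker_tag is SpeakerTag.CHN:
                vocs[h] += 1
                voc_sec[h] += seg.duration_ms / 1000.0
        for h in range(n_hours):
            rows.append(
                {
                    "recording_id": rec.recording_id,
                    "child_id": rec.child_id,
                    "hour_index": h,
                    "words": words[h],
                    "adult_sec": adult_sec[h],
                    "adult_min": adult_sec[h] / 60.0,
                    "voc_count": vocs[h],
                    "voc_sec": voc_sec[h],
                }
            )
    return pd.DataFrame(rows)


def voc_duration_table(recordings: Iterable[Recording]) -> pd.DataFrame:
    """Segment-level child vocalization durations (for repeated-measure models)."""
    rows = [
        {
            "recording_id": rec.recording_id,
            "child_id": rec.child_id,
            "duration_ms": seg.duration_ms,
        }
        for rec in recordings
        for seg in rec.segments
        if seg.speaker_tag is SpeakerTag.CHN
    ]
    return pd.DataFrame(rows, columns=["recording_id", "child_id", "duration_ms"])
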