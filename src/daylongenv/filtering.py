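"""Clip-exclusion rules applied before any metric is computed.

Removed, in one pass: target-child clips containing cries, adult clips
containing any non-speech, and adult clips strictly longer than the
configured maximum (default 10 s; over-long adult clips tend to be
mislabeled).  OTHER-tagged clips pass through untouched.  An adult clip
violating both rules is counted once, under non-speech.
"""

from __future__ import annotations

from dataclasses import dataclass

from .segments_io import (
    ADULT_TAGS,
    AnalysisConfig,
    Recording,
    SpeakerTag,
)

__all__ = ["FilterReport", "filter_segments"]


@dataclass(slots=True)
class FilterReport:
    """Per-recording accounting of removed clips."""

    recording_id: str
    n_total: int
    n_removed_chn_cry: int
    n_removed_adult_nonspeech: int
    n_removed_adult_long: int

    @property
    def n_removed(self) -> int:
        return (
            self.n_removed_chn_cry
            + self.n_removed_adult_nonspeech
            + self.n_removed_adult_long
        )

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_removed

    @property
    def pct_removed(self) -> float:
        return self.n_removed / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "recording_id": self.recording_id,
            "n_total": self.n_total,
            "n_removed_chn_cry": self.n_removed_chn_cry,
            "n_removed_adult_nonspeech": self.n_removed_adult_nonspeech,
            "n_removed_adult_long": self.n_removed_adult_long,
            "n_retained": self.n_retained,
            "pct_removed": self.pct_removed,
        }


def filter_segments(
    recording: Recording, config: AnalysisConfig | None = None
) -> tuple[Recording, FilterReport]:
    """Return a filtered copy of ``recording`` plus a removal report.

    Segment order is preserved; each removed clip is counted under exactly
    one category (non-speech takes precedence over over-long for adult
    clips satisfying both).
    """
    config = config or AnalysisConfig()
    kept = []
    n_cry = n_nonspeech = n_long = 0
    for seg in recording.segments:
        if seg.speaker_tag is SpeakerTag.CHN and seg.has_cry:
            n_cry += 1
        elif seg.speaker_tag in ADULT_TAGS and seg.has_nonspeech:
            n_nonspeech += 1
        elif (
            seg.speaker_tag in ADULT_TAGS
            and seg.duration_ms > config.adult_max_clip_ms
        ):
            n_long += 1
        else:
            kept.append(seg)
    report = FilterReport(
        recording_id=recording.recording_id,
        n_total=len(recording.segments),
        n_removed_chn_cry=n_cry,
        n_removed_adult_nonspeech=n_nonspeech,
        n_removed_adult_long=n_long,
    )
    filtered = Recording(
        recording_id=recording.recording_id,
        child_id=recording.child_id,
        duration_ms=recording.duration_ms,
        segments=kept,
    )
    return filtered, report
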