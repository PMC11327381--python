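"""Data model and I/O for diarized daylong recordings.

A recording is an ordered timeline of speaker-tagged clips ("segments").
Timestamps are integer milliseconds from recording start; intervals are
half-open ``[onset, offset)`` so that abutting clips never double-count at
bin boundaries.  The canonical on-disk format is a UTF-8 comma-delimited
table with a fixed header and booleans serialized as ``0``/``1``, chosen so
that ``read(write(x)) == x`` bit-exactly.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SpeakerTag",
    "HearingGroup",
    "SegmentRecord",
    "Recording",
    "ChildMeta",
    "AnalysisConfig",
    "SchemaError",
    "RecordValidationError",
    "SEGMENT_COLUMNS",
    "COHORT_COLUMNS",
    "read_segment_table",
    "write_segment_table",
    "read_cohort_table",
    "write_cohort_table",
    "read_its_subset",
    "compute_hearing_age",
    "validate_recording",
]


class SchemaError(ValueError):
    """A table is missing required columns or has the wrong layout."""


class RecordValidationError(ValueError):
    """A row or record violates a data-model invariant."""


class SpeakerTag(str, Enum):
    """Diarizer speaker categories consumed by the analysis."""

    CHN = "CHN"  # target child
    FAN = "FAN"  # female adult near
    MAN = "MAN"  # male adult near
    OTHER = "OTHER"  # anything else; retained but ignored downstream


ADULT_TAGS = frozenset({SpeakerTag.FAN, SpeakerTag.MAN})


class HearingGroup(str, Enum):
    CI = "CI"
    CA_MATCH = "CA_MATCH"
    HA_MATCH = "HA_MATCH"


@dataclass(frozen=True, slots=True)
class SegmentRecord:
    """One diarized clip.

    ``word_count`` is the adult-word estimate attached to the clip; it is
    meaningful only for FAN/MAN clips and must be 0 otherwise.
    """

    recording_id: str
    speaker_tag: SpeakerTag
    onset_ms: int
    offset_ms: int
    word_count: int = 0
    has_cry: bool = False
    has_nonspeech: bool = False

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms

    def validate(self) -> None:
        if self.onset_ms < 0:
            raise RecordValidationError(
                f"{self.recording_id}: onset_ms {self.onset_ms} < 0"
            )
        if self.offset_ms <= self.onset_ms:
            raise RecordValidationError(
                f"{self.recording_id}: offset_ms {self.offset_ms} <= "
                f"onset_ms {self.onset_ms}"
            )
        if self.word_count < 0:
            raise RecordValidationError(
                f"{self.recording_id}: negative word_count {self.word_count}"
            )
        if self.speaker_tag not in ADULT_TAGS and self.word_count != 0:
            raise RecordValidationError(
                f"{self.recording_id}: word_count must be 0 for "
                f"{self.speaker_tag.value} segments"
            )


def _segment_sort_key(seg: SegmentRecord):
    return (seg.onset_ms, seg.offset_ms, seg.speaker_tag.value)


@dataclass(slots=True)
class Recording:
    """A child-day timeline of segments plus the total recorded duration."""

    recording_id: str
    child_id: str
    duration_ms: int
    segments: list[SegmentRecord] = field(default_factory=list)

    @property
    def duration_hr(self) -> float:
        return self.duration_ms / 3_600_000.0

    def validate(self) -> None:
        validate_recording(self)


def validate_recording(rec: Recording) -> None:
    """Run the full invariant suite; raise RecordValidationError on failure."""
    if rec.duration_ms <= 0:
        raise RecordValidationError(
            f"{rec.recording_id}: non-positive duration_ms {rec.duration_ms}"
        )
    prev_key = None
    for seg in rec.segments:
        seg.validate()
        if seg.recording_id != rec.recording_id:
            raise RecordValidationError(
                f"segment recording_id {seg.recording_id!r} != "
                f"{rec.recording_id!r}"
            )
        if seg.offset_ms > rec.duration_ms:
            raise RecordValidationError(
                f"{rec.recording_id}: segment offset {seg.offset_ms} exceeds "
                f"recording duration {rec.duration_ms}"
            )
        key = _segment_sort_key(seg)
        if prev_key is not None and key < prev_key:
            raise RecordValidationError(
                f"{rec.recording_id}: segments not sorted at onset "
                f"{seg.onset_ms}"
            )
        prev_key = key


@dataclass(slots=True)
class ChildMeta:
    """Group membership, ages and demographics for one child."""

    child_id: str
    hearing_group: HearingGroup
    chrono_age_mo: float
    activation_age_mo: float | None = None
    hearing_age_mo: float | None = None
    maternal_ed: int = 4
    gender: str = "F"

    def __post_init__(self) -> None:
        if not 1 <= self.maternal_ed <= 7:
            raise RecordValidationError(
                f"{self.child_id}: maternal_ed {self.maternal_ed} not in 1..7"
            )
        if self.hearing_group is HearingGroup.CI:
            if self.activation_age_mo is None:
                raise RecordValidationError(
                    f"{self.child_id}: CI child without activation_age_mo"
                )
            if self.hearing_age_mo is None:
                self.hearing_age_mo = compute_hearing_age(
                    self.chrono_age_mo, self.activation_age_mo
                )
        elif self.activation_age_mo is not None:
            raise RecordValidationError(
                f"{self.child_id}: activation_age_mo set for non-CI child"
            )
        elif self.hearing_age_mo is None:
            # typical hearing: hearing experience == chronological age
            self.hearing_age_mo = self.chrono_age_mo


@dataclass(slots=True)
class AnalysisConfig:
    """Tunable constants of the analysis.

    Defaults encode the published rules: adult clips longer than 10 s are
    discarded, a turn requires child and adult speech within 5 s, word and
    vocalization consistency use 1-minute bins, turn consistency uses
    5-minute epochs, and hearing-age analyses require >= 12 months of
    hearing experience.
    """

    adult_max_clip_ms: int = 10_000
    turn_max_gap_ms: int = 5_000
    minute_unit_s: int = 60
    epoch_unit_s: int = 300
    min_hearing_age_mo: float = 12.0
    exclude_child_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("adult_max_clip_ms", "minute_unit_s", "epoch_unit_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.turn_max_gap_ms < 0:
            raise ValueError("turn_max_gap_ms must be >= 0")
        self.exclude_child_ids = tuple(self.exclude_child_ids)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "adult_max_clip_ms": self.adult_max_clip_ms,
            "turn_max_gap_ms": self.turn_max_gap_ms,
            "minute_unit_s": self.minute_unit_s,
            "epoch_unit_s": self.epoch_unit_s,
            "min_hearing_age_mo": self.min_hearing_age_mo,
            "exclude_child_ids": list(self.exclude_child_ids),
        }


def compute_hearing_age(chrono_age_mo: float, activation_age_mo: float) -> float:
    """Months of hearing experience: chronological age minus activation age."""
    if chrono_age_mo < 0 or activation_age_mo < 0:
        raise ValueError("ages must be non-negative")
    if activation_age_mo > chrono_age_mo:
        raise ValueError(
            f"activation age {activation_age_mo} exceeds chronological age "
            f"{chrono_age_mo}"
        )
    return chrono_age_mo - activation_age_mo


# ---------------------------------------------------------------------------
# canonical segment table

SEGMENT_COLUMNS = [
    "recording_id",
    "child_id",
    "speaker_tag",
    "onset_ms",
    "offset_ms",
    "word_count",
    "has_cry",
    "has_nonspeech",
    "duration_ms",
]


def _coerce_tag(raw: str) -> SpeakerTag:
    try:
        return SpeakerTag(str(raw).strip().upper())
    except ValueError:
        return SpeakerTag.OTHER


def read_segment_table(
    path: str | Path, config: AnalysisConfig | None = None
) -> list[Recording]:
    """Read a canonical segment CSV into validated Recordings.

    Rows are grouped by ``recording_id`` and re-sorted; unknown speaker tags
    map to OTHER with a logged warning; any invariant violation raises with
    the offending 0-based data-row index.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"recording_id": str, "child_id": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    n_unknown = 0
    recordings: dict[str, Recording] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        tag = _coerce_tag(row.speaker_tag)
        if str(row.speaker_tag).strip().upper() not in SpeakerTag.__members__:
            n_unknown += 1
        word_count = int(row.word_count)
        if tag not in ADULT_TAGS and word_count != 0:
            logger.warning(
                "%s row %d: zeroing word_count %d on %s segment",
                path.name, idx, word_count, tag.value,
            )
            word_count = 0
        seg = SegmentRecord(
            recording_id=str(row.recording_id),
            speaker_tag=tag,
            onset_ms=int(row.onset_ms),
            offset_ms=int(row.offset_ms),
            word_count=word_count,
            has_cry=bool(int(row.has_cry)),
            has_nonspeech=bool(int(row.has_nonspeech)),
        )
        try:
            seg.validate()
        except RecordValidationError as exc:
            raise RecordValidationError(f"{path} row {idx}: {exc}") from exc
        rec = recordings.get(seg.recording_id)
        if rec is None:
            rec = Recording(
                recording_id=seg.recording_id,
                child_id=str(row.child_id),
                duration_ms=int(row.duration_ms),
            )
            recordings[seg.recording_id] = rec
        rec.segments.append(seg)

    if n_unknown:
        logger.warning(
            "%s: mapped %d unknown speaker tag(s) to OTHER", path.name, n_unknown
        )
    out = sorted(recordings.values(), key=lambda r: r.recording_id)
    for rec in out:
        rec.segments.sort(key=_segment_sort_key)
        rec.validate()
    return out


def write_segment_table(
    recordings: Iterable[Recording], path: str | Path
) -> Path:
    """Write Recordings as canonical CSV; deterministic row order."""
    path = Path(path)
    rows = []
    for rec in sorted(recordings, key=lambda r: r.recording_id):
        rec.validate()
        for seg in sorted(rec.segments, key=_segment_sort_key):
            rows.append(
                (
                    rec.recording_id,
                    rec.child_id,
                    seg.speaker_tag.value,
                    seg.onset_ms,
                    seg.offset_ms,
                    seg.word_count,
                    int(seg.has_cry),
                    int(seg.has_nonspeech),
                    rec.duration_ms,
                )
            )
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# cohort metadata table

COHORT_COLUMNS = [
    "child_id",
    "hearing_group",
    "chrono_age_mo",
    "activation_age_mo",
    "hearing_age_mo",
    "maternal_ed",
    "gender",
]


def read_cohort_table(path: str | Path) -> list[ChildMeta]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"child_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        act = row.activation_age_mo
        act = None if pd.isna(act) else float(act)
        ha = row.hearing_age_mo
        ha = None if pd.isna(ha) else float(ha)
        out.append(
            ChildMeta(
                child_id=str(row.child_id),
                hearing_group=HearingGroup(row.hearing_group),
                chrono_age_mo=float(row.chrono_age_mo),
                activation_age_mo=act,
                hearing_age_mo=ha,
                maternal_ed=int(row.maternal_ed),
                gender=str(row.gender),
            )
        )
    return out


def write_cohort_table(cohort: Iterable[ChildMeta], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        (
            c.child_id,
            c.hearing_group.value,
            c.chrono_age_mo,
            "" if c.activation_age_mo is None else c.activation_age_mo,
            "" if c.hearing_age_mo is None else c.hearing_age_mo,
            c.maternal_ed,
            c.gender,
        )
        for c in sorted(cohort, key=lambda c: c.child_id)
    ]
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# ITS-style XML (best-effort read-only subset)

# LENA-style codes collapse onto the four analysis tags; near/far and
# clear/quiet variants of other speakers are all OTHER.
_ITS_TAG_MAP = {
    "CHN": SpeakerTag.CHN,
    "CHF": SpeakerTag.OTHER,  # non-target child
    "FAN": SpeakerTag.FAN,
    "FAF": SpeakerTag.OTHER,
    "MAN": SpeakerTag.MAN,
    "MAF": SpeakerTag.OTHER,
}


def _parse_its_time_ms(raw: str) -> int:
    """Parse 'PT123.45S'-style (or bare-seconds) clock offsets to ms."""
    s = raw.strip().upper()
    if s.startswith("PT"):
        s = s[2:]
    if s.endswith("S"):
        s = s[:-1]
    return round(float(s) * 1000)


def read_its_subset(path: str | Path) -> Recording:
    """Best-effort ingestion of an ITS-style XML file.

    Only ``<Segment>`` elements with ``spkr``/``startTime``/``endTime``
    attributes are consumed; female+male adult word-count attributes are
    summed into ``word_count``.  Segments missing time attributes are
    skipped and counted in a logged warning.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SchemaError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()

    rec_id = path.stem
    child_id = path.stem
    for elem in root.iter():
        if elem.tag.split("}")[-1] == "Recording":
            rec_id = elem.get("num", rec_id)
            child_id = elem.get("childId", child_id)
            break

    segments: list[SegmentRecord] = []
    n_skipped = 0
    n_unmapped = 0
    for elem in root.iter():
        if elem.tag.split("}")[-1] != "Segment":
            continue
        spkr = elem.get("spkr")
        start = elem.get("startTime")
        end = elem.get("endTime")
        if spkr is None or start is None or end is None:
            n_skipped += 1
            continue
        spkr = spkr.strip().upper()
        tag = _ITS_TAG_MAP.get(spkr)
        if tag is None:
            tag = SpeakerTag.OTHER
            n_unmapped += 1
        onset = _parse_its_time_ms(start)
        offset = _parse_its_time_ms(end)
        if offset <= onset:
            n_skipped += 1
            continue
        words = 0
        if tag in ADULT_TAGS:
            for attr in ("femaleAdultWordCnt", "maleAdultWordCnt"):
                val = elem.get(attr)
                if val is not None:
                    words += round(float(val))
        has_cry = float(elem.get("childCryVfxLen", "0").strip("PTS") or 0) > 0
        segments.append(
            SegmentRecord(
                recording_id=str(rec_id),
                speaker_tag=tag,
                onset_ms=onset,
                offset_ms=offset,
                word_count=words,
                has_cry=has_cry and tag is SpeakerTag.CHN,
            )
        )
    if n_skipped or n_unmapped:
        logger.warning(
            "%s: skipped %d segment(s) without usable times; mapped %d "
            "unknown speaker code(s) to OTHER",
            path.name, n_skipped, n_unmapped,
        )
    segments.sort(key=_segment_sort_key)
    duration_ms = max((s.offset_ms for s in segments), default=1)
    rec = Recording(
        recording_id=str(rec_id),
        child_id=str(child_id),
        duration_ms=duration_ms,
        segments=segments,
    )
    rec.validate()
    return rec
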