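import numpy as np
import pytest

from daylongenv.segments_io import (
    AnalysisConfig,
    Recording,
    SegmentRecord,
    SpeakerTag,
)

TAGS = [SpeakerTag.CHN, SpeakerTag.FAN, SpeakerTag.MAN, SpeakerTag.OTHER]


def make_segment(
    rec_id="r1",
    tag=SpeakerTag.CHN,
    onset=0,
    offset=1000,
    words=0,
    cry=False,
    nonspeech=False,
):
    return SegmentRecord(
        recording_id=rec_id,
        speaker_tag=tag,
        onset_ms=onset,
        offset_ms=offset,
        word_count=words,
        has_cry=cry,
        has_nonspeech=nonspeech,
    )


def make_recording(segments, rec_id="r1", child_id="c1", duration_ms=None):
    if duration_ms is None:
        duration_ms = max((s.offset_ms for s in segments), default=1000)
        duration_ms = max(duration_ms, 3_600_000)
    segs = sorted(
        segments, key=lambda s: (s.onset_ms, s.offset_ms, s.speaker_tag.value)
    )
    rec = Recording(
        recording_id=rec_id,
        child_id=child_id,
        duration_ms=duration_ms,
        segments=segs,
    )
    rec.validate()
    return rec


def random_recording(rng, n_segments=100, duration_ms=3_600_000, rec_id="r1"):
    """Arbitrary (but valid) timeline for oracle-equivalence tests."""
    segs = []
    for _ in range(n_segments):
        tag = TAGS[rng.integers(len(TAGS))]
        onset = int(rng.integers(0, duration_ms - 30_000))
        dur = int(rng.integers(100, 20_000))
        offset = min(onset + dur, duration_ms)
        words = (
            int(rng.integers(0, 40))
            if tag in (SpeakerTag.FAN, SpeakerTag.MAN)
            else 0
        )
        segs.append(
            SegmentRecord(
                recording_id=rec_id,
                speaker_tag=tag,
                onset_ms=onset,
                offset_ms=offset,
                word_count=words,
                has_cry=bool(rng.random() < 0.1),
                has_nonspeech=bool(rng.random() < 0.1),
            )
        )
    return make_recording(segs, rec_id=rec_id, duration_ms=duration_ms)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240216)
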