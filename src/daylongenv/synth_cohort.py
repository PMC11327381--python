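"""Matched-cohort and daylong-timeline simulator.

Generates (1) three matched groups of children — a CI group with activation
ages, plus chronological-age and hearing-age matched typical-hearing groups
— and (2) per-child diarized timelines with the statistical structure the
analysis assumes: bursty adult speech with age-dependent word rates for the
typical-hearing groups, child vocalizations with an 80 ms duration floor,
mutual child/adult contingent responses inside a latency window, and
configurable cry / non-speech / over-long-clip contamination.

Every generative mean has a closed form (``expected_rates``) so empirical
rates can be tested against analytic expectations, and every planted group
effect or age slope has a matching estimator downstream, which is what the
parameter-recovery harness (``recovery_experiment``) exercises.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import stats_models
from .env_metrics import metrics_table, voc_duration_table
from .filtering import filter_segments
from .segments_io import (
    AnalysisConfig,
    ChildMeta,
    HearingGroup,
    Recording,
    SegmentRecord,
    SpeakerTag,
)

__all__ = [
    "SynthParams",
    "GenerationError",
    "generate_cohort",
    "generate_group_children",
    "generate_recording",
    "generate_recordings",
    "expected_rates",
    "recovery_experiment",
    "recover_age_slope",
    "simulate_hourly_table",
    "simulate_productivity_cohort",
    "type1_group_lrt",
    "type1_interaction_lrt",
]

GROUPS = [g.value for g in HearingGroup]


class GenerationError(RuntimeError):
    """The requested cohort/timeline could not be generated."""


def _per_group(value) -> dict[str, float]:
    """Broadcast a scalar to a {group: value} map; pass dicts through."""
    if isinstance(value, dict):
        missing = set(GROUPS) - set(value)
        if missing:
            raise ValueError(f"per-group parameter missing groups {missing}")
        return {g: float(value[g]) for g in GROUPS}
    return {g: float(value) for g in GROUPS}


@dataclass(slots=True)
class SynthParams:
    """Generative parameters; defaults are calibrated so group means sit
    near realistic daylong-recording scales (~1200 adult words/hr, ~270
    child vocalizations/hr, ~65 turns/hr)."""

    n_per_group: int = 18
    seed: int = 20240216
    # cohort structure
    age_range_mo: dict = field(
        default_factory=lambda: {
            "CI": (31.0, 65.0),
            "CA_MATCH": (32.0, 66.0),
            "HA_MATCH": (17.0, 52.0),
        }
    )
    activation_age_range_mo: tuple[float, float] = (7.0, 45.0)
    n_low_hearing_age: int = 0  # CI children forced below the 12 mo floor
    match_tolerance_mo: float = 3.0
    mat_ed_tolerance: int = 1
    # recording scale
    recording_hours: float = 16.0
    # adult speech burst process
    adult_burst_rate_per_hr: float = 12.0
    burst_mean_len_s: float = 24.0
    adult_seg_dur_lognorm: tuple[float, float] = (math.log(2.0), 0.5)
    adult_seg_cap_s: float = 10.0
    adult_fan_prop: float = 0.85
    words_per_sec: float = 4.2
    word_rate_age_slope: dict | float = field(
        default_factory=lambda: {"CI": 0.0, "CA_MATCH": 20.7, "HA_MATCH": 16.49}
    )
    # child vocalizations
    child_base_rate_per_hr: float = 210.0
    voc_dur_base_ms: dict | float = field(
        default_factory=lambda: {"CI": 938.0, "CA_MATCH": 1004.0, "HA_MATCH": 967.0}
    )
    voc_dur_age_slope_ms: dict | float = field(
        default_factory=lambda: {"CI": 3.16, "CA_MATCH": 0.59, "HA_MATCH": 6.59}
    )
    voc_dur_noise_sd_ms: float = 250.0
    voc_dur_min_ms: int = 80
    # contingency (the social feedback loop)
    p_child_response: dict | float = field(
        default_factory=lambda: {"CI": 0.45, "CA_MATCH": 0.5, "HA_MATCH": 0.5}
    )
    p_adult_response: float = 0.25
    response_window_ms: int = 5_000
    # contamination
    cry_rate: float = 0.02
    adult_nonspeech_rate: float = 0.02
    long_clip_rate: float = 0.002
    long_clip_range_s: tuple[float, float] = (10.5, 20.0)
    # reference ages at which base rates apply (per group)
    age_ref_mo: dict | float = field(
        default_factory=lambda: {"CI": 48.0, "CA_MATCH": 49.0, "HA_MATCH": 34.5}
    )

    def __post_init__(self) -> None:
        for name in (
            "adult_fan_prop", "p_adult_response", "cry_rate",
            "adult_nonspeech_rate", "long_clip_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for g, p in _per_group(self.p_child_response).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_child_response[{g}]={p} outside [0, 1]")
        if self.recording_hours <= 0:
            raise ValueError("recording_hours must be positive")
        if self.voc_dur_min_ms <= 0:
            raise ValueError("voc_dur_min_ms must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthParams":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown synth param(s): {sorted(unknown)}")
        for key in ("adult_seg_dur_lognorm", "long_clip_range_s",
                    "activation_age_range_mo"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "age_range_mo" in data:
            data["age_range_mo"] = {
                g: tuple(v) for g, v in data["age_range_mo"].items()
            }
        return cls(**data)


# ---------------------------------------------------------------------------
# cohort generation


def _child_rng(params: SynthParams, child_id: str) -> np.random.Generator:
    # stable per-child stream: cohort-level seed + CRC of the id
    return np.random.default_rng([params.seed, zlib.crc32(child_id.encode())])


def generate_cohort(params: SynthParams) -> list[ChildMeta]:
    """Draw a CI group and its matched triads.

    Each CI child gets a chronological-age match (within the matching
    tolerance, same gender, maternal education within one level) and —
    when the child has at least 12 months of hearing experience — a
    hearing-age match whose chronological age sits within tolerance of the
    CI child's hearing age.  Deterministic under ``params.seed``.
    """
    if params.n_per_group < 1:
        raise GenerationError("n_per_group must be >= 1")
    if params.n_low_hearing_age > params.n_per_group:
        raise GenerationError("n_low_hearing_age exceeds n_per_group")
    rng = np.random.default_rng([params.seed, 0xC0])
    lo, hi = params.age_range_mo["CI"]
    act_lo, act_hi = params.activation_age_range_mo
    tol = params.match_tolerance_mo
    cohort: list[ChildMeta] = []
    for i in range(params.n_per_group):
        chrono = round(float(rng.uniform(lo, hi)), 2)
        if i < params.n_low_hearing_age:
            hearing = round(float(rng.uniform(6.0, 11.9)), 2)
            activation = round(chrono - hearing, 2)
        else:
            a_hi = min(act_hi, chrono - 12.0)
            if a_hi < act_lo:
                raise GenerationError(
                    f"cannot draw activation age in [{act_lo}, {a_hi}]"
                )
            activation = round(float(rng.uniform(act_lo, a_hi)), 2)
        gender = "F" if rng.random() < 0.5 else "M"
        mat_ed = int(rng.integers(3, 8))
        ci = ChildMeta(
            child_id=f"ci{i + 1:02d}",
            hearing_group=HearingGroup.CI,
            chrono_age_mo=chrono,
            activation_age_mo=activation,
            maternal_ed=mat_ed,
            gender=gender,
        )
        cohort.append(ci)

        def _match(prefix: str, target_age: float) -> ChildMeta:
            age = round(float(target_age + rng.uniform(-tol, tol)), 2)
            ed = int(
                np.clip(
                    mat_ed + rng.integers(
                        -params.mat_ed_tolerance, params.mat_ed_tolerance + 1
                    ),
                    1,
                    7,
                )
            )
            group = (
                HearingGroup.CA_MATCH if prefix == "ca" else HearingGroup.HA_MATCH
            )
            return ChildMeta(
                child_id=f"{prefix}{i + 1:02d}",
                hearing_group=group,
                chrono_age_mo=age,
                maternal_ed=ed,
                gender=gender,
            )

        cohort.append(_match("ca", chrono))
        if ci.hearing_age_mo >= 12.0:
            cohort.append(_match("ha", ci.hearing_age_mo))
    return cohort


def generate_group_children(
    params: SynthParams, group: str, n: int, id_prefix: str = "s"
) -> list[ChildMeta]:
    """Unmatched children of one group with ages uniform over the group range
    (recovery harnesses that only need a single group)."""
    rng = np.random.default_rng([params.seed, 0xA5, zlib.crc32(group.encode())])
    lo, hi = params.age_range_mo[group]
    out = []
    for i in range(n):
        chrono = round(float(rng.uniform(lo, hi)), 2)
        activation = None
        if group == "CI":
            a_lo, a_hi = params.activation_age_range_mo
            activation = round(
                float(rng.uniform(a_lo, min(a_hi, chrono - 12.0))), 2
            )
        out.append(
            ChildMeta(
                child_id=f"{id_prefix}{i + 1:03d}",
                hearing_group=HearingGroup(group),
                chrono_age_mo=chrono,
                activation_age_mo=activation,
                maternal_ed=int(rng.integers(3, 8)),
                gender="F" if rng.random() < 0.5 else "M",
            )
        )
    return out


# ---------------------------------------------------------------------------
# timeline generation


def _capped_lognorm_mean_s(params: SynthParams) -> float:
    """E[min(X, cap)] for lognormal X, in seconds (closed form)."""
    mu, sigma = params.adult_seg_dur_lognorm
    c = params.adult_seg_cap_s
    z1 = (math.log(c) - mu - sigma**2) / sigma
    z2 = (math.log(c) - mu) / sigma
    phi = scipy.stats.norm.cdf
    return math.exp(mu + sigma**2 / 2) * phi(z1) + c * (1 - phi(z2))


def _adult_words_per_sec(params: SynthParams, child: ChildMeta) -> float:
    """Effective word emission rate encoding the per-group age slope
    (words/hr per month) on top of the base rate."""
    group = child.hearing_group.value
    slope = _per_group(params.word_rate_age_slope)[group]
    ref = _per_group(params.age_ref_mo)[group]
    sec_per_hr = _expected_retained_adult_sec_per_hr(params)
    if sec_per_hr <= 0:
        return params.words_per_sec
    wps = params.words_per_sec + slope * (child.chrono_age_mo - ref) / sec_per_hr
    return max(wps, 0.0)


def _adult_seg_rate_per_hr(params: SynthParams) -> float:
    """Base (burst-process) adult segments per hour."""
    d_mean = _capped_lognorm_mean_s(params)
    if d_mean <= 0 or params.burst_mean_len_s <= 0:
        return 0.0
    segs_per_burst = params.burst_mean_len_s / d_mean
    return params.adult_burst_rate_per_hr * segs_per_burst


def _expected_retained_adult_sec_per_hr(params: SynthParams) -> float:
    d_mean = _capped_lognorm_mean_s(params)
    rate = (
        _adult_seg_rate_per_hr(params)
        + params.p_adult_response * params.child_base_rate_per_hr
    )
    retained = (1 - params.long_clip_rate) * (1 - params.adult_nonspeech_rate)
    return rate * retained * d_mean


def expected_rates(params: SynthParams, child: ChildMeta) -> dict[str, float]:
    """Closed-form expectations of the post-filter per-hour metrics."""
    group = child.hearing_group.value
    sec_per_hr = _expected_retained_adult_sec_per_hr(params)
    wps = _adult_words_per_sec(params, child)
    p_cr = _per_group(params.p_child_response)[group]
    child_rate = (
        params.child_base_rate_per_hr + p_cr * _adult_seg_rate_per_hr(params)
    ) * (1 - params.cry_rate)
    return {
        "awc_per_hr": sec_per_hr * wps,
        "adult_sec_per_hr": sec_per_hr,
        "adult_min_per_hr": sec_per_hr / 60.0,
        "cvc_per_hr": child_rate,
    }


def _resolve_overlaps(
    onsets: np.ndarray, durs: np.ndarray, t_max: int, min_gap_ms: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Shift later segments after earlier ones within a speaker stream;
    drop anything pushed past the end of the recording."""
    order = np.argsort(onsets, kind="stable")
    onsets = onsets[order].astype(np.int64)
    durs = durs[order].astype(np.int64)
    out_on = np.empty_like(onsets)
    cursor = -min_gap_ms
    for i in range(len(onsets)):
        start = max(onsets[i], cursor + min_gap_ms)
        out_on[i] = start
        cursor = start + durs[i]
    keep = out_on + durs <= t_max
    return out_on[keep], durs[keep]


def generate_recording(
    child: ChildMeta,
    params: SynthParams,
    recording_id: str | None = None,
) -> Recording:
    """Simulate one daylong diarized timeline for ``child``.

    Adult speech: burst onsets are Poisson; each burst holds a Poisson
    number of capped-lognormal segments with Poisson word counts.  Child
    vocalizations: a baseline Poisson process plus contingent responses
    after adult segments (probability ``p_child_response``, uniform latency
    within the response window); adult responses to baseline child
    vocalizations are symmetric.  Within-speaker overlaps are resolved by
    shifting; cross-speaker overlap is allowed (the turn detector must
    handle negative gaps).
    """
    rng = _child_rng(params, child.child_id)
    rec_id = recording_id or f"rec_{child.child_id}"
    group = child.hearing_group.value
    t_max = int(round(params.recording_hours * 3_600_000))
    hours = params.recording_hours
    mu, sigma = params.adult_seg_dur_lognorm
    cap_ms = int(params.adult_seg_cap_s * 1000)

    # --- adult base bursts
    adult_on: list[np.ndarray] = []
    adult_dur: list[np.ndarray] = []
    n_bursts = rng.poisson(params.adult_burst_rate_per_hr * hours)
    d_mean = _capped_lognorm_mean_s(params)
    lam_segs = params.burst_mean_len_s / d_mean if d_mean > 0 else 0.0
    burst_onsets = np.sort(rng.uniform(0, t_max, size=n_bursts))
    for b_on in burst_onsets:
        n_seg = rng.poisson(lam_segs)
        if n_seg == 0:
            continue
        long_mask = rng.random(n_seg) < params.long_clip_rate
        durs = np.minimum(
            rng.lognormal(mu, sigma, size=n_seg) * 1000, cap_ms
        )
        lo_s, hi_s = params.long_clip_range_s
        durs[long_mask] = rng.uniform(lo_s * 1000, hi_s * 1000, long_mask.sum())
        gaps = rng.uniform(200, 1500, size=n_seg)
        onsets = b_on + np.concatenate(([0.0], np.cumsum(durs + gaps)[:-1]))
        adult_on.append(onsets)
        adult_dur.append(durs)
    if adult_on:
        base_adult_on = np.concatenate(adult_on)
        base_adult_dur = np.concatenate(adult_dur)
    else:
        base_adult_on = np.empty(0)
        base_adult_dur = np.empty(0)

    # --- child baseline
    n_base_voc = rng.poisson(params.child_base_rate_per_hr * hours)
    child_base_on = rng.uniform(0, t_max, size=n_base_voc)

    # --- contingent responses (first order only: responses never cascade)
    p_cr = _per_group(params.p_child_response)[group]
    resp_mask = rng.random(len(base_adult_on)) < p_cr
    elicitors = base_adult_on[resp_mask] + base_adult_dur[resp_mask]
    child_resp_on = elicitors + rng.uniform(
        0, params.response_window_ms, size=len(elicitors)
    )

    ar_mask = rng.random(n_base_voc) < params.p_adult_response

    # child durations: linear in age with a hard floor
    voc_base = _per_group(params.voc_dur_base_ms)[group]
    voc_slope = _per_group(params.voc_dur_age_slope_ms)[group]
    ref = _per_group(params.age_ref_mo)[group]

    def _voc_durs(n: int) -> np.ndarray:
        raw = (
            voc_base
            + voc_slope * (child.chrono_age_mo - ref)
            + rng.normal(0, params.voc_dur_noise_sd_ms, size=n)
        )
        return np.maximum(raw, params.voc_dur_min_ms)

    child_base_dur = _voc_durs(n_base_voc)
    child_resp_dur = _voc_durs(len(child_resp_on))

    adult_resp_src = child_base_on[ar_mask] + child_base_dur[ar_mask]
    adult_resp_on = adult_resp_src + rng.uniform(
        0, params.response_window_ms, size=len(adult_resp_src)
    )
    n_ar = len(adult_resp_on)
    ar_long = rng.random(n_ar) < params.long_clip_rate
    adult_resp_dur = np.minimum(rng.lognormal(mu, sigma, size=n_ar) * 1000, cap_ms)
    lo_s, hi_s = params.long_clip_range_s
    adult_resp_dur[ar_long] = rng.uniform(
        lo_s * 1000, hi_s * 1000, ar_long.sum()
    )

    all_adult_on = np.concatenate([base_adult_on, adult_resp_on])
    all_adult_dur = np.concatenate([base_adult_dur, adult_resp_dur])
    all_child_on = np.concatenate([child_base_on, child_resp_on])
    all_child_dur = np.concatenate([child_base_dur, child_resp_dur])

    # split adults into FAN/MAN streams, resolve overlaps per tag
    fan_mask = rng.random(len(all_adult_on)) < params.adult_fan_prop
    segments: list[SegmentRecord] = []
    wps = _adult_words_per_sec(params, child)
    for tag, mask in (
        (SpeakerTag.FAN, fan_mask),
        (SpeakerTag.MAN, ~fan_mask),
    ):
        on, dur = _resolve_overlaps(
            np.round(all_adult_on[mask]).astype(np.int64),
            np.maximum(np.round(all_adult_dur[mask]).astype(np.int64), 1),
            t_max,
        )
        words = rng.poisson(wps * dur / 1000.0)
        nonspeech = rng.random(len(on)) < params.adult_nonspeech_rate
        for j in range(len(on)):
            segments.append(
                SegmentRecord(
                    recording_id=rec_id,
                    speaker_tag=tag,
                    onset_ms=int(on[j]),
                    offset_ms=int(on[j] + dur[j]),
                    word_count=int(words[j]),
                    has_nonspeech=bool(nonspeech[j]),
                )
            )

    on, dur = _resolve_overlaps(
        np.round(all_child_on).astype(np.int64),
        np.maximum(
            np.round(all_child_dur).astype(np.int64), params.voc_dur_min_ms
        ),
        t_max,
    )
    cry = rng.random(len(on)) < params.cry_rate
    for j in range(len(on)):
        segments.append(
            SegmentRecord(
                recording_id=rec_id,
                speaker_tag=SpeakerTag.CHN,
                onset_ms=int(on[j]),
                offset_ms=int(on[j] + dur[j]),
                has_cry=bool(cry[j]),
            )
        )

    segments.sort(key=lambda s: (s.onset_ms, s.offset_ms, s.speaker_tag.value))
    rec = Recording(
        recording_id=rec_id,
        child_id=child.child_id,
        duration_ms=t_max,
        segments=segments,
    )
    rec.validate()
    return rec


def generate_recordings(
    cohort: Iterable[ChildMeta], params: SynthParams
) -> list[Recording]:
    return [generate_recording(c, params) for c in cohort]


# ---------------------------------------------------------------------------
# model-level cohort simulators (for estimator calibration)


def simulate_hourly_table(
    n_children: int = 60,
    n_hours: int = 8,
    group_effects: dict | None = None,
    child_sd: float = 1.0,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Hour-level outcome drawn straight from the mixed model's assumed
    data-generating process (children split evenly over the three groups)."""
    rng = rng or np.random.default_rng()
    effects = {g: 0.0 for g in GROUPS}
    effects.update(group_effects or {})
    rows = []
    for i in range(n_children):
        group = GROUPS[i % 3]
        intercept = rng.normal(0, child_sd)
        y = (
            effects[group]
            + intercept
            + rng.normal(0, noise_sd, size=n_hours)
        )
        for h in range(n_hours):
            rows.append(
                {
                    "child_id": f"c{i:03d}",
                    "hearing_group": group,
                    "hour_index": h,
                    "y": y[h],
                }
            )
    return pd.DataFrame(rows)


def simulate_productivity_cohort(
    n_per_group: int = 18,
    turn_slopes: dict | None = None,
    age_slope: float = 0.5,
    intercept: float = 100.0,
    ctc_mean: float = 65.0,
    ctc_sd: float = 25.0,
    noise_sd: float = 30.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-child table with planted group-specific turns->vocalizations
    slopes (the construct the productivity model estimates)."""
    rng = rng or np.random.default_rng()
    slopes = {"CI": 2.2, "CA_MATCH": 3.66, "HA_MATCH": 3.53}
    slopes.update(turn_slopes or {})
    age_ranges = {
        "CI": (31.0, 65.0),
        "CA_MATCH": (32.0, 66.0),
        "HA_MATCH": (17.0, 52.0),
    }
    rows = []
    for g in GROUPS:
        lo, hi = age_ranges[g]
        ages = rng.uniform(lo, hi, size=n_per_group)
        ctc = np.maximum(rng.normal(ctc_mean, ctc_sd, size=n_per_group), 1.0)
        cvc = (
            intercept
            + age_slope * (ages - 45.0)
            + slopes[g] * ctc
            + rng.normal(0, noise_sd, size=n_per_group)
        )
        for i in range(n_per_group):
            rows.append(
                {
                    "child_id": f"{g.lower()}{i:03d}",
                    "hearing_group": g,
                    "chrono_age_mo": float(ages[i]),
                    "hearing_age_mo": float(ages[i]),
                    "ctc_per_hr": float(ctc[i]),
                    "cvc_per_hr": float(cvc[i]),
                }
            )
    return pd.DataFrame(rows)


def type1_group_lrt(
    n_cohorts: int = 500,
    n_children: int = 60,
    n_hours: int = 8,
    alpha: float = 0.05,
    seed: int = 20240216,
) -> float:
    """Rejection rate of the hearing-group LRT under zero planted effect."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_cohorts):
        table = simulate_hourly_table(n_children, n_hours, rng=rng)
        comp = stats_models.lrt_group_effect(table, "y", ("child",))
        rejections += comp.p < alpha
    return rejections / n_cohorts


def type1_interaction_lrt(
    n_cohorts: int = 500,
    n_per_group: int = 60,
    alpha: float = 0.05,
    seed: int = 20240216,
) -> float:
    """Rejection rate of the turns-by-group interaction LRT when all groups
    share one turns->vocalizations slope."""
    rng = np.random.default_rng(seed)
    equal = {"CI": 3.0, "CA_MATCH": 3.0, "HA_MATCH": 3.0}
    rejections = 0
    for _ in range(n_cohorts):
        table = simulate_productivity_cohort(
            n_per_group, turn_slopes=equal, rng=rng
        )
        result = stats_models.fit_productivity_model(table)
        rejections += result.interaction_test.p < alpha
    return rejections / n_cohorts


# ---------------------------------------------------------------------------
# parameter recovery


def _true_slope(params: SynthParams, group: str, estimand: str) -> float:
    if estimand == "awc_age_slope":
        return _per_group(params.word_rate_age_slope)[group]
    if estimand == "voc_dur_age_slope":
        return _per_group(params.voc_dur_age_slope_ms)[group]
    raise ValueError(f"unknown estimand {estimand!r}")


def recover_age_slope(
    params: SynthParams,
    group: str,
    estimand: str = "awc_age_slope",
    n_children: int = 100,
    n_reps: int = 50,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Replicated single-group recovery of a planted age slope.

    Each replicate simulates ``n_children`` of ``group``, runs the full
    filtering -> metrics (-> duration-model) path, and records the
    estimated slope next to the generative truth.  ``awc_age_slope`` uses
    the per-child OLS estimator; ``voc_dur_age_slope`` uses the
    segment-level mixed model with child intercepts.
    """
    config = config or AnalysisConfig()
    truth = _true_slope(params, group, estimand)
    rows = []
    for rep in range(n_reps):
        rep_params = replace(params, seed=params.seed + 1009 * rep)
        children = generate_group_children(rep_params, group, n_children)
        filtered = [
            filter_segments(generate_recording(c, rep_params), config)[0]
            for c in children
        ]
        per_child = metrics_table(children, filtered, config, with_turns=False)
        if estimand == "awc_age_slope":
            slopes = stats_models.cross_sectional_slopes(
                per_child, "awc_per_hr", "CHRONO", config
            )
        else:
            dur_tbl = voc_duration_table(filtered)
            slopes = stats_models.voc_duration_slopes(
                dur_tbl, per_child, "CHRONO", config
            )
        est = next(s for s in slopes if s.group == group)
        # per-rep CI half-width for coverage accounting
        x = per_child["chrono_age_mo"].to_numpy()
        if estimand == "awc_age_slope":
            y = per_child["awc_per_hr"].to_numpy()
            se = scipy.stats.linregress(x, y).stderr
        else:
            se = float("nan")
        rows.append(
            {
                "rep": rep,
                "group": group,
                "estimand": estimand,
                "true": truth,
                "estimate": est.beta,
                "se": se,
                "covered": bool(
                    np.isfinite(se) and abs(est.beta - truth) <= 1.96 * se
                ),
            }
        )
    return pd.DataFrame(rows)


def summarize_recovery(report: pd.DataFrame) -> pd.DataFrame:
    """Bias / RMSE / 95%-interval coverage per (group, estimand)."""
    def _agg(sub: pd.DataFrame) -> pd.Series:
        err = sub["estimate"] - sub["true"]
        return pd.Series(
            {
                "n_reps": len(sub),
                "true": sub["true"].iloc[0],
                "mean_estimate": sub["estimate"].mean(),
                "se_mean": sub["estimate"].std(ddof=1) / math.sqrt(len(sub)),
                "bias": err.mean(),
                "rmse": math.sqrt((err**2).mean()),
                "coverage": sub["covered"].mean()
                if sub["covered"].notna().all()
                else float("nan"),
            }
        )

    return (
        report.groupby(["group", "estimand"])
        .apply(_agg, include_groups=False)
        .reset_index()
    )


def recovery_experiment(
    params: SynthParams,
    n_reps: int = 20,
    n_children: int = 50,
    estimands: Sequence[tuple[str, str]] = (
        ("CA_MATCH", "awc_age_slope"),
        ("HA_MATCH", "voc_dur_age_slope"),
    ),
    config: AnalysisConfig | None = None,
) -> dict:
    """End-to-end recovery harness over the requested (group, estimand)
    pairs; returns the raw replicate table and a bias/RMSE/coverage summary."""
    reports = [
        recover_age_slope(params, group, estimand, n_children, n_reps, config)
        for group, estimand in estimands
    ]
    raw = pd.concat(reports, ignore_index=True)
    return {"replicates": raw, "summary": summarize_recovery(raw)}
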