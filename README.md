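# daylongenv

Speech-environment analytics for daylong, speaker-diarized child-audio
recordings. Given segment-level diarizer output (speaker tag, onset/offset,
adult word estimates, contamination flags) and cohort metadata, the package

- applies the standard clip-exclusion rules (crying child clips, adult clips
  with non-speech, adult clips over 10 s) with per-recording accounting,
- derives hourly-normalized quantity metrics (adult words/hr, adult speech
  minutes/hr, child vocalizations/hr) and consistency metrics (proportion of
  minutes with ≥1 adult word or ≥1 child vocalization),
- detects caregiver–child conversational turns (child and adult clips within
  5 s of each other, in either order) and their quantity/5-min-epoch
  consistency,
- fits the statistical layer: hearing-group mixed models with random
  intercepts by child (and hour), likelihood-ratio model comparisons,
  per-group cross-sectional age slopes (chronological or hearing age), the
  turns×group vocal-productivity regression, and an outlier-exclusion
  sensitivity rerun,
- and ships a matched-cohort simulator (CI / chronological-age-match /
  hearing-age-match triads, bursty adult speech, contingent vocal responses)
  with closed-form expected rates, so every stage is testable and
  calibratable without audio.

## Data formats

Canonical segment CSV columns: `recording_id, child_id, speaker_tag,
onset_ms, offset_ms, word_count, has_cry, has_nonspeech, duration_ms`.
Speaker tags are `CHN` (target child), `FAN`/`MAN` (female/male adult near);
anything else maps to `OTHER`. Timestamps are integer milliseconds,
intervals half-open `[onset, offset)`; booleans are `0/1`. Cohort CSV:
`child_id, hearing_group, chrono_age_mo, activation_age_mo, hearing_age_mo,
maternal_ed, gender`. A best-effort reader for ITS-style XML
(`read_its_subset`) maps LENA-like speaker codes and PT-second timestamps
onto the same model.

## CLI

```bash
# generate a synthetic cohort and run everything on it
daylongenv synth --params params.yaml --out-dir out/

# or run the pipeline on your own tables
daylongenv run-all segments.csv cohort.csv --config config.yaml --out-dir out/

# stage-by-stage
daylongenv filter segments.csv --out-dir out/
daylongenv metrics segments.csv cohort.csv --out-dir out/
daylongenv turns segments.csv --out-dir out/
daylongenv models out/metrics.csv --hourly out/hourly.csv \
    --voc-durations out/voc_durations.csv --out-dir out/

# sensitivity rerun without a given child
daylongenv run-all segments.csv cohort.csv --exclude-child ci07 --out-dir out/

# parameter-recovery experiment (bias / RMSE / coverage)
daylongenv recover --reps 20 --n-children 50 --out-dir out/
```

Outputs are plain CSV/JSON (`metrics.csv`, `hourly.csv`, `turns.csv`,
`models.json`, `models_slopes.csv`, `filter_reports.csv`, `report.json`);
runs are byte-identical for identical inputs, config and seed.

## Python API

```python
from daylongenv import (
    AnalysisConfig, SynthParams, generate_cohort, generate_recording,
    filter_segments, compute_env_metrics, detect_turns, turn_metrics,
    run_pipeline, run_synthetic,
)

params = SynthParams(n_per_group=18, seed=1)
report = run_synthetic(params, AnalysisConfig(), "out/")
```

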