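"""End-to-end orchestration: ingest -> filter -> metrics -> turns -> models.

All outputs are plain CSV/JSON with deterministic content for a fixed
config, inputs and seed, so reruns are byte-identical and each stage can be
re-run from the previous stage's saved tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import stats_models, synth_cohort
from .env_metrics import hourly_long_table, metrics_table, voc_duration_table
from .filtering import FilterReport, filter_segments
from .segments_io import (
    AnalysisConfig,
    read_cohort_table,
    read_segment_table,
    write_cohort_table,
    write_segment_table,
)
from .turn_detection import detect_turns, turns_to_frame

logger = logging.getLogger(__name__)

__all__ = ["PipelineReport", "run_pipeline", "run_synthetic"]


@dataclass(slots=True)
class PipelineReport:
    """What a run produced, and with which knobs."""

    config_used: dict
    seed: int | None
    base_dir: Path | None = None
    filter_reports: list[FilterReport] = field(default_factory=list)
    output_paths: dict = field(default_factory=dict)
    run_log: list[str] = field(default_factory=list)
    degenerate: bool = False

    def log(self, event: str) -> None:
        self.run_log.append(event)
        logger.info(event)

    def _relative(self, path) -> str:
        # relative paths keep report.json portable and byte-stable across
        # output directories
        path = Path(path)
        if self.base_dir is not None:
            try:
                return str(path.relative_to(self.base_dir))
            except ValueError:
                return path.name
        return str(path)

    def to_dict(self) -> dict:
        return {
            "config_used": self.config_used,
            "seed": self.seed,
            "filter_reports": [r.to_dict() for r in self.filter_reports],
            "output_paths": {
                k: self._relative(v) for k, v in self.output_paths.items()
            },
            "run_log": self.run_log,
            "degenerate": self.degenerate,
        }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path


def _results_to_json(results: dict) -> dict:
    out: dict = {
        "group_models": {
            k: m.to_dict() for k, m in results["group_models"].items()
        },
        "group_lrt": {k: c.to_dict() for k, c in results["group_lrt"].items()},
        "slopes": [s.to_dict() for s in results["slopes"]],
        "productivity": results["productivity"].to_dict(),
    }
    return out


def _write_models(results: dict, out_dir: Path, report: PipelineReport,
                  stem: str = "models") -> None:
    models_path = out_dir / f"{stem}.json"
    models_path.write_text(
        json.dumps(_results_to_json(results), indent=2, sort_keys=True)
    )
    report.output_paths[stem] = models_path
    slopes = stats_models.slopes_to_frame(results["slopes"])
    slopes_path = out_dir / f"{stem}_slopes.csv"
    slopes.to_csv(slopes_path, index=False, lineterminator="\n")
    report.output_paths[f"{stem}_slopes"] = slopes_path


def run_pipeline(
    segments_path: str | Path,
    cohort_path: str | Path,
    config: AnalysisConfig | None = None,
    out_dir: str | Path = "out",
    seed: int | None = None,
) -> PipelineReport:
    """Run the whole post-diarization analysis and write every table.

    Stages: filtering (with per-recording removal accounting) -> quantity
    and consistency metrics -> turn detection -> group models, age slopes
    on both bases, the productivity model, and — when the config excludes
    children — the sensitivity rerun.
    """
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(
        config_used=config.to_dict(), seed=seed, base_dir=out_dir
    )

    report.log(f"ingest: {Path(segments_path).name}")
    recordings = read_segment_table(segments_path, config)
    cohort = read_cohort_table(cohort_path)
    report.log(
        f"ingest: {len(recordings)} recording(s), {len(cohort)} child(ren)"
    )

    filtered = []
    for rec in recordings:
        frec, frep = filter_segments(rec, config)
        filtered.append(frec)
        report.filter_reports.append(frep)
        report.log(
            f"filter {rec.recording_id}: removed {frep.n_removed}/"
            f"{frep.n_total} (cry={frep.n_removed_chn_cry}, "
            f"nonspeech={frep.n_removed_adult_nonspeech}, "
            f"long={frep.n_removed_adult_long})"
        )
    filt_path = out_dir / "filter_reports.csv"
    pd.DataFrame([r.to_dict() for r in report.filter_reports]).to_csv(
        filt_path, index=False, lineterminator="\n"
    )
    report.output_paths["filter_reports"] = filt_path
    seg_path = out_dir / "filtered_segments.csv"
    write_segment_table(filtered, seg_path)
    report.output_paths["filtered_segments"] = seg_path

    if not recordings:
        report.degenerate = True
        report.log("no recordings: writing empty outputs")
        for stem in ("metrics", "hourly", "voc_durations", "turns"):
            path = out_dir / f"{stem}.csv"
            pd.DataFrame().to_csv(path, index=False, lineterminator="\n")
            report.output_paths[stem] = path
        report.output_paths["report"] = report.write(out_dir / "report.json")
        return report

    per_child = metrics_table(cohort, filtered, config, with_turns=True)
    metrics_path = out_dir / "metrics.csv"
    per_child.to_csv(metrics_path, index=False, lineterminator="\n")
    report.output_paths["metrics"] = metrics_path

    hourly = hourly_long_table(filtered)
    hourly_path = out_dir / "hourly.csv"
    hourly.to_csv(hourly_path, index=False, lineterminator="\n")
    report.output_paths["hourly"] = hourly_path

    voc_dur = voc_duration_table(filtered)
    voc_path = out_dir / "voc_durations.csv"
    voc_dur.to_csv(voc_path, index=False, lineterminator="\n")
    report.output_paths["voc_durations"] = voc_path

    turns = [ev for rec in filtered for ev in detect_turns(rec, config)]
    turns_path = out_dir / "turns.csv"
    turns_to_frame(turns).to_csv(turns_path, index=False, lineterminator="\n")
    report.output_paths["turns"] = turns_path
    report.log(f"turns: {len(turns)} event(s)")

    try:
        results = stats_models.fit_all_models(per_child, hourly, voc_dur, config)
        _write_models(results, out_dir, report)
        report.log("models: fit complete")
        if config.exclude_child_ids:
            sens = stats_models.sensitivity_rerun(
                per_child, hourly, voc_dur, config
            )
            _write_models(sens["reduced"], out_dir, report, stem="models_reduced")
            shifts_path = out_dir / "sensitivity_shifts.csv"
            sens["shifts"].to_csv(shifts_path, index=False, lineterminator="\n")
            report.output_paths["sensitivity_shifts"] = shifts_path
            report.log(
                f"sensitivity rerun: excluded {list(config.exclude_child_ids)}"
            )
    except stats_models.DegenerateDesignError as exc:
        report.degenerate = True
        report.log(f"models: degenerate design ({exc})")

    report.output_paths["report"] = report.write(out_dir / "report.json")
    return report


def run_synthetic(
    params: synth_cohort.SynthParams | str | Path,
    config: AnalysisConfig | None = None,
    out_dir: str | Path = "out",
    recovery_reps: int = 0,
) -> PipelineReport:
    """Generate a matched cohort + recordings, then run the full pipeline.

    With ``recovery_reps > 0`` a parameter-recovery experiment is run on
    top and its replicate/summary tables written alongside the pipeline
    outputs.
    """
    if not isinstance(params, synth_cohort.SynthParams):
        params = synth_cohort.SynthParams.from_yaml(params)
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = synth_cohort.generate_cohort(params)
    recordings = synth_cohort.generate_recordings(cohort, params)
    seg_path = out_dir / "synthetic_segments.csv"
    write_segment_table(recordings, seg_path)
    cohort_path = out_dir / "synthetic_cohort.csv"
    write_cohort_table(cohort, cohort_path)

    report = run_pipeline(seg_path, cohort_path, config, out_dir, params.seed)
    report.output_paths["synthetic_segments"] = seg_path
    report.output_paths["synthetic_cohort"] = cohort_path
    report.log(
        f"synth: {len(cohort)} children, seed={params.seed}, "
        f"{params.recording_hours} h/recording"
    )

    if recovery_reps > 0:
        result = synth_cohort.recovery_experiment(
            params, n_reps=recovery_reps, config=config
        )
        rep_path = out_dir / "recovery_replicates.csv"
        result["replicates"].to_csv(rep_path, index=False, lineterminator="\n")
        summ_path = out_dir / "recovery_summary.csv"
        result["summary"].to_csv(summ_path, index=False, lineterminator="\n")
        report.output_paths["recovery_replicates"] = rep_path
        report.output_paths["recovery_summary"] = summ_path
        report.log(f"recovery: {recovery_reps} replicate(s)")

    report.output_paths["report"] = report.write(out_dir / "report.json")
    return report
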