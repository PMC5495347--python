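"""End-to-end orchestration: subject runs and full study runs.

``run_subject`` chains calibration -> segment frames -> joint angles ->
repetition detection -> occlusion filter -> selection -> time
normalization -> AVS/APS scoring -> spatiotemporal / PTA / ROM extraction,
producing per-repetition and per-subject aggregated outcome rows.
``run_study`` maps it over a cohort and hands the outcome table to the
statistics battery. Every exclusion or selection decision is emitted as a
structured log record, mirroring the traceability the study's manual
selection steps would need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from armkin.kinematics import (
    LandmarkModel,
    calibrate_landmarks,
    compute_joint_angles,
    compute_segment_frames,
)
from armkin.markers import DEFAULT_MARKER_SET, MarkerSetDefinition, MarkerTrajectorySet
from armkin.outcomes import ReferenceBank, aggregate_subject, score_repetition
from armkin.segmentation import (
    DetectionConfig,
    detect_repetitions,
    filter_by_occlusion,
    select_repetitions,
)
from armkin.stats import StatsReport, run_group_comparison

log = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Pipeline parameters, each a named key with its protocol default."""

    normalization_points: int = Field(101, ge=2)
    occlusion_threshold: float = Field(0.20, ge=0.0, le=1.0)
    selection_k: int = Field(2, ge=1)
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    correlation_display_min: float = 0.30
    avs_mode: str = "mean_reference"
    lowpass_hz: float = 6.0
    speed_rise: float = 0.05
    home_radius: float = 0.05
    seed: int = 0

    def detection(self) -> DetectionConfig:
        return DetectionConfig(
            speed_rise=self.speed_rise,
            home_radius=self.home_radius,
            lowpass_hz=self.lowpass_hz,
        )


@dataclass
class SubjectResult:
    """Per-repetition rows, aggregate rows and the segments that produced
    them; tasks that failed a stage are listed in ``skipped``."""

    repetitions: pd.DataFrame
    aggregate: pd.DataFrame
    segments: list = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)


def run_subject(
    static: MarkerTrajectorySet,
    dynamics: dict[str, list[MarkerTrajectorySet]],
    bank: ReferenceBank,
    subject: str = "",
    markerset: MarkerSetDefinition = DEFAULT_MARKER_SET,
    config: RunConfig | None = None,
    model: LandmarkModel | None = None,
) -> SubjectResult:
    """All outcome rows for one subject (tasks -> list of recordings).

    A task whose processing fails at any stage is skipped with a structured
    log entry; the run continues with the remaining tasks.
    """
    config = config or RunConfig()
    if model is None:
        model = calibrate_landmarks(static, markerset)
    rep_rows, all_segments, skipped = [], [], {}
    for task, recordings in dynamics.items():
        try:
            selected_pairs = []
            segments_task = []
            for r, trial in enumerate(recordings):
                angles = compute_joint_angles(
                    compute_segment_frames(trial, model,
                                           lowpass_hz=config.lowpass_hz)
                )
                segs = detect_repetitions(trial, task, config.detection(),
                                          recording=f"rec{r}")
                segs = filter_by_occlusion(segs, trial,
                                           threshold=config.occlusion_threshold)
                segments_task.extend(segs)
                selected_pairs.extend((trial, angles, s) for s in segs)
            chosen = select_repetitions([s for _, _, s in selected_pairs],
                                        k=config.selection_k)
            all_segments.extend(segments_task)
            if not chosen:
                skipped[task] = "no surviving repetitions"
                log.warning("subject=%s task=%s skipped: no repetitions",
                            subject, task)
                continue
            chosen_ids = {(s.recording, s.repetition) for s in chosen}
            for trial, angles, seg in selected_pairs:
                if (seg.recording, seg.repetition) in chosen_ids:
                    rep_rows.append(
                        score_repetition(trial, angles, seg, bank,
                                         subject=subject,
                                         avs_mode=config.avs_mode)
                    )
        except Exception as exc:  # stage failure: skip task, keep running
            skipped[task] = str(exc)
            log.warning("subject=%s task=%s skipped: %s", subject, task, exc)
    reps = pd.DataFrame(rep_rows)
    agg = aggregate_subject(reps) if not reps.empty else pd.DataFrame()
    return SubjectResult(repetitions=reps, aggregate=agg,
                         segments=all_segments, skipped=skipped)


def run_study(
    cohort,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, StatsReport]:
    """Process a :class:`~armkin.simulate.CohortBundle` end to end.

    Returns the per-subject outcome table and the statistics report
    (Kruskal-Wallis + post-hoc, correlations, stepwise regression per task).
    Deterministic given the cohort and config.
    """
    config = config or RunConfig()
    if not cohort.subjects:
        raise ValueError("empty cohort")
    agg_rows = []
    for sid, sub in cohort.subjects.items():
        res = run_subject(sub["static"], sub["recordings"], cohort.bank,
                          subject=sid, config=config)
        if not res.aggregate.empty:
            agg_rows.append(res.aggregate)
    outcomes = pd.concat(agg_rows, ignore_index=True)
    report = run_group_comparison(outcomes, cohort.clinical, alpha=config.alpha)
    return outcomes, report


def load_cohort_tree(directory: str | Path, format: str = "trc"):
    """Re-assemble a cohort written by :func:`armkin.simulate.write_cohort`."""
    import json

    from armkin.markers import read_marker_trial
    from armkin.simulate import CohortBundle, SimulationConfig

    directory = Path(directory)
    bank = ReferenceBank.load(directory / "reference_bank")
    clinical = pd.read_csv(directory / "clinical.csv")
    truths = json.loads((directory / "ground_truth.json").read_text())
    subjects = {}
    for sid in sorted(truths):
        sdir = directory / sid
        static = read_marker_trial(sdir / f"static.{format}", trial_kind="static")
        recordings: dict[str, list] = {}
        for p in sorted(sdir.glob(f"*_rec*.{format}")):
            task = p.stem.split("_")[0]
            recordings.setdefault(task, []).append(
                read_marker_trial(p, task=task)
            )
        subjects[sid] = {"static": static, "recordings": recordings,
                         "truth": truths[sid], "macs": truths[sid]["macs"]}
    return CohortBundle(config=SimulationConfig(), bank=bank,
                        subjects=subjects, clinical=clinical)
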