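"""End-to-end study runner.

``run_study`` drives the whole analysis on a simulated cohort: render both
sensor streams from the shared ground truth, process each branch
independently, segment repetitions on each branch's own vertical
displacement, extract per-repetition outcomes and per-task medians, apply the
heading-drift QC, and produce the agreement report (the Table-1 analogue),
between-task comparisons for both sources, and between-gender comparisons on
the smartphone data.

A run is reproducible from config + seed alone; every output table carries a
hash of the configuration.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import OutcomeParams, PLANES, TaskLabel
from .fileio import write_table
from .mocap import process_mocap
from .outcomes import compute_rep_outcomes, summarize_task
from .phone import process_phone, qc_heading_drift
from .segment import SegmentationParams, segment_kinematics
from .simulate import CohortRecording, SimulationConfig, simulate_cohort
from .stats import (
    OUTCOME_UNITS,
    agreement_report_frame,
    build_agreement_report,
    compare_groups,
    compare_tasks,
)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, TaskLabel):
        return obj.value
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


@dataclass
class RunConfig:
    """Everything needed to reproduce a study run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    outcome_params: OutcomeParams = field(default_factory=OutcomeParams)
    alpha: float = 0.05
    drift_threshold_deg: float = 5.0
    icc_model: str = "auto"
    strict: bool = False
    noise_scale: float = 1.0
    make_figures: bool = False
    out_dir: str | None = None

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = _jsonable(self)
        for key in ("out_dir", "make_figures"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(_jsonable(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", {})
        seg = raw.pop("segmentation", {})
        out = raw.pop("outcome_params", {})
        for key in ("tasks", "mounting_offset_deg", "sway_band_hz"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        return cls(
            simulation=SimulationConfig(**sim),
            segmentation=SegmentationParams(**seg),
            outcome_params=OutcomeParams(**out),
            **raw,
        )


def process_recording(
    rec: CohortRecording, config: RunConfig
) -> tuple[dict, dict]:
    """Both branches of one recording -> two outcome-table rows (mocap, phone)."""
    rows = {}
    seg_params = config.segmentation
    expected = config.simulation.reps_per_task

    kin_mocap = process_mocap(rec.markers)
    kin_phone = process_phone(rec.phone)

    drift = qc_heading_drift(
        kin_phone["transverse"],
        kin_phone.rate,
        pre_window_s=min(4.0, config.simulation.quiet_pre_s),
        post_window_s=min(4.0, config.simulation.quiet_post_s),
        threshold_deg=config.drift_threshold_deg,
    )

    for kin in (kin_mocap, kin_phone):
        marks = segment_kinematics(
            kin, seg_params, expected_reps=expected, strict=config.strict
        )
        row = {
            "participant": rec.participant,
            "gender": rec.gender,
            "task": rec.task.value,
            "source": kin.source,
            "drift_excluded": not drift.passed,
            "drift_deg": drift.drift_deg,
        }
        if marks.n_reps == 0:
            # unusable waveform (permissive mode): row kept, outcomes missing
            row.update(
                {
                    "duration": np.nan,
                    "ml_acceleration": np.nan,
                    "n_reps": 0,
                    "flags": ";".join(marks.flags + ["no_reps_detected"]),
                    **{plane: np.nan for plane in PLANES},
                }
            )
            rows[kin.source] = row
            continue
        reps = compute_rep_outcomes(
            kin, marks, config.outcome_params.peak_window_s, strict=config.strict
        )
        summary = summarize_task(
            reps, rec.participant, rec.task, kin.source, flags=marks.flags
        )
        row.update(
            {
                "duration": summary.median_duration_s,
                "ml_acceleration": summary.median_ml_variability_ms2,
                "n_reps": summary.n_reps,
                "flags": ";".join(summary.flags),
            }
        )
        for plane in PLANES:
            row[plane] = summary.median_orientation_delta_deg[plane]
        rows[kin.source] = row
    return rows["mocap"], rows["phone"]


@dataclass
class StudyResult:
    config_hash: str
    outcomes: pd.DataFrame
    agreement_rows: list
    agreement: pd.DataFrame
    task_comparisons: pd.DataFrame
    task_posthoc: pd.DataFrame
    group_comparisons: pd.DataFrame
    qc: dict


def run_study(config: RunConfig) -> StudyResult:
    """Simulate the cohort and run the full two-branch analysis."""
    cohort = simulate_cohort(config.simulation, noise_scale=config.noise_scale)
    records = []
    for rec in cohort:
        mocap_row, phone_row = process_recording(rec, config)
        records.extend([mocap_row, phone_row])
    outcomes = pd.DataFrame.from_records(records).sort_values(
        ["participant", "task", "source"], ignore_index=True
    )

    rows = build_agreement_report(
        outcomes, alpha=config.alpha, icc_model=config.icc_model
    )
    agreement = agreement_report_frame(rows)

    comp_records, posthoc_records = [], []
    for source in ("mocap", "phone"):
        sub = outcomes[outcomes["source"] == source]
        for outcome in OUTCOME_UNITS:
            wide = sub.pivot(index="participant", columns="task", values=outcome)
            wide = wide[[t.value for t in config.simulation.tasks if t.value in wide]]
            if wide.shape[1] < 3:
                continue
            res = compare_tasks(wide, alpha=config.alpha)
            comp_records.append(
                {
                    "source": source,
                    "outcome": outcome,
                    "test": res.test,
                    "statistic": res.statistic,
                    "df1": None if res.df is None else res.df[0],
                    "df2": None if res.df is None else res.df[1],
                    "p": res.p,
                    "n": res.n,
                    "n_dropped": res.n_dropped,
                }
            )
            for ph in res.posthoc:
                posthoc_records.append(
                    {
                        "source": source,
                        "outcome": outcome,
                        "task_a": ph.pair[0],
                        "task_b": ph.pair[1],
                        "test": ph.test,
                        "statistic": ph.statistic,
                        "p_raw": ph.p_raw,
                        "p_bonferroni": ph.p_adjusted,
                        "mean_difference": ph.mean_difference,
                    }
                )
    task_comparisons = pd.DataFrame.from_records(comp_records)
    task_posthoc = pd.DataFrame.from_records(posthoc_records)

    group_records = []
    phone_rows = outcomes[outcomes["source"] == "phone"]
    for outcome in OUTCOME_UNITS:
        for task in config.simulation.tasks:
            sub = phone_rows[phone_rows["task"] == task.value]
            if sub["gender"].nunique() != 2:
                continue
            if sub.groupby("gender")[outcome].size().min() < 3:
                continue
            res = compare_groups(
                sub[outcome].to_numpy(), sub["gender"].to_numpy(), config.alpha
            )
            group_records.append(
                {
                    "outcome": outcome,
                    "task": task.value,
                    "test": res.test,
                    "statistic": res.statistic,
                    "p": res.p,
                    **{f"mean_{g}": v for g, v in res.group_means.items()},
                }
            )
    group_comparisons = pd.DataFrame.from_records(group_records)

    qc = {
        "n_recordings": len(cohort),
        "n_drift_excluded": int(
            outcomes.loc[outcomes["source"] == "phone", "drift_excluded"].sum()
        ),
        "n_count_mismatch": int(
            outcomes["flags"].str.contains("count_mismatch").sum()
        ),
    }

    config_hash = config.config_hash()
    result = StudyResult(
        config_hash=config_hash,
        outcomes=outcomes,
        agreement_rows=rows,
        agreement=agreement,
        task_comparisons=task_comparisons,
        task_posthoc=task_posthoc,
        group_comparisons=group_comparisons,
        qc=qc,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(out / "task_outcomes.csv", outcomes, config_hash)
        write_table(out / "agreement.csv", agreement, config_hash)
        write_table(out / "task_comparisons.csv", task_comparisons, config_hash)
        write_table(out / "task_posthoc.csv", task_posthoc, config_hash)
        write_table(out / "group_comparisons.csv", group_comparisons, config_hash)
        (out / "qc.json").write_text(
            json.dumps({"config_hash": config_hash, **qc}, indent=1)
        )
        if config.make_figures:
            from .plots import bland_altman_grid, task_boxplots

            bland_altman_grid(outcomes, out / "bland_altman.png")
            task_boxplots(outcomes, out / "task_boxplots.png")
    return result
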