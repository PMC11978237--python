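"""Per-repetition outcomes and per-task summaries.

Three outcome families, computed identically for both sensor branches:

* repetition duration — end minus start of the movement (interpolated
  threshold crossings);
* mediolateral-acceleration variability — sample standard deviation of the
  filtered mediolateral acceleration between start and end, a postural-sway
  proxy;
* pelvic orientation at peak squat — mean orientation per plane over a 200 ms
  window centred on the peak, minus the quiet-standing baseline of the same
  branch (each branch subtracts its own baseline, so constant mounting
  offsets cancel).

The per-task summary is the componentwise median across repetitions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PelvicKinematics, PelvikinError, PLANES, TaskLabel
from .segment import RepetitionMarks


class WindowError(PelvikinError):
    """Peak window does not fit inside the recording."""


@dataclass(frozen=True)
class RepetitionOutcome:
    duration_s: float
    ml_variability_ms2: float
    orientation_delta_deg: dict[str, float]
    plateau_used: bool = False
    truncated_window: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("repetition duration must be positive")
        if self.ml_variability_ms2 < 0:
            raise ValueError("acceleration variability cannot be negative")


@dataclass
class TaskOutcome:
    """Median outcomes for one participant x task x source."""

    participant: int
    task: TaskLabel
    source: str
    median_duration_s: float
    median_ml_variability_ms2: float
    median_orientation_delta_deg: dict[str, float]
    n_reps: int
    flags: list[str] = field(default_factory=list)


def orientation_at_peak(
    kinematics: PelvicKinematics,
    marks: RepetitionMarks,
    window_s: float = 0.2,
    strict: bool = True,
) -> list[dict[str, float]]:
    """Baseline-subtracted window-mean orientation per repetition.

    For each repetition, every sample whose centre lies within half the
    window of the peak time (inclusive) contributes to the per-plane mean;
    the branch's own baseline angle is subtracted.  A window extending past
    the recording raises in strict mode and is truncated (and flagged on the
    outcome) in permissive mode.
    """
    times = kinematics.series.times()
    half = window_s / 2 + 1e-12
    out = []
    for rep in marks.reps:
        inside = np.abs(times - rep.peak_time) <= half
        truncated = (
            rep.peak_time - window_s / 2 < times[0] - 1e-12
            or rep.peak_time + window_s / 2 > times[-1] + 1e-12
        )
        if truncated and strict:
            raise WindowError(
                f"peak window around t={rep.peak_time:.3f} s exceeds the recording"
            )
        if not np.any(inside):
            raise WindowError(f"no samples inside peak window at t={rep.peak_time:.3f} s")
        deltas = {
            plane: float(
                np.mean(kinematics[plane][inside]) - marks.baseline_values[plane]
            )
            for plane in PLANES
        }
        deltas["_truncated"] = float(truncated)
        out.append(deltas)
    return out


def rep_duration(marks: RepetitionMarks) -> list[float]:
    """Seconds per repetition, from the interpolated start/end crossings."""
    return [rep.duration for rep in marks.reps]


def ml_variability(
    kinematics: PelvicKinematics, marks: RepetitionMarks
) -> list[float]:
    """Sample SD (ddof=1) of the mediolateral acceleration within each rep."""
    times = kinematics.series.times()
    out = []
    for rep in marks.reps:
        inside = (times >= rep.start_time) & (times <= rep.end_time)
        seg = kinematics["ml_acc"][inside]
        if seg.shape[0] < 2:
            raise WindowError(
                f"fewer than 2 acceleration samples in repetition at "
                f"t={rep.start_time:.3f} s"
            )
        out.append(float(np.std(seg, ddof=1)))
    return out


def compute_rep_outcomes(
    kinematics: PelvicKinematics,
    marks: RepetitionMarks,
    window_s: float = 0.2,
    strict: bool = True,
) -> list[RepetitionOutcome]:
    """All three outcome families for every detected repetition."""
    deltas = orientation_at_peak(kinematics, marks, window_s, strict)
    durations = rep_duration(marks)
    variability = ml_variability(kinematics, marks)
    return [
        RepetitionOutcome(
            duration_s=dur,
            ml_variability_ms2=var,
            orientation_delta_deg={p: dl[p] for p in PLANES},
            plateau_used=rep.plateau_used,
            truncated_window=bool(dl["_truncated"]),
        )
        for dur, var, dl, rep in zip(durations, variability, deltas, marks.reps)
    ]


def summarize_task(
    rep_outcomes: list[RepetitionOutcome],
    participant: int,
    task: TaskLabel,
    source: str,
    flags: list[str] | None = None,
) -> TaskOutcome:
    """Componentwise median across repetitions (mean of middle two if even)."""
    if not rep_outcomes:
        raise ValueError("cannot summarise an empty repetition list")
    return TaskOutcome(
        participant=participant,
        task=TaskLabel(task),
        source=source,
        median_duration_s=float(np.median([r.duration_s for r in rep_outcomes])),
        median_ml_variability_ms2=float(
            np.median([r.ml_variability_ms2 for r in rep_outcomes])
        ),
        median_orientation_delta_deg={
            p: float(np.median([r.orientation_delta_deg[p] for r in rep_outcomes]))
            for p in PLANES
        },
        n_reps=len(rep_outcomes),
        flags=list(flags or []),
    )
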