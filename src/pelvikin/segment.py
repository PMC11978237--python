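"""Repetition segmentation from a vertical-displacement channel.

An automatic, parameterised replacement for visual event picking: a stable
quiet-standing baseline is located first, then repetitions are found as
hysteretic threshold excursions below the baseline, with sub-sample crossing
refinement (duration is an outcome, so crossings are linearly interpolated
between samples).  Because the start/end are exit-threshold crossings that lie
strictly inside the true movement span, detected durations are systematically
shorter than true durations — the same direction of bias a displacement
threshold produces on real recordings.

Marks serialise to JSON so they can be corrected by hand and fed back into
the downstream stages.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    CountMismatchError,
    PelvicKinematics,
    PLANES,
    UnstableBaselineError,
)


@dataclass(frozen=True)
class SegmentationParams:
    """All constants of the segmentation automaton.

    ``enter_threshold_m`` arms a candidate repetition; the span then extends
    outward to the crossings of ``enter_threshold_m * exit_ratio``
    (hysteresis).  Spans shorter than ``min_duration_s`` or shallower than
    ``min_depth_m`` are discarded.  A flat bottom within
    ``plateau_tolerance_m`` of the minimum lasting at least ``plateau_min_s``
    reports its temporal midpoint as the peak.

    ``local_baseline_window_s`` replaces the global quiet-standing baseline
    with a rolling upper percentile of the displacement itself — the
    automated analogue of reading events against the local pre-repetition
    rest level, which a visual analyst does implicitly.  High-pass-estimated
    displacement (the phone branch) has no stable DC level: the drift filter
    removes the mean of the squat-pulse train, elevating the between-rep rest
    level by several centimetres, so global-baseline thresholds would fire
    far inside the movement.  For an undistorted channel the rolling
    percentile equals the quiet-standing level and the two references
    coincide.  Set to ``None`` for the plain global-baseline behaviour.
    """

    enter_threshold_m: float = 0.010
    exit_ratio: float = 0.5
    min_duration_s: float = 1.0
    min_depth_m: float = 0.030
    plateau_tolerance_m: float = 0.002
    plateau_min_s: float = 0.2
    quiet_duration_s: float = 5.0
    stability_window_s: float = 0.5
    variance_ceiling_deg2: float = 2.0
    local_baseline_window_s: float | None = 8.0
    local_baseline_percentile: float = 80.0
    end_guard_s: float = 2.0

    def __post_init__(self) -> None:
        if self.enter_threshold_m <= 0:
            raise ValueError("enter threshold must be positive")
        if not 0 < self.exit_ratio <= 1:
            raise ValueError("exit ratio must be in (0, 1]")
        if self.local_baseline_window_s is not None and self.local_baseline_window_s <= 0:
            raise ValueError("local baseline window must be positive")


@dataclass(frozen=True)
class RepMark:
    start_time: float
    peak_time: float
    end_time: float
    start_index: int
    peak_index: int
    end_index: int
    plateau_used: bool = False

    def __post_init__(self) -> None:
        if not self.start_time < self.peak_time < self.end_time:
            raise ValueError(
                f"repetition marks must be ordered start < peak < end, got "
                f"({self.start_time}, {self.peak_time}, {self.end_time})"
            )

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class RepetitionMarks:
    """Baseline plus ordered, non-overlapping per-repetition events."""

    baseline_index: int
    baseline_time: float
    baseline_values: dict[str, float]
    reps: list[RepMark]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.reps, self.reps[1:]):
            if cur.start_time < prev.end_time:
                raise ValueError("repetitions overlap or are out of order")
        if self.reps and self.baseline_time > self.reps[0].start_time:
            raise ValueError("baseline must precede the first repetition start")

    @property
    def n_reps(self) -> int:
        return len(self.reps)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "baseline_index": self.baseline_index,
            "baseline_time": self.baseline_time,
            "baseline_values": self.baseline_values,
            "flags": self.flags,
            "reps": [dataclasses.asdict(r) for r in self.reps],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RepetitionMarks":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            baseline_index=payload["baseline_index"],
            baseline_time=payload["baseline_time"],
            baseline_values=payload["baseline_values"],
            reps=[RepMark(**r) for r in payload["reps"]],
            flags=list(payload.get("flags", [])),
        )


def _rolling_variance(x: np.ndarray, window: int) -> np.ndarray:
    """Variance over each length-``window`` block (population form)."""
    c1 = np.cumsum(np.insert(x, 0, 0.0))
    c2 = np.cumsum(np.insert(x * x, 0, 0.0))
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    return np.maximum(s2 / window - (s1 / window) ** 2, 0.0)


def find_baseline(
    kinematics: PelvicKinematics,
    quiet_duration_s: float = 5.0,
    stability_window_s: float = 0.5,
    variance_ceiling_deg2: float = 2.0,
) -> tuple[int, dict[str, float]]:
    """Locate the stillest window inside the pre-task quiet standing.

    Returns the centre sample index of the ``stability_window_s`` window with
    the minimal summed rolling variance of the three angle channels within the
    first ``quiet_duration_s`` of the recording, and the window means of every
    kinematics channel (the baseline values).
    """
    rate = kinematics.rate
    n_quiet = int(round(quiet_duration_s * rate))
    if n_quiet > kinematics.series.n:
        raise UnstableBaselineError(
            f"recording has only {kinematics.series.n / rate:.2f} s, shorter than "
            f"the {quiet_duration_s} s pre-task quiet standing"
        )
    window = max(2, int(round(stability_window_s * rate)))
    if window > n_quiet:
        raise UnstableBaselineError("stability window longer than the quiet span")

    total = np.zeros(n_quiet - window + 1)
    for plane in PLANES:
        total += _rolling_variance(kinematics[plane][:n_quiet], window)
    best = int(np.argmin(total))
    if total[best] > variance_ceiling_deg2:
        raise UnstableBaselineError(
            f"no stable window: minimal summed angle variance "
            f"{total[best]:.3f} deg^2 exceeds ceiling {variance_ceiling_deg2}"
        )
    center = best + window // 2
    values = {
        name: float(np.mean(kinematics[name][best : best + window]))
        for name in kinematics.series.channels
    }
    return center, values


def _local_baseline(
    x: np.ndarray, rate: float, window_s: float, percentile: float
) -> np.ndarray:
    """Rolling upper-percentile rest-level estimate of a displacement channel.

    Computed on a ~20 Hz decimated copy (the rest level is a sub-0.2 Hz
    object) and linearly interpolated back to the full grid.
    """
    from scipy import ndimage

    step = max(1, int(round(rate / 20.0)))
    coarse = x[::step]
    size = max(3, int(round(window_s * rate / step)))
    size = min(size, coarse.shape[0])
    env = ndimage.percentile_filter(coarse, percentile, size=size, mode="nearest")
    idx_coarse = np.arange(coarse.shape[0]) * step
    return np.interp(np.arange(x.shape[0]), idx_coarse, env)


def _cross_time(t0: float, d0: float, t1: float, d1: float, level: float) -> float:
    """Linear-interpolated time where the segment (t0,d0)-(t1,d1) hits level."""
    if d1 == d0:
        return t0
    frac = (level - d0) / (d1 - d0)
    return t0 + frac * (t1 - t0)


def detect_repetitions(
    vertical_displacement: np.ndarray,
    rate: float,
    baseline_value: float,
    params: SegmentationParams = SegmentationParams(),
    t0: float = 0.0,
    expected_reps: int | None = None,
) -> tuple[list[RepMark], list[str]]:
    """Find repetitions as hysteretic excursions below the baseline.

    Candidate repetitions are maximal spans where the displacement deviates
    below ``baseline - enter_threshold``; the span boundaries are the
    outermost crossings of the exit threshold, refined by linear
    interpolation.  The baseline is either the supplied quiet-standing value
    or, with ``params.local_baseline_window_s`` set, a rolling upper
    percentile of the channel (see :class:`SegmentationParams`).  Detection
    is invariant to adding a constant to the displacement channel
    (everything is baseline-relative).
    """
    x = np.asarray(vertical_displacement, dtype=float)
    if params.local_baseline_window_s is not None:
        d = x - _local_baseline(
            x, rate, params.local_baseline_window_s, params.local_baseline_percentile
        )
    else:
        d = x - baseline_value
    n = d.shape[0]
    dt = 1.0 / rate
    thr_in = -params.enter_threshold_m
    thr_out = -params.enter_threshold_m * params.exit_ratio

    below = d < thr_in
    if not np.any(below):
        flags = []
        if expected_reps:
            flags.append(f"count_mismatch: found 0, expected {expected_reps}")
        return [], flags

    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    run_starts = ([0] if below[0] else []) + [int(e) + 1 for e in edges if not below[e]]
    run_ends = [int(e) for e in edges if below[e]] + ([n - 1] if below[-1] else [])

    spans: list[tuple[float, float, int, int]] = []
    for i0, i1 in zip(run_starts, run_ends):
        j = i0
        while j > 0 and d[j - 1] < thr_out:
            j -= 1
        if j == 0:
            t_start = t0
        else:
            t_start = _cross_time(
                t0 + (j - 1) * dt, d[j - 1], t0 + j * dt, d[j], thr_out
            )
        k = i1
        while k < n - 1 and d[k + 1] < thr_out:
            k += 1
        if k == n - 1:
            t_end = t0 + k * dt
        else:
            t_end = _cross_time(
                t0 + k * dt, d[k], t0 + (k + 1) * dt, d[k + 1], thr_out
            )
        spans.append((t_start, t_end, j, k))

    # merge spans whose hysteresis extensions touch
    merged: list[tuple[float, float, int, int]] = []
    for span in spans:
        if merged and span[0] <= merged[-1][1]:
            prev = merged[-1]
            merged[-1] = (prev[0], max(prev[1], span[1]), prev[2], max(prev[3], span[3]))
        else:
            merged.append(span)

    reps: list[RepMark] = []
    flags: list[str] = []
    for t_start, t_end, j, k in merged:
        if t_end - t_start < params.min_duration_s:
            continue
        seg = d[j : k + 1]
        depth = -float(seg.min())
        if depth < params.min_depth_m:
            continue
        i_min = j + int(np.argmin(seg))
        plateau_used = False
        peak_time = t0 + i_min * dt
        # plateau: contiguous samples around the minimum within tolerance
        level = seg.min() + params.plateau_tolerance_m
        lo = i_min
        while lo > j and d[lo - 1] <= level:
            lo -= 1
        hi = i_min
        while hi < k and d[hi + 1] <= level:
            hi += 1
        if (hi - lo) * dt >= params.plateau_min_s:
            peak_time = t0 + 0.5 * (lo + hi) * dt
            plateau_used = True
        reps.append(
            RepMark(
                start_time=t_start,
                peak_time=peak_time,
                end_time=t_end,
                start_index=int(round((t_start - t0) * rate)),
                peak_index=int(round((peak_time - t0) * rate)),
                end_index=int(round((t_end - t0) * rate)),
                plateau_used=plateau_used,
            )
        )

    if expected_reps is not None and len(reps) != expected_reps:
        flags.append(f"count_mismatch: found {len(reps)}, expected {expected_reps}")
    return reps, flags


def validate_marks(
    marks: RepetitionMarks, expected_reps: int, strict: bool = True
) -> RepetitionMarks:
    """Check the detected repetition count against the protocol.

    Strict mode raises on a mismatch; permissive mode flags the marks and
    lets the analysis proceed on everything that was found.
    """
    if marks.n_reps == expected_reps:
        return marks
    message = f"count_mismatch: found {marks.n_reps}, expected {expected_reps}"
    if strict:
        raise CountMismatchError(message)
    if message not in marks.flags:
        marks.flags.append(message)
    return marks


def segment_kinematics(
    kinematics: PelvicKinematics,
    params: SegmentationParams = SegmentationParams(),
    expected_reps: int | None = None,
    strict: bool = False,
) -> RepetitionMarks:
    """Baseline + repetition detection on one processed recording."""
    center, values = find_baseline(
        kinematics,
        params.quiet_duration_s,
        params.stability_window_s,
        params.variance_ceiling_deg2,
    )
    t0 = kinematics.series.t0
    reps, flags = detect_repetitions(
        kinematics["vertical_disp"],
        kinematics.rate,
        values["vertical_disp"],
        params,
        t0=t0,
    )
    baseline_time = t0 + center / kinematics.rate
    artifacts = [r for r in reps if r.start_time < baseline_time]
    if artifacts:
        # a squat cannot precede the quiet standing; edge artifacts only
        reps = [r for r in reps if r.start_time >= baseline_time]
        flags.append(f"pre_baseline_rep_discarded: {len(artifacts)}")
    # zero-phase filtering (and, for integrated displacement estimates, the
    # drift filter especially) leaves a transient at the recording edges;
    # spans reaching into the trailing guard are artifacts, not squats
    end_time = t0 + (kinematics.series.n - 1) / kinematics.rate
    tail = [r for r in reps if r.end_time > end_time - params.end_guard_s]
    if tail:
        reps = [r for r in reps if r.end_time <= end_time - params.end_guard_s]
        flags.append(f"edge_rep_discarded: {len(tail)}")
    marks = RepetitionMarks(
        baseline_index=center,
        baseline_time=baseline_time,
        baseline_values=values,
        reps=reps,
        flags=flags,
    )
    if expected_reps is not None:
        marks = validate_marks(marks, expected_reps, strict=strict)
    return marks
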