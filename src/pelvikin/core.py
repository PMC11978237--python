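"""Shared domain types and conventions for pelvic-kinematics analysis.

Coordinate frame (lab)
----------------------
All 3-vectors use one ordered orthonormal basis:

* axis 0 — vertical, up-positive (m)
* axis 1 — mediolateral, subject's-left-positive (m)
* axis 2 — anteroposterior, anterior-positive (m)

Smartphone acceleration channels X, Y, Z map onto these three axes in the
same order, so both sensor branches share a single frame and no per-branch
sign tables are needed.  The basis is used as an abstract ordered triad with
``e0 x e1 := e2`` inside the rotation algebra; simulator and both processing
branches use the identical matrices, so angle round-trips are exact by
construction.

Angle sign convention (right-leg stance, contralateral = left)
--------------------------------------------------------------
* transverse  +  forward contralateral pelvic rotation (left side moves anterior)
* frontal     +  contralateral pelvic drop (left side moves down)
* sagittal    +  anterior pelvic tilt (top of pelvis rotates forward)

Angles are stored in degrees end-to-end; radians appear only inside the
rotation math.  All filtering is zero-phase (forward-backward Butterworth),
because outcomes are defined at time-aligned events and phase lag would bias
peak timing.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

AXIS_VERTICAL = 0
AXIS_MEDIOLATERAL = 1
AXIS_ANTEROPOSTERIOR = 2

PLANES = ("transverse", "frontal", "sagittal")

#: device orientation channel -> pelvic plane, for the reference mounting
#: (landscape over the sacrum, screen outward, camera to the subject's left).
DEVICE_ANGLE_MAP = {"roll": "sagittal", "pitch": "frontal", "azimuth": "transverse"}
#: sign applied when mapping each device channel into the pelvic convention.
DEVICE_ANGLE_SIGN = {"roll": 1.0, "pitch": 1.0, "azimuth": 1.0}


class PelvikinError(Exception):
    """Base class for package errors."""


class IngestError(PelvikinError):
    """Malformed or inconsistent input file / series."""


class DegenerateGeometryError(PelvikinError):
    """Marker configuration does not define a pelvis frame."""


class UnstableBaselineError(PelvikinError):
    """No sufficiently quiet pre-task window found."""


class CountMismatchError(PelvikinError):
    """Detected repetition count differs from the expected count."""


class TooShortError(PelvikinError):
    """Signal shorter than the processing step can accommodate."""


class CorruptOrientationError(PelvikinError):
    """Orientation channel inconsistent even after unwrapping."""


class TaskLabel(str, enum.Enum):
    """The three single-leg weight-bearing tasks."""

    SLS = "SLS"
    SD15 = "SD15"
    SD20 = "SD20"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


TASKS = (TaskLabel.SLS, TaskLabel.SD15, TaskLabel.SD20)


@dataclass(frozen=True)
class PelvicAngles:
    """Pelvic orientation in the three planes (degrees, convention above)."""

    transverse: float
    frontal: float
    sagittal: float

    def __post_init__(self) -> None:
        for plane in PLANES:
            v = getattr(self, plane)
            if not math.isfinite(v):
                raise ValueError(f"{plane} angle is not finite: {v!r}")
            if abs(v) >= 90.0:
                raise ValueError(
                    f"{plane} angle magnitude {v:.1f} deg >= 90 deg; "
                    "not a valid pelvic recording"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.transverse, self.frontal, self.sagittal], dtype=float)

    @classmethod
    def from_array(cls, a) -> "PelvicAngles":
        t, f, s = np.asarray(a, dtype=float)
        return cls(float(t), float(f), float(s))


@dataclass
class UniformSeries:
    """Uniformly sampled, gap-free multichannel time series.

    Gaps are an ingest error, not a runtime state: every channel has the
    same length and the time axis is ``t0 + arange(n)/rate``.
    """

    t0: float
    rate: float
    channels: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if not self.channels:
            raise ValueError("series must have at least one channel")
        lengths = set()
        for name, values in self.channels.items():
            arr = np.asarray(values, dtype=float)
            self.channels[name] = arr
            if arr.ndim != 1:
                raise ValueError(f"channel {name!r} must be 1-D")
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        if lengths.pop() < 2:
            raise ValueError("channels must have at least 2 samples")

    @property
    def n(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def duration(self) -> float:
        return (self.n - 1) / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times()}
        data.update(self.channels)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth filter specification.

    ``order`` is the design order of the underlying Butterworth filter; it is
    applied forward-backward (``sosfiltfilt``), which squares the magnitude
    response and cancels phase.
    """

    kind: str  # "lowpass" | "highpass"
    order: int
    cutoff_hz: float

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ValueError(f"kind must be 'lowpass' or 'highpass', got {self.kind!r}")
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if self.cutoff_hz <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff_hz}")

    def apply(self, x: np.ndarray, rate: float) -> np.ndarray:
        """Filter ``x`` (1-D) sampled at ``rate`` Hz, zero-phase."""
        if self.cutoff_hz >= rate / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz >= Nyquist {rate / 2} Hz at rate {rate}"
            )
        sos = signal.butter(self.order, self.cutoff_hz, btype=self.kind, fs=rate, output="sos")
        return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


#: defaults used throughout: 10 Hz low-pass for orientation, 1 Hz high-pass
#: for acceleration (both 4th order), 0.1 Hz high-pass (2nd order) against
#: integration drift.
ORIENTATION_LOWPASS = FilterSpec("lowpass", 4, 10.0)
ACCELERATION_HIGHPASS = FilterSpec("highpass", 4, 1.0)
DRIFT_HIGHPASS = FilterSpec("highpass", 2, 0.1)


@dataclass(frozen=True)
class OutcomeParams:
    """Parameters of the per-repetition outcome extraction."""

    peak_window_s: float = 0.2
    reps_per_task: int = 5
    start_end_threshold_m: float = 0.010
    baseline_window_s: float = 0.5

    def __post_init__(self) -> None:
        if self.peak_window_s <= 0:
            raise ValueError("peak window width must be positive")
        if self.start_end_threshold_m <= 0:
            raise ValueError("start/end deviation threshold must be positive")
        if self.baseline_window_s <= 0:
            raise ValueError("baseline stability window must be positive")


@dataclass
class PelvicKinematics:
    """Processed pelvic kinematics from one sensor branch.

    Channels: ``transverse``/``frontal``/``sagittal`` (deg, filtered),
    ``vertical_disp`` (m), ``ml_acc`` (m/s^2, high-pass filtered) and, for the
    marker branch, ``ml_disp`` (m).  ``source`` is ``"mocap"`` or ``"phone"``.
    """

    series: UniformSeries
    source: str

    def __post_init__(self) -> None:
        if self.source not in ("mocap", "phone"):
            raise ValueError(f"source must be 'mocap' or 'phone', got {self.source!r}")
        for required in PLANES + ("vertical_disp", "ml_acc"):
            if required not in self.series.channels:
                raise ValueError(f"missing kinematics channel {required!r}")

    @property
    def rate(self) -> float:
        return self.series.rate

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]


# ---------------------------------------------------------------------------
# Rotation algebra (shared by the simulator and the marker branch).
# Euler sequence: intrinsic transverse -> frontal -> sagittal, i.e. rotations
# about the vertical, anteroposterior and mediolateral axes respectively.
# ---------------------------------------------------------------------------


def _rot_transverse(rad: np.ndarray) -> np.ndarray:
    c, s = np.cos(rad), np.sin(rad)
    out = np.zeros(np.shape(rad) + (3, 3))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = -s
    out[..., 2, 1] = s
    out[..., 2, 2] = c
    return out


def _rot_frontal(rad: np.ndarray) -> np.ndarray:
    c, s = np.cos(rad), np.sin(rad)
    out = np.zeros(np.shape(rad) + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def _rot_sagittal(rad: np.ndarray) -> np.ndarray:
    c, s = np.cos(rad), np.sin(rad)
    out = np.zeros(np.shape(rad) + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = -s
    out[..., 1, 1] = 1.0
    out[..., 2, 0] = s
    out[..., 2, 2] = c
    return out


def euler_to_matrix(transverse_deg, frontal_deg, sagittal_deg) -> np.ndarray:
    """Rotation matrix (pelvis -> lab) for angles in degrees.

    Accepts scalars or equally shaped arrays; returns shape ``(..., 3, 3)``.
    A positive transverse angle moves the left side anterior, positive frontal
    drops the left side, positive sagittal tilts the pelvis anteriorly.
    """
    t = np.deg2rad(np.asarray(transverse_deg, dtype=float))
    f = np.deg2rad(np.asarray(frontal_deg, dtype=float))
    s = np.deg2rad(np.asarray(sagittal_deg, dtype=float))
    return _rot_transverse(t) @ _rot_frontal(f) @ _rot_sagittal(s)


def matrix_to_euler(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`euler_to_matrix`; returns degrees.

    Valid for frontal magnitudes < 90 deg (always true for pelvic motion).
    """
    R = np.asarray(R, dtype=float)
    frontal = np.arcsin(np.clip(-R[..., 0, 1], -1.0, 1.0))
    sagittal = np.arctan2(-R[..., 0, 2], R[..., 0, 0])
    transverse = np.arctan2(R[..., 2, 1], R[..., 1, 1])
    return tuple(np.rad2deg(a) for a in (transverse, frontal, sagittal))
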