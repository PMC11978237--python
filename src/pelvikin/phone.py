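"""Smartphone processing branch.

Maps device orientation channels (roll / pitch / azimuth at 100 Hz) into the
shared pelvic-angle convention, estimates vertical displacement by
drift-filtered double integration of the vertical acceleration channel, and
prepares the mediolateral acceleration for the variability outcome.

The device's own fused orientation is taken as given (no sensor fusion here).
The estimated vertical displacement is used *only* for event identification;
its low-frequency shape is distorted by the repeated high-pass filtering and
must not be interpreted metrically.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import (
    ACCELERATION_HIGHPASS,
    CorruptOrientationError,
    DEVICE_ANGLE_MAP,
    DEVICE_ANGLE_SIGN,
    DRIFT_HIGHPASS,
    FilterSpec,
    ORIENTATION_LOWPASS,
    PelvicKinematics,
    TooShortError,
    UniformSeries,
)

PHONE_RATE_HZ = 100.0
PHONE_CHANNELS = ("ax", "ay", "az", "roll", "pitch", "azimuth")


@dataclass
class PhoneRecording:
    """Smartphone log: 3 acceleration (m/s^2) + 3 orientation (deg) channels.

    Device axes: X vertical, Y mediolateral, Z anteroposterior; orientation
    as roll (sagittal plane), pitch (frontal plane), azimuth (transverse
    plane) for the reference sacrum mounting.
    """

    series: UniformSeries

    def __post_init__(self) -> None:
        for name in PHONE_CHANNELS:
            if name not in self.series.channels:
                raise ValueError(f"missing phone channel {name!r}")
        if abs(self.series.rate - PHONE_RATE_HZ) > 0.01 * PHONE_RATE_HZ:
            raise ValueError(
                f"phone rate {self.series.rate} Hz deviates more than 1% "
                f"from nominal {PHONE_RATE_HZ} Hz"
            )

    @property
    def rate(self) -> float:
        return self.series.rate

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]


def to_pelvic_angles(
    recording: PhoneRecording, quiet_reference_s: float = 2.0
) -> dict[str, np.ndarray]:
    """Device orientation channels -> pelvic angle channels (deg).

    Unwraps the azimuth across the +/-180 deg seam, applies the documented
    sign map, and re-references the transverse channel to its own initial
    quiet-standing median so the arbitrary compass zero never enters the
    outcomes.  Roll/pitch mounting offsets are left in place; they cancel in
    the baseline subtraction downstream.
    """
    azimuth = np.unwrap(np.asarray(recording["azimuth"], dtype=float), period=360.0)
    steps = np.abs(np.diff(azimuth))
    if steps.size and steps.max() > 180.0:
        raise CorruptOrientationError(
            f"azimuth jump of {steps.max():.1f} deg persists after unwrapping"
        )
    n_ref = max(1, int(round(quiet_reference_s * recording.rate)))
    azimuth = azimuth - np.median(azimuth[:n_ref])

    raw = {"roll": recording["roll"], "pitch": recording["pitch"], "azimuth": azimuth}
    return {
        DEVICE_ANGLE_MAP[ch]: DEVICE_ANGLE_SIGN[ch] * np.asarray(raw[ch], dtype=float)
        for ch in ("roll", "pitch", "azimuth")
    }


def estimate_vertical_displacement(
    vertical_acceleration: np.ndarray,
    rate: float,
    drift_filter: FilterSpec = DRIFT_HIGHPASS,
    n_filter_stages: int = 3,
) -> np.ndarray:
    """Vertical displacement (m) by drift-filtered double integration.

    Pipeline: high-pass(acceleration) -> trapezoidal integral -> high-pass
    (velocity) -> trapezoidal integral -> high-pass(displacement).  With
    ``n_filter_stages=2`` the final displacement high-pass is skipped.  The
    zero DC response of the high-pass removes any constant (gravity-like)
    component, so the result is zero-mean by construction.
    """
    acc = np.asarray(vertical_acceleration, dtype=float)
    if acc.shape[0] < 4 * rate:
        raise TooShortError(
            f"need at least 4 s of signal for the drift filter, got "
            f"{acc.shape[0] / rate:.2f} s"
        )
    if n_filter_stages not in (2, 3):
        raise ValueError("n_filter_stages must be 2 or 3")
    dt = 1.0 / rate
    x = drift_filter.apply(acc, rate)
    x = cumulative_trapezoid(x, dx=dt, initial=0.0)
    x = drift_filter.apply(x, rate)
    x = cumulative_trapezoid(x, dx=dt, initial=0.0)
    if n_filter_stages == 3:
        x = drift_filter.apply(x, rate)
    return x


def prepare_ml_acceleration(
    recording: PhoneRecording, filter_spec: FilterSpec = ACCELERATION_HIGHPASS
) -> np.ndarray:
    """Mediolateral acceleration channel, zero-phase high-pass filtered.

    The 1 Hz high-pass removes gravity leakage and posture offsets from the
    device-frame channel.
    """
    return filter_spec.apply(recording["ay"], recording.rate)


def filter_orientation(
    angles: dict[str, np.ndarray],
    rate: float,
    filter_spec: FilterSpec = ORIENTATION_LOWPASS,
) -> dict[str, np.ndarray]:
    """Zero-phase low-pass on each angle channel."""
    return {name: filter_spec.apply(x, rate) for name, x in angles.items()}


class DriftStatus(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_ASSESSABLE = "not_assessable"


@dataclass(frozen=True)
class DriftQC:
    status: DriftStatus
    drift_deg: float | None

    @property
    def passed(self) -> bool:
        return self.status is DriftStatus.PASS


def qc_heading_drift(
    transverse: np.ndarray,
    rate: float,
    pre_window_s: float = 4.0,
    post_window_s: float = 4.0,
    threshold_deg: float = 5.0,
) -> DriftQC:
    """Flag heading (transverse-plane) drift from the quiet end windows.

    Compares the transverse-channel median over the initial quiet standing
    with the median over the trailing window; a difference beyond
    ``threshold_deg`` fails the recording for transverse-plane analyses,
    mirroring the visible-drift exclusion rule.
    """
    x = np.asarray(transverse, dtype=float)
    n_pre = int(round(pre_window_s * rate))
    n_post = int(round(post_window_s * rate))
    if n_pre < 1 or n_post < 1 or n_pre + n_post > x.shape[0]:
        return DriftQC(DriftStatus.NOT_ASSESSABLE, None)
    drift = float(np.median(x[-n_post:]) - np.median(x[:n_pre]))
    status = DriftStatus.FAIL if abs(drift) > threshold_deg else DriftStatus.PASS
    return DriftQC(status, drift)


def process_phone(
    recording: PhoneRecording,
    orientation_filter: FilterSpec = ORIENTATION_LOWPASS,
    acceleration_filter: FilterSpec = ACCELERATION_HIGHPASS,
    drift_filter: FilterSpec = DRIFT_HIGHPASS,
    n_filter_stages: int = 3,
) -> PelvicKinematics:
    """Full phone branch: device channels -> filtered pelvic kinematics."""
    rate = recording.rate
    angles = filter_orientation(to_pelvic_angles(recording), rate, orientation_filter)
    channels = dict(angles)
    channels["vertical_disp"] = estimate_vertical_displacement(
        recording["ax"], rate, drift_filter, n_filter_stages
    )
    channels["ml_acc"] = prepare_ml_acceleration(recording, acceleration_filter)
    units = {p: "deg" for p in angles}
    units.update({"vertical_disp": "m", "ml_acc": "m/s^2"})
    series = UniformSeries(recording.series.t0, rate, channels, units)
    return PelvicKinematics(series=series, source="phone")
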