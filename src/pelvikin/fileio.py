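"""Delimited-text readers and writers for the two sensor dialects.

Marker files: CSV with header ``time,LASIS_x,...,RPSIS_z`` (meters, 250 Hz,
axis suffixes x = vertical, y = mediolateral, z = anteroposterior).
Phone files: CSV with header ``time,ax,ay,az,roll,pitch,azimuth`` (m/s^2 and
degrees, 100 Hz).  Lines starting with ``#`` are metadata comments; writers
emit the configuration hash there.

Readers validate the header, monotone timestamps and the sampling rate; small
timestamp jitter (< 1% of the sampling interval) is absorbed by linear
interpolation onto the uniform grid, anything larger is an ingest error.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import IngestError, UniformSeries
from .mocap import AXIS_SUFFIXES, MARKER_LABELS, MOCAP_RATE_HZ, MarkerTrajectorySet
from .phone import PHONE_CHANNELS, PHONE_RATE_HZ, PhoneRecording

MARKER_COLUMNS = tuple(
    f"{label}_{suffix}" for label in MARKER_LABELS for suffix in AXIS_SUFFIXES
)


def _read_uniform_csv(
    path: str | Path, expected_columns: tuple[str, ...], nominal_rate: float
) -> UniformSeries:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if "time" not in df.columns:
        raise IngestError(f"{path.name}: missing 'time' column")
    missing = [c for c in expected_columns if c not in df.columns]
    if missing:
        raise IngestError(f"{path.name}: missing column(s) {missing}")
    t = df["time"].to_numpy(dtype=float)
    if t.shape[0] < 2:
        raise IngestError(f"{path.name}: fewer than 2 samples")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise IngestError(
            f"{path.name}: non-monotone time at row {int(bad[0]) + 2}"
        )
    dt_est = float(t[-1] - t[0]) / (t.shape[0] - 1)
    rate = 1.0 / dt_est
    if abs(rate - nominal_rate) > 0.01 * nominal_rate:
        raise IngestError(
            f"{path.name}: sampling rate {rate:.2f} Hz deviates more than 1% "
            f"from nominal {nominal_rate} Hz"
        )
    jitter = float(np.max(np.abs(dt - dt_est)))
    grid = t[0] + np.arange(t.shape[0]) * dt_est
    channels = {}
    if jitter > 0.01 * dt_est:
        raise IngestError(
            f"{path.name}: timestamp jitter {jitter * 1e3:.3f} ms exceeds 1% of "
            f"the {dt_est * 1e3:.1f} ms sampling interval"
        )
    for c in expected_columns:
        x = df[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise IngestError(f"{path.name}: non-finite value in column {c!r}")
        channels[c] = np.interp(grid, t, x) if jitter > 0 else x
    return UniformSeries(float(t[0]), nominal_rate, channels)


def read_marker_csv(path: str | Path) -> MarkerTrajectorySet:
    """Read a 250 Hz marker trajectory CSV."""
    series = _read_uniform_csv(path, MARKER_COLUMNS, MOCAP_RATE_HZ)
    series.units = {c: "m" for c in MARKER_COLUMNS}
    return MarkerTrajectorySet(series)


def read_phone_csv(path: str | Path) -> PhoneRecording:
    """Read a 100 Hz smartphone log CSV."""
    series = _read_uniform_csv(path, PHONE_CHANNELS, PHONE_RATE_HZ)
    series.units = {
        "ax": "m/s^2", "ay": "m/s^2", "az": "m/s^2",
        "roll": "deg", "pitch": "deg", "azimuth": "deg",
    }
    return PhoneRecording(series)


def _write_series_csv(
    path: str | Path,
    series: UniformSeries,
    columns: tuple[str, ...],
    header_comment: str | None = None,
) -> None:
    df = series.to_frame()[["time", *columns]]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def write_marker_csv(
    path: str | Path, markers: MarkerTrajectorySet, comment: str | None = None
) -> None:
    _write_series_csv(path, markers.series, MARKER_COLUMNS, comment)


def write_phone_csv(
    path: str | Path, recording: PhoneRecording, comment: str | None = None
) -> None:
    _write_series_csv(path, recording.series, PHONE_CHANNELS, comment)


def write_table(path: str | Path, df: pd.DataFrame, config_hash: str) -> None:
    """Write a results table with the run's configuration hash on top."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
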