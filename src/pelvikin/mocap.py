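"""Marker-based (motion capture) processing branch.

Turns the four pelvis marker trajectories (bilateral ASIS/PSIS, 250 Hz) into
pelvic orientation, centroid displacement and mediolateral acceleration in the
shared convention of :mod:`pelvikin.core`.

The pelvis frame is built per sample from the markers: the mediolateral axis
from the ASIS pair, the anteroposterior axis from mid-PSIS toward mid-ASIS
(orthogonalised against the mediolateral axis), and the vertical axis
completing the triad.  Orientation is the Euler decomposition (intrinsic
transverse -> frontal -> sagittal) of the rotation from a reference frame —
by default the quiet-standing first sample, so a participant standing
slightly rotated reads zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ACCELERATION_HIGHPASS,
    AXIS_MEDIOLATERAL,
    AXIS_VERTICAL,
    DegenerateGeometryError,
    FilterSpec,
    ORIENTATION_LOWPASS,
    PelvicKinematics,
    UniformSeries,
    matrix_to_euler,
)

MARKER_LABELS = ("LASIS", "RASIS", "LPSIS", "RPSIS")
MOCAP_RATE_HZ = 250.0

# axis suffix order of the marker CSV columns: _x vertical, _y mediolateral,
# _z anteroposterior (mirrors the phone channel semantics).
AXIS_SUFFIXES = ("x", "y", "z")


@dataclass
class MarkerTrajectorySet:
    """Positions of the 4 pelvis markers in lab coordinates (m) at 250 Hz."""

    series: UniformSeries

    def __post_init__(self) -> None:
        for label in MARKER_LABELS:
            for suffix in AXIS_SUFFIXES:
                name = f"{label}_{suffix}"
                if name not in self.series.channels:
                    raise ValueError(f"missing marker channel {name!r}")
                if not np.all(np.isfinite(self.series[name])):
                    raise ValueError(f"non-finite positions in channel {name!r}")

    @property
    def rate(self) -> float:
        return self.series.rate

    @property
    def n(self) -> int:
        return self.series.n

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def positions(self, label: str) -> np.ndarray:
        """(n, 3) lab-frame positions of one marker."""
        if label not in MARKER_LABELS:
            raise KeyError(f"unknown marker label {label!r}")
        return np.stack(
            [self.series[f"{label}_{s}"] for s in AXIS_SUFFIXES], axis=1
        )

    def stacked(self) -> np.ndarray:
        """(n, 4, 3) positions in MARKER_LABELS order."""
        return np.stack([self.positions(lb) for lb in MARKER_LABELS], axis=1)


def _pelvis_frames(markers: MarkerTrajectorySet) -> np.ndarray:
    """Per-sample rotation matrices (pelvis basis vectors as lab columns)."""
    lasis = markers.positions("LASIS")
    rasis = markers.positions("RASIS")
    lpsis = markers.positions("LPSIS")
    rpsis = markers.positions("RPSIS")

    m_axis = lasis - rasis
    m_norm = np.linalg.norm(m_axis, axis=1, keepdims=True)
    if np.any(m_norm < 1e-9):
        raise DegenerateGeometryError("ASIS markers coincide; no mediolateral axis")
    m_axis = m_axis / m_norm

    a_raw = 0.5 * (lasis + rasis) - 0.5 * (lpsis + rpsis)
    a_axis = a_raw - np.sum(a_raw * m_axis, axis=1, keepdims=True) * m_axis
    a_norm = np.linalg.norm(a_axis, axis=1, keepdims=True)
    if np.any(a_norm < 1e-9):
        raise DegenerateGeometryError(
            "markers are collinear; no anteroposterior axis"
        )
    a_axis = a_axis / a_norm

    v_axis = np.cross(m_axis, a_axis)
    return np.stack([v_axis, m_axis, a_axis], axis=2)


def orientation_from_markers(
    markers: MarkerTrajectorySet,
    reference: np.ndarray | int | None = None,
) -> dict[str, np.ndarray]:
    """Pelvic angle channels (deg) from marker trajectories.

    Parameters
    ----------
    markers
        The 4-marker trajectory set.
    reference
        Reference frame to decompose against: ``None`` (first sample), a
        sample index, or a precomputed 3x3 rotation matrix.

    Returns
    -------
    dict with ``transverse``, ``frontal``, ``sagittal`` arrays in degrees,
    drop/tilt/rotation-positive.
    """
    frames = _pelvis_frames(markers)
    if reference is None:
        R0 = frames[0]
    elif isinstance(reference, (int, np.integer)):
        R0 = frames[int(reference)]
    else:
        R0 = np.asarray(reference, dtype=float)
        if R0.shape != (3, 3):
            raise ValueError("reference matrix must be 3x3")
    relative = np.einsum("ji,njk->nik", R0, frames)
    transverse, frontal, sagittal = matrix_to_euler(relative)
    return {"transverse": transverse, "frontal": frontal, "sagittal": sagittal}


def centroid_displacement(markers: MarkerTrajectorySet) -> dict[str, np.ndarray]:
    """Vertical and mediolateral projection of the 4-marker centroid (m)."""
    centroid = markers.stacked().mean(axis=1)
    return {
        "vertical_disp": centroid[:, AXIS_VERTICAL],
        "ml_disp": centroid[:, AXIS_MEDIOLATERAL],
    }


def double_differentiate(displacement: np.ndarray, rate: float) -> np.ndarray:
    """Acceleration (m/s^2) by two central-difference passes.

    One-sided second-order differences at the edges; exact for quadratics and
    length-preserving.
    """
    displacement = np.asarray(displacement, dtype=float)
    if displacement.shape[0] < 5:
        raise ValueError("need at least 5 samples to double-differentiate")
    dt = 1.0 / rate
    return np.gradient(np.gradient(displacement, dt), dt)


def process_mocap(
    markers: MarkerTrajectorySet,
    orientation_filter: FilterSpec = ORIENTATION_LOWPASS,
    acceleration_filter: FilterSpec = ACCELERATION_HIGHPASS,
    reference: np.ndarray | int | None = None,
) -> PelvicKinematics:
    """Full marker branch: markers -> filtered pelvic kinematics."""
    rate = markers.rate
    angles = orientation_from_markers(markers, reference=reference)
    disp = centroid_displacement(markers)
    channels = {
        plane: orientation_filter.apply(angles[plane], rate) for plane in angles
    }
    # displacement is low-passed before numerical differentiation: broadband
    # marker noise would otherwise dominate the second derivative
    channels["vertical_disp"] = orientation_filter.apply(disp["vertical_disp"], rate)
    channels["ml_disp"] = orientation_filter.apply(disp["ml_disp"], rate)
    ml_acc = double_differentiate(channels["ml_disp"], rate)
    channels["ml_acc"] = acceleration_filter.apply(ml_acc, rate)

    units = {p: "deg" for p in angles}
    units.update({"vertical_disp": "m", "ml_disp": "m", "ml_acc": "m/s^2"})
    series = UniformSeries(markers.series.t0, rate, channels, units)
    return PelvicKinematics(series=series, source="mocap")
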