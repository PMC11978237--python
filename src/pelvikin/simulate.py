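"""Synthetic paired-sensor generator.

Produces ground-truth pelvis pose trajectories for the three single-leg
tasks (SLS, SD15, SD20) and renders each one twice from the same latent
truth: as a 250 Hz four-marker trajectory set and as a 100 Hz smartphone log
with gravity, mounting offset, heading drift and sensor noise.  Every
downstream stage is therefore testable without any recorded data, and the
two renderings share one Euler convention so ground-truth recovery is exact
in the noise-free limit.

Study schedule (defaults): 5 s quiet standing, then 5 repetitions of a 4 s
raised-cosine descent/ascent separated by 2 s rests, then trailing quiet
standing.  Orientation excursions and mediolateral sway magnitudes default to
scales typical of healthy adults performing these tasks, with a shared
per-participant random effect across tasks so that between-task contrasts are
paired, as in a within-subject study.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _signal

from .core import (
    AXIS_ANTEROPOSTERIOR,
    AXIS_MEDIOLATERAL,
    AXIS_VERTICAL,
    PelvicAngles,
    PLANES,
    TASKS,
    TaskLabel,
    UniformSeries,
    euler_to_matrix,
)
from .mocap import AXIS_SUFFIXES, MARKER_LABELS, MOCAP_RATE_HZ, MarkerTrajectorySet
from .phone import PHONE_RATE_HZ, PhoneRecording


@dataclass(frozen=True)
class MarkerGeometry:
    """Local pelvis-frame marker coordinates (m), axes (vertical, ML, AP)."""

    local: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if set(self.local) != set(MARKER_LABELS):
            raise ValueError(f"geometry must define exactly {MARKER_LABELS}")
        for left, right in (("LASIS", "RASIS"), ("LPSIS", "RPSIS")):
            lv, rv = np.asarray(self.local[left]), np.asarray(self.local[right])
            mirrored = rv * np.array([1.0, -1.0, 1.0])
            if not np.allclose(lv, mirrored, atol=1e-12):
                raise ValueError(
                    f"{left}/{right} must mirror about the midsagittal plane"
                )

    @classmethod
    def default(cls) -> "MarkerGeometry":
        """ASIS pair +/-120 mm ML, +90 mm anterior; PSIS pair +/-60 mm ML,
        -90 mm anterior; all at 0 vertical."""
        return cls(
            {
                "LASIS": (0.0, 0.120, 0.090),
                "RASIS": (0.0, -0.120, 0.090),
                "LPSIS": (0.0, 0.060, -0.090),
                "RPSIS": (0.0, -0.060, -0.090),
            }
        )

    def array(self) -> np.ndarray:
        """(4, 3) local coordinates in MARKER_LABELS order."""
        return np.array([self.local[lb] for lb in MARKER_LABELS], dtype=float)


def _default_angle_centers() -> dict:
    # per-task, per-plane peak-angle centers (deg) on the scale observed in
    # healthy adults: SLS rotates posteriorly with little drop; step-downs
    # show contralateral drop growing with step height.
    return {
        TaskLabel.SLS: {"transverse": -6.4, "frontal": -0.9, "sagittal": 0.9},
        TaskLabel.SD15: {"transverse": -1.2, "frontal": 3.4, "sagittal": -3.2},
        TaskLabel.SD20: {"transverse": -0.2, "frontal": 4.5, "sagittal": -1.3},
    }


def _default_depths() -> dict:
    return {TaskLabel.SLS: 0.15, TaskLabel.SD15: 0.18, TaskLabel.SD20: 0.20}


def _default_sway() -> dict:
    return {TaskLabel.SLS: 0.22, TaskLabel.SD15: 0.26, TaskLabel.SD20: 0.29}


@dataclass
class SimulationConfig:
    """Conditions of a simulated cohort recording session.

    Angle amplitudes are per-participant random effects drawn once per
    participant x task (not per repetition): for plane ``p`` and task ``t``,
    amplitude = center[t][p] + u[p] + e[t][p] with u a participant effect
    shared across tasks (``angle_between_sd_deg``) and e a task residual
    (``angle_within_sd_deg``).  Mediolateral sway amplitude is lognormal
    around the per-task center with the analogous two variance components.
    """

    n_participants: int = 52
    tasks: tuple[TaskLabel, ...] = TASKS
    reps_per_task: int = 5
    rep_duration_s: float = 4.0
    rest_s: float = 2.0
    quiet_pre_s: float = 5.0
    quiet_post_s: float = 5.0
    plateau_s: float = 0.0
    master_rate_hz: float = 500.0

    depth_mean_m: dict = field(default_factory=_default_depths)
    depth_sd_m: float = 0.03
    angle_center_deg: dict = field(default_factory=_default_angle_centers)
    angle_between_sd_deg: float = 3.5
    angle_within_sd_deg: float = 1.0
    sway_center_ms2: dict = field(default_factory=_default_sway)
    sway_between_log_sd: float = 0.25
    sway_within_log_sd: float = 0.08
    sway_band_hz: tuple[float, float] = (0.8, 3.0)

    marker_noise_sd_m: float = 0.0005
    phone_accel_noise_sd: float = 0.05
    phone_orient_noise_sd_deg: float = 0.3
    mounting_offset_deg: tuple[float, float, float] = (45.0, 2.0, 3.0)
    heading_drift_rate_deg_s: float = 0.02
    gravity_ms2: float = 9.81
    include_gravity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rep_duration_s", "rest_s", "quiet_pre_s", "quiet_post_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.plateau_s < 0 or self.plateau_s >= self.rep_duration_s:
            raise ValueError("plateau must be >= 0 and shorter than the repetition")
        for name in (
            "depth_sd_m",
            "angle_between_sd_deg",
            "angle_within_sd_deg",
            "marker_noise_sd_m",
            "phone_accel_noise_sd",
            "phone_orient_noise_sd_deg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.tasks = tuple(TaskLabel(t) for t in self.tasks)
        self.depth_mean_m = {TaskLabel(k): float(v) for k, v in self.depth_mean_m.items()}
        self.angle_center_deg = {
            TaskLabel(k): dict(v) for k, v in self.angle_center_deg.items()
        }
        self.sway_center_ms2 = {
            TaskLabel(k): float(v) for k, v in self.sway_center_ms2.items()
        }
        for task in self.tasks:
            if self.depth_mean_m[task] < 0:
                raise ValueError(
                    f"depth mean for {task} is negative: squatting cannot raise "
                    "the pelvis"
                )
        for rate in (MOCAP_RATE_HZ, PHONE_RATE_HZ):
            step = self.master_rate_hz / rate
            if abs(step - round(step)) > 1e-9 or step < 1:
                raise ValueError(
                    f"master rate {self.master_rate_hz} Hz must be an integer "
                    f"multiple of the sensor rate {rate} Hz"
                )
        if self.master_rate_hz < 500.0:
            raise ValueError("master rate must be >= 500 Hz")

    def rep_windows(self) -> list[tuple[float, float]]:
        """True (start, end) times of every repetition."""
        out = []
        t = self.quiet_pre_s
        for _ in range(self.reps_per_task):
            out.append((t, t + self.rep_duration_s))
            t += self.rep_duration_s + self.rest_s
        return out

    @property
    def total_duration_s(self) -> float:
        return self.rep_windows()[-1][1] + self.quiet_post_s


@dataclass
class PoseTrajectory:
    """Latent ground-truth pelvis pose plus true event times and amplitudes."""

    series: UniformSeries
    rep_times: list[tuple[float, float, float]]  # (start, peak, end)
    peak_angles: list[PelvicAngles]
    depth_m: float
    task: TaskLabel

    @property
    def rate(self) -> float:
        return self.series.rate

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]


def _rep_profile(t_local: np.ndarray, duration: float, plateau: float) -> np.ndarray:
    """Normalised 0 -> 1 -> 0 raised-cosine squat profile, optional plateau."""
    p = np.zeros_like(t_local)
    inside = (t_local >= 0) & (t_local <= duration)
    tl = t_local[inside]
    if plateau <= 0:
        prof = 0.5 * (1.0 - np.cos(2.0 * np.pi * tl / duration))
    else:
        ramp = 0.5 * (duration - plateau)
        prof = np.ones_like(tl)
        desc = tl < ramp
        prof[desc] = 0.5 * (1.0 - np.cos(np.pi * tl[desc] / ramp))
        asc = tl > duration - ramp
        prof[asc] = 0.5 * (1.0 - np.cos(np.pi * (duration - tl[asc]) / ramp))
    p[inside] = prof
    return p


def _activity_profile(config: SimulationConfig, times: np.ndarray) -> np.ndarray:
    prof = np.zeros_like(times)
    for start, end in config.rep_windows():
        prof += _rep_profile(times - start, config.rep_duration_s, config.plateau_s)
    return prof


def _make_sway(
    config: SimulationConfig,
    times: np.ndarray,
    activity: np.ndarray,
    accel_sd_target: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited mediolateral sway displacement whose acceleration has the
    requested standard deviation inside the repetitions."""
    if accel_sd_target <= 0:
        return np.zeros_like(times)
    rate = config.master_rate_hz
    lo, hi = config.sway_band_hz
    sos = _signal.butter(2, (lo, hi), btype="bandpass", fs=rate, output="sos")
    noise = rng.standard_normal(times.shape[0])
    smooth = _signal.sosfiltfilt(sos, noise)
    disp = activity * smooth
    dt = 1.0 / rate
    acc = np.gradient(np.gradient(disp, dt), dt)
    active = activity > 0.5
    scale = np.std(acc[active]) if np.any(active) else 0.0
    if scale < 1e-12:
        return np.zeros_like(times)
    return disp * (accel_sd_target / scale)


def generate_pose(
    config: SimulationConfig,
    task: TaskLabel,
    amplitudes: PelvicAngles | None = None,
    depth_m: float | None = None,
    sway_accel_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> PoseTrajectory:
    """Ground-truth pose for one participant x task.

    Each repetition is a smooth raised-cosine descent/ascent in vertical
    displacement; every angle channel is a per-plane amplitude times the same
    normalised profile, drawn once per participant x task unless passed
    explicitly.  Sampled at the internal master rate so both sensor rates can
    be decimated exactly.
    """
    task = TaskLabel(task)
    if task not in config.tasks:
        raise ValueError(f"task {task} not in config.tasks {config.tasks}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    if amplitudes is None:
        centers = config.angle_center_deg[task]
        sd = float(
            np.hypot(config.angle_between_sd_deg, config.angle_within_sd_deg)
        )
        amplitudes = PelvicAngles(
            *(centers[p] + sd * rng.standard_normal() for p in PLANES)
        )
    if depth_m is None:
        depth_m = float(
            np.clip(
                config.depth_mean_m[task] + config.depth_sd_m * rng.standard_normal(),
                0.0,
                None,
            )
        )
    if depth_m < 0:
        raise ValueError("squat depth must be non-negative (pelvis moves down)")
    if sway_accel_sd is None:
        sway_accel_sd = config.sway_center_ms2[task] * float(
            np.exp(
                np.hypot(config.sway_between_log_sd, config.sway_within_log_sd)
                * rng.standard_normal()
            )
        )

    rate = config.master_rate_hz
    n = int(round(config.total_duration_s * rate)) + 1
    times = np.arange(n) / rate
    activity = _activity_profile(config, times)

    channels = {
        plane: getattr(amplitudes, plane) * activity for plane in PLANES
    }
    channels["vertical_disp"] = -depth_m * activity
    channels["ml_disp"] = _make_sway(config, times, activity, sway_accel_sd, rng)

    units = {p: "deg" for p in PLANES}
    units.update({"vertical_disp": "m", "ml_disp": "m"})
    series = UniformSeries(0.0, rate, channels, units)

    rep_times = [
        (start, 0.5 * (start + end), end) for start, end in config.rep_windows()
    ]
    peak_angles = [amplitudes] * config.reps_per_task
    return PoseTrajectory(series, rep_times, peak_angles, depth_m, task)


def render_mocap(
    pose: PoseTrajectory,
    geometry: MarkerGeometry | None = None,
    marker_noise_sd_m: float = 0.0,
    rng: np.random.Generator | None = None,
) -> MarkerTrajectorySet:
    """Render the pose as a rigid 4-marker trajectory set at 250 Hz.

    Markers are the local geometry rotated by the intrinsic
    transverse->frontal->sagittal Euler sequence, translated by the pose
    displacements, decimated exactly to 250 Hz, with isotropic Gaussian noise
    added afterwards.  Zero noise reproduces a perfect rigid body.
    """
    if geometry is None:
        geometry = MarkerGeometry.default()
    local = geometry.array()  # (4, 3)
    R = euler_to_matrix(pose["transverse"], pose["frontal"], pose["sagittal"])
    positions = np.einsum("nij,mj->nmi", R, local)  # (n, 4, 3)
    positions[..., AXIS_VERTICAL] += pose["vertical_disp"][:, None]
    positions[..., AXIS_MEDIOLATERAL] += pose["ml_disp"][:, None]

    step = int(round(pose.rate / MOCAP_RATE_HZ))
    positions = positions[::step]
    if marker_noise_sd_m > 0:
        if rng is None:
            raise ValueError("rng required when marker noise sd > 0")
        positions = positions + marker_noise_sd_m * rng.standard_normal(positions.shape)

    channels = {}
    for m, label in enumerate(MARKER_LABELS):
        for a, suffix in enumerate(AXIS_SUFFIXES):
            channels[f"{label}_{suffix}"] = positions[:, m, a]
    units = {name: "m" for name in channels}
    return MarkerTrajectorySet(UniformSeries(0.0, MOCAP_RATE_HZ, channels, units))


def _wrap_degrees(x: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180] as an orientation sensor would report."""
    return -(np.mod(-x + 180.0, 360.0) - 180.0)


def render_phone(
    pose: PoseTrajectory,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PhoneRecording:
    """Render the pose as a smartphone log at 100 Hz.

    Orientation channels are the pose angles plus the constant mounting
    offset, plus heading drift on the azimuth only (a magnetometer-fusion
    artifact, so it does not touch the accelerometer), plus Gaussian noise;
    the azimuth is wrapped to (-180, 180] as a device reports it.
    Acceleration channels are the second derivative of the pose displacement
    rotated into the (offset) device frame, plus gravity expressed in the
    device frame when ``include_gravity`` is set, plus noise.
    """
    off_t, off_f, off_s = config.mounting_offset_deg
    times = pose.series.times()

    transverse = pose["transverse"] + off_t + config.heading_drift_rate_deg_s * times
    frontal = pose["frontal"] + off_f
    sagittal = pose["sagittal"] + off_s

    dt = 1.0 / pose.rate
    a_lab = np.zeros((times.shape[0], 3))
    a_lab[:, AXIS_VERTICAL] = np.gradient(
        np.gradient(pose["vertical_disp"], dt), dt
    )
    a_lab[:, AXIS_MEDIOLATERAL] = np.gradient(np.gradient(pose["ml_disp"], dt), dt)
    if config.include_gravity:
        # accelerometers measure specific force: +g on the vertical axis at rest
        a_lab[:, AXIS_VERTICAL] += config.gravity_ms2

    # device physical attitude excludes the heading drift
    R = euler_to_matrix(pose["transverse"] + off_t, frontal, sagittal)
    f_dev = np.einsum("nji,nj->ni", R, a_lab)

    step = int(round(pose.rate / PHONE_RATE_HZ))
    sl = slice(None, None, step)
    n_out = f_dev[sl].shape[0]

    def _noise(sd: float) -> np.ndarray:
        if sd <= 0:
            return np.zeros(n_out)
        if rng is None:
            raise ValueError("rng required when phone noise sd > 0")
        return sd * rng.standard_normal(n_out)

    osd = config.phone_orient_noise_sd_deg
    channels = {
        "ax": f_dev[sl, AXIS_VERTICAL] + _noise(config.phone_accel_noise_sd),
        "ay": f_dev[sl, AXIS_MEDIOLATERAL] + _noise(config.phone_accel_noise_sd),
        "az": f_dev[sl, AXIS_ANTEROPOSTERIOR] + _noise(config.phone_accel_noise_sd),
        "roll": sagittal[sl] + _noise(osd),
        "pitch": frontal[sl] + _noise(osd),
        "azimuth": _wrap_degrees(transverse[sl] + _noise(osd)),
    }
    units = {"ax": "m/s^2", "ay": "m/s^2", "az": "m/s^2",
             "roll": "deg", "pitch": "deg", "azimuth": "deg"}
    return PhoneRecording(UniformSeries(0.0, PHONE_RATE_HZ, channels, units))


@dataclass
class CohortRecording:
    """One participant x task with both sensor renderings and the truth."""

    participant: int
    gender: str
    task: TaskLabel
    pose: PoseTrajectory
    markers: MarkerTrajectorySet
    phone: PhoneRecording


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    noise_scale: float = 1.0,
) -> list[CohortRecording]:
    """Simulate the full cohort; deterministic under a fixed seed.

    ``noise_scale`` multiplies every sensor noise sd (marker, accelerometer,
    orientation) while leaving the latent amplitudes untouched; because the
    amplitude and noise substreams are split per recording, scaling the noise
    reuses the same underlying draws, which makes noise-sweep comparisons
    paired.  With ``out_dir`` set, marker/phone CSVs and a ground-truth JSON
    sidecar are written per recording.
    """
    root = np.random.SeedSequence(config.seed)
    participant_seeds = root.spawn(config.n_participants)
    genders = ["F" if i % 2 == 0 else "M" for i in range(config.n_participants)]

    out: list[CohortRecording] = []
    for i, pseed in enumerate(participant_seeds):
        amp_seq, noise_seq = pseed.spawn(2)
        amp_rng = np.random.default_rng(amp_seq)
        u_angle = {p: config.angle_between_sd_deg * amp_rng.standard_normal() for p in PLANES}
        u_sway = config.sway_between_log_sd * amp_rng.standard_normal()
        task_noise_seqs = noise_seq.spawn(len(config.tasks))
        for task, nseq in zip(config.tasks, task_noise_seqs):
            centers = config.angle_center_deg[task]
            amplitudes = PelvicAngles(
                *(
                    centers[p]
                    + u_angle[p]
                    + config.angle_within_sd_deg * amp_rng.standard_normal()
                    for p in PLANES
                )
            )
            depth = float(
                np.clip(
                    config.depth_mean_m[task]
                    + config.depth_sd_m * amp_rng.standard_normal(),
                    0.0,
                    None,
                )
            )
            sway = config.sway_center_ms2[task] * float(
                np.exp(
                    u_sway + config.sway_within_log_sd * amp_rng.standard_normal()
                )
            )
            pose = generate_pose(
                config, task, amplitudes=amplitudes, depth_m=depth,
                sway_accel_sd=sway, rng=amp_rng,
            )
            noise_rng = np.random.default_rng(nseq)
            markers = render_mocap(
                pose,
                marker_noise_sd_m=noise_scale * config.marker_noise_sd_m,
                rng=noise_rng,
            )
            noisy_cfg = config
            if noise_scale != 1.0:
                noisy_cfg = dataclasses.replace(
                    config,
                    phone_accel_noise_sd=noise_scale * config.phone_accel_noise_sd,
                    phone_orient_noise_sd_deg=(
                        noise_scale * config.phone_orient_noise_sd_deg
                    ),
                )
            recording = render_phone(pose, noisy_cfg, rng=noise_rng)
            out.append(CohortRecording(i, genders[i], task, pose, markers, recording))

    if out_dir is not None:
        from .fileio import write_marker_csv, write_phone_csv

        root_dir = Path(out_dir)
        root_dir.mkdir(parents=True, exist_ok=True)
        for rec in out:
            stem = f"p{rec.participant:03d}_{rec.task.value}"
            write_marker_csv(root_dir / f"{stem}_markers.csv", rec.markers)
            write_phone_csv(root_dir / f"{stem}_phone.csv", rec.phone)
            truth = {
                "participant": rec.participant,
                "gender": rec.gender,
                "task": rec.task.value,
                "depth_m": rec.pose.depth_m,
                "rep_times": rec.pose.rep_times,
                "peak_angles": [
                    {p: getattr(a, p) for p in PLANES} for a in rec.pose.peak_angles
                ],
            }
            (root_dir / f"{stem}_truth.json").write_text(
                json.dumps(truth, indent=1, sort_keys=True)
            )
    return out
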