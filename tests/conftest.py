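import dataclasses

import numpy as np
import pytest

import pelvikin as pk


@pytest.fixture
def clean_config():
    """Noise-free, offset-free, drift-free simulation with gravity-free
    acceleration channels: both branches should recover the latent pose."""
    return pk.SimulationConfig(
        n_participants=2,
        marker_noise_sd_m=0.0,
        phone_accel_noise_sd=0.0,
        phone_orient_noise_sd_deg=0.0,
        heading_drift_rate_deg_s=0.0,
        mounting_offset_deg=(0.0, 0.0, 0.0),
        include_gravity=False,
        seed=7,
    )


@pytest.fixture
def clean_gravity_config(clean_config):
    return dataclasses.replace(clean_config, include_gravity=True)


@pytest.fixture
def clean_pose(clean_config):
    return pk.generate_pose(
        clean_config,
        pk.TaskLabel.SLS,
        amplitudes=pk.PelvicAngles(-6.0, 3.0, 5.0),
        depth_m=0.15,
        sway_accel_sd=0.0,
    )


def make_kinematics(
    rate=100.0,
    duration=40.0,
    angles=None,
    vertical=None,
    ml_acc=None,
    source="phone",
):
    """Hand-built PelvicKinematics for segmentation/outcome tests."""
    n = int(round(duration * rate)) + 1
    zeros = np.zeros(n)
    channels = {
        "transverse": zeros.copy() if angles is None else np.asarray(angles["transverse"]),
        "frontal": zeros.copy() if angles is None else np.asarray(angles["frontal"]),
        "sagittal": zeros.copy() if angles is None else np.asarray(angles["sagittal"]),
        "vertical_disp": zeros.copy() if vertical is None else np.asarray(vertical),
        "ml_acc": zeros.copy() if ml_acc is None else np.asarray(ml_acc),
    }
    series = pk.UniformSeries(0.0, rate, channels)
    return pk.PelvicKinematics(series=series, source=source)


@pytest.fixture
def triangle_displacement():
    """Symmetric triangular dip: 0 at 1 s, -0.10 m at 2 s, 0 at 3 s (250 Hz)."""
    rate = 250.0
    t = np.arange(0, int(10 * rate) + 1) / rate
    d = np.zeros_like(t)
    rising = (t >= 1.0) & (t < 2.0)
    falling = (t >= 2.0) & (t <= 3.0)
    d[rising] = -0.10 * (t[rising] - 1.0)
    d[falling] = -0.10 * (3.0 - t[falling])
    return t, d, rate
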