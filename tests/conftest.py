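"""Shared fixtures: small synthetic recordings and the (expensive)
session-scoped benchmark cohorts."""

import pytest

import iosproc as ip


@pytest.fixture
def small_acq():
    """Desk-scale acquisition: 16x16 frames, otherwise study timing."""
    return ip.AcquisitionConfig(frame_shape=(16, 16), n_trials=2,
                                pixel_pitch_um=325.0)


@pytest.fixture
def quiet_dist():
    """All disturbance sources off."""
    return ip.DisturbanceConfig(breathing_amp=0.0, heartbeat_amp=0.0,
                                electrical_noise_sd=0.0, drift_rate=0.0,
                                trial_gain_jitter_sd=0.0)


@pytest.fixture
def small_resp():
    return ip.ResponseConfig(spatial_sigma=3.0)


@pytest.fixture
def noise_free_recording(small_acq, quiet_dist, small_resp):
    raw, gt = ip.generate_raw_stack(small_acq, quiet_dist, small_resp, seed=0)
    return raw, gt


def benchmark_configs():
    """The scaled-down study conditions: 32x32 frames covering the same
    field of view as the full-resolution acquisition (162.5 um/px), so the
    response blob, smoothing sigma and ROI keep their physical sizes."""
    acq = ip.AcquisitionConfig(frame_shape=(32, 32), pixel_pitch_um=162.5)
    dist = ip.DisturbanceConfig()
    resp = ip.ResponseConfig(spatial_sigma=4.0)  # 0.65 mm
    return acq, dist, resp


@pytest.fixture(scope="session")
def benchmark_report():
    """All seven techniques at 50 trials/half, 19 replicates (the Fig 5/8
    comparison point)."""
    acq, dist, resp = benchmark_configs()
    return ip.run_benchmark(acq, dist, resp, trial_counts=(50,),
                            n_replicates=19, seed=0, roi_size=6)


@pytest.fixture(scope="session")
def averaging_grid_report():
    """Trial averaging across N = 1, 10, 25, 50 on the same cohort."""
    acq, dist, resp = benchmark_configs()
    return ip.run_benchmark(acq, dist, resp, techniques=["averaging"],
                            trial_counts=(1, 10, 25, 50), n_replicates=19,
                            seed=0, roi_size=6)
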