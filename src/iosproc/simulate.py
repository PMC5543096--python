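"""Synthetic multi-wavelength IOS recordings with known ground truth.

The forward model mirrors the physics the unmixing stage inverts.  For each
wavelength ``lam`` with baseline illumination ``I0(lam)``::

    I(x, y, t) = I0(lam) * 10**(-dA(x, y, t, lam)) * (1 + d(t)) + eta

    dA = epsO(lam) * lO(lam) * dC_O(x, y, t) + epsR(lam) * lR(lam) * dC_R(x, y, t)

where the extinction/pathlength products come from the same
:class:`~iosproc.beer_lambert.ChromophoreTable` the unmixer uses (so the
noise-free round trip is exact), ``d(t)`` is the global multiplicative
disturbance (breathing and heartbeat sinusoids with harmonics and slow
phase wander, plus a random-walk drift) and ``eta`` is per-pixel additive
white Gaussian electrical noise in camera counts.

The concentration fields factor into an isotropic Gaussian blob and a
causal gamma-variate temporal kernel repeated each trial with per-trial
gain jitter.  The fields are held constant within each wavelength cycle
(the same simultaneity assumption least-squares unmixing makes), while
disturbances and noise vary frame by frame at the full camera rate.

All randomness derives from a single seed through independent
``SeedSequence`` spawns per component, so each component is reproducible
on its own and the whole stack is bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .config import AcquisitionConfig, DisturbanceConfig, ResponseConfig
from .stacks import RawStack

__all__ = [
    "GroundTruth",
    "generate_raw_stack",
    "generate_blank_stack",
    "generate_no_stimulus_stack",
    "gamma_kernel",
    "gaussian_blob",
    "disturbance_trace",
]


def gamma_kernel(t_in_trial: np.ndarray, onset_s: float, time_to_peak_s: float,
                 decay_tau_s: float) -> np.ndarray:
    """Causal gamma-variate response kernel, zero before ``onset_s`` and
    normalised to peak amplitude 1 at ``onset_s + time_to_peak_s``.

    The asymptotic decay time constant is ``decay_tau_s``.
    """
    t = np.asarray(t_in_trial, dtype=float)
    u = t - onset_s
    alpha = time_to_peak_s / decay_tau_s
    out = np.zeros_like(u)
    pos = u > 0
    x = u[pos] / time_to_peak_s
    out[pos] = x**alpha * np.exp(alpha * (1.0 - x))
    return out


def gaussian_blob(frame_shape: Tuple[int, int], center: Tuple[int, int],
                  sigma_px: float) -> np.ndarray:
    """Unit-peak isotropic 2-D Gaussian footprint."""
    rows = np.arange(frame_shape[0])[:, None] - center[0]
    cols = np.arange(frame_shape[1])[None, :] - center[1]
    return np.exp(-(rows**2 + cols**2) / (2.0 * sigma_px**2))


def _phase_walk(n: int, dt: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    return np.cumsum(rng.standard_normal(n)) * sd * np.sqrt(dt)


def disturbance_trace(acq: AcquisitionConfig, dist: DisturbanceConfig,
                      seed_seq: np.random.SeedSequence) -> dict:
    """Global multiplicative disturbance components at the camera frame rate.

    Returns a dict of per-frame traces (``breathing``, ``heartbeat``,
    ``drift`` and their sum ``total``), each a fraction of baseline
    intensity.  Harmonics share the fundamental's phase walk, as harmonics
    of one physical oscillator do.
    """
    n = acq.frames_per_trial_total * acq.n_trials
    dt = 1.0 / acq.frame_rate_hz
    t = np.arange(n) * dt
    ss_breath, ss_heart, ss_drift = seed_seq.spawn(3)

    def periodic(f_hz, amp, ss):
        rng = np.random.default_rng(ss)
        walk = _phase_walk(n, dt, dist.phase_noise_sd, rng)
        phi0 = rng.uniform(0, 2 * np.pi)
        base = 2 * np.pi * f_hz * t + walk + phi0
        out = np.zeros(n)
        for m in range(1, dist.n_harmonics + 2):  # fundamental + harmonics
            out += amp * dist.harmonic_decay ** (m - 1) * np.sin(m * base)
        return out

    breathing = periodic(dist.breathing_hz, dist.breathing_amp, ss_breath)
    heartbeat = periodic(dist.heartbeat_hz, dist.heartbeat_amp, ss_heart)
    drift_rng = np.random.default_rng(ss_drift)
    if dist.drift_rate > 0:
        drift = np.cumsum(drift_rng.standard_normal(n)) * dist.drift_rate * np.sqrt(dt)
    else:
        drift = np.zeros(n)
    return {
        "breathing": breathing,
        "heartbeat": heartbeat,
        "drift": drift,
        "total": breathing + heartbeat + drift,
    }


@dataclass
class GroundTruth:
    """Everything needed to score a simulated recording.

    The concentration fields factor as ``peak * spatial_profile (x, y) *
    temporal_profile (t)`` on the per-wavelength-cycle clock
    (``frames_per_trial * n_trials`` samples); :attr:`dc_o` / :attr:`dc_r`
    materialise the full fields on demand.
    """

    spatial_profile: np.ndarray       # (rows, cols), unit peak
    temporal_profile: np.ndarray      # (frames_per_trial * n_trials,), gains included
    delta_hbo_peak: float
    delta_hbr_peak: float
    center: Tuple[int, int]
    trial_gains: np.ndarray           # (n_trials,)
    disturbances: dict                # per-frame traces at the camera rate
    acquisition: AcquisitionConfig
    disturbance_config: DisturbanceConfig
    response_config: ResponseConfig

    @property
    def dc_o(self) -> np.ndarray:
        return self.delta_hbo_peak * (
            self.spatial_profile[:, :, None] * self.temporal_profile[None, None, :]
        )

    @property
    def dc_r(self) -> np.ndarray:
        return self.delta_hbr_peak * (
            self.spatial_profile[:, :, None] * self.temporal_profile[None, None, :]
        )

    def roi_trace(self, component: str = "hbt", roi_size: int = 50) -> np.ndarray:
        """Ground-truth ROI-mean concentration trace around the blob centre."""
        from .response import roi_slices

        rs, cs = roi_slices(self.spatial_profile.shape, self.center, roi_size)
        w = float(self.spatial_profile[rs, cs].mean())
        peak = {
            "hbo": self.delta_hbo_peak,
            "hbr": self.delta_hbr_peak,
            "hbt": self.delta_hbo_peak + self.delta_hbr_peak,
        }[component.lower()]
        return peak * w * self.temporal_profile


def _chromophore_products(acq: AcquisitionConfig, table):
    from .beer_lambert import ChromophoreTable

    if table is None:
        table = ChromophoreTable.default()
    return table.design_matrix(acq.wavelengths_nm)  # (n_wavelengths, 2)


def generate_raw_stack(
    acq: AcquisitionConfig,
    dist: DisturbanceConfig,
    resp: ResponseConfig,
    seed,
    table=None,
    dtype=np.float64,
) -> Tuple[RawStack, GroundTruth]:
    """Simulate one interleaved multi-wavelength recording.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.  ``table``
    overrides the chromophore table (defaults to the packaged one, shared
    with the unmixer).
    """
    dist.validate_against(acq)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_dist, ss_gain, ss_noise = ss.spawn(3)

    rows, cols = acq.frame_shape
    w = acq.n_wavelengths
    fpt = acq.frames_per_trial
    n_per = fpt * acq.n_trials
    n_total = n_per * w

    center = resp.resolve_center(acq.frame_shape)
    blob = gaussian_blob(acq.frame_shape, center, resp.spatial_sigma)

    # temporal profile on the per-wavelength cycle clock, gains per trial
    gain_rng = np.random.default_rng(ss_gain)
    gains = 1.0 + dist.trial_gain_jitter_sd * gain_rng.standard_normal(acq.n_trials)
    t_trial = np.arange(fpt) / acq.per_wavelength_rate_hz
    kern = gamma_kernel(t_trial, resp.onset_s, resp.time_to_peak_s, resp.decay_tau_s)
    profile = (kern[None, :] * gains[:, None]).ravel()

    disturbances = disturbance_trace(acq, dist, ss_dist)
    d_total = disturbances["total"]

    M = _chromophore_products(acq, table)  # (w, 2) of eps*l
    a = M[:, 0] * resp.delta_hbo_peak + M[:, 1] * resp.delta_hbr_peak  # per wavelength

    out = np.empty((rows, cols, n_total), dtype=dtype)
    for k in range(w):
        # dA for wavelength k factorises: a_k * blob * profile
        atten = 10.0 ** (-(a[k] * profile)[None, None, :] * blob[:, :, None])
        out[:, :, k::w] = (
            acq.illumination_counts[k] * atten * (1.0 + d_total[k::w])[None, None, :]
        )
    if dist.electrical_noise_sd > 0:
        noise_rng = np.random.default_rng(ss_noise)
        out += noise_rng.normal(0.0, dist.electrical_noise_sd, size=out.shape).astype(
            dtype, copy=False
        )

    gt = GroundTruth(
        spatial_profile=blob,
        temporal_profile=profile,
        delta_hbo_peak=resp.delta_hbo_peak,
        delta_hbr_peak=resp.delta_hbr_peak,
        center=center,
        trial_gains=gains,
        disturbances=disturbances,
        acquisition=acq,
        disturbance_config=dist,
        response_config=resp,
    )
    return RawStack(data=out, acquisition=acq), gt


def generate_blank_stack(acq: AcquisitionConfig, dist: DisturbanceConfig, seed,
                         dtype=np.float64) -> RawStack:
    """Stationary-scene recording: constant per-wavelength illumination plus
    electrical white noise only (no biological disturbances, no response)."""
    quiet = replace(dist, breathing_amp=0.0, heartbeat_amp=0.0, drift_rate=0.0,
                    trial_gain_jitter_sd=0.0)
    flat = ResponseConfig(delta_hbo_peak=0.0, delta_hbr_peak=0.0)
    stack, _ = generate_raw_stack(acq, quiet, flat, seed, dtype=dtype)
    return stack


def generate_no_stimulus_stack(acq: AcquisitionConfig, dist: DisturbanceConfig, seed,
                               dtype=np.float64) -> RawStack:
    """Resting-cortex recording: full disturbance model, response forced to
    zero amplitude."""
    flat = ResponseConfig(delta_hbo_peak=0.0, delta_hbr_peak=0.0)
    stack, _ = generate_raw_stack(acq, dist, flat, seed, dtype=dtype)
    return stack
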