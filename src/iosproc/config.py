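"""Acquisition, disturbance and response configuration objects.

These dataclasses carry the parameters of a multi-wavelength IOS recording:
the camera/LED timing (:class:`AcquisitionConfig`), the magnitudes and
frequencies of the physiological and electrical disturbances
(:class:`DisturbanceConfig`), and the simulated stimulus-evoked haemodynamic
response (:class:`ResponseConfig`).  All three validate their invariants at
construction time and round-trip through plain dicts for YAML configs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence


def _as_tuple(x) -> tuple:
    return tuple(x) if isinstance(x, (list, tuple)) else (x,)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera and trial-structure parameters of an interleaved recording.

    The camera runs at ``frame_rate_hz`` while the illumination cycles
    through ``wavelengths_nm`` one wavelength per frame, so each wavelength
    is sampled at ``frame_rate_hz / len(wavelengths_nm)`` frames per second
    (15 Hz at the defaults).  A trial consists of ``baseline_s`` of resting
    imaging, ``stimulus_s`` of stimulation and ``post_s`` of post-stimulus
    imaging (10 s total at the defaults, i.e. 600 camera frames and 150
    frames per wavelength).
    """

    frame_rate_hz: float = 60.0
    wavelengths_nm: tuple = (470.0, 530.0, 588.0, 627.0)
    frame_shape: tuple = (260, 280)
    baseline_s: float = 1.5
    stimulus_s: float = 1.5
    post_s: float = 7.0
    n_trials: int = 1
    pixel_pitch_um: float = 20.0
    #: mean illumination intensity reaching the camera per wavelength
    #: (arbitrary camera counts); scalar or one value per wavelength.
    illumination_counts: tuple = (800.0, 1000.0, 900.0, 700.0)

    def __post_init__(self):
        object.__setattr__(self, "wavelengths_nm", _as_tuple(self.wavelengths_nm))
        object.__setattr__(self, "frame_shape", tuple(int(v) for v in self.frame_shape))
        counts = _as_tuple(self.illumination_counts)
        if len(counts) == 1:
            counts = counts * self.n_wavelengths
        object.__setattr__(self, "illumination_counts", tuple(float(c) for c in counts))
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if len(self.illumination_counts) != self.n_wavelengths:
            raise ValueError("illumination_counts must match the number of wavelengths")
        if any(c <= 0 for c in self.illumination_counts):
            raise ValueError("illumination_counts must be positive")
        if self.frame_rate_hz % self.n_wavelengths != 0:
            raise ValueError(
                f"frame_rate_hz ({self.frame_rate_hz}) must be divisible by the "
                f"number of wavelengths ({self.n_wavelengths})"
            )
        n = self.trial_s * self.per_wavelength_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"trial duration {self.trial_s} s at {self.per_wavelength_rate_hz} "
                f"frames/s per wavelength gives a non-integer frame count {n}"
            )

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths_nm)

    @property
    def per_wavelength_rate_hz(self) -> float:
        return self.frame_rate_hz / self.n_wavelengths

    @property
    def trial_s(self) -> float:
        return self.baseline_s + self.stimulus_s + self.post_s

    @property
    def frames_per_trial(self) -> int:
        """Frames per trial for a single wavelength (150 at the defaults)."""
        return round(self.trial_s * self.per_wavelength_rate_hz)

    @property
    def frames_per_trial_total(self) -> int:
        """Camera frames per trial across all wavelengths (600 at defaults)."""
        return self.frames_per_trial * self.n_wavelengths

    @property
    def n_baseline_frames(self) -> int:
        """Length of the per-wavelength baseline window (22 at defaults)."""
        return int(self.frames_per_trial * self.baseline_s / self.trial_s)

    def to_dict(self) -> dict:
        return {k: list(v) if isinstance(v, tuple) else v
                for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        return cls(**d)


@dataclass(frozen=True)
class DisturbanceConfig:
    """Magnitudes and frequencies of the simulated disturbance sources.

    Breathing and heartbeat are global multiplicative sinusoids (fractions of
    the baseline intensity) with ``n_harmonics`` harmonics each, the k-th
    harmonic scaled by ``harmonic_decay**k``.  Their instantaneous phase
    performs a random walk with increment SD ``phase_noise_sd`` rad/sqrt(s),
    emulating physiological rate wander; this decoheres the interference
    from the trial clock the way real breathing does.  Drift is a Gaussian
    random walk (increment SD ``drift_rate`` per sqrt(s)) in relative
    intensity.  Electrical noise is i.i.d. additive Gaussian per pixel per
    frame in camera counts.  ``trial_gain_jitter_sd`` is the SD of the
    multiplicative per-trial jitter of the evoked-response amplitude.
    """

    breathing_hz: float = 1.2
    breathing_amp: float = 0.02
    heartbeat_hz: float = 6.0
    heartbeat_amp: float = 0.01
    n_harmonics: int = 2
    harmonic_decay: float = 0.5
    phase_noise_sd: float = 0.6
    electrical_noise_sd: float = 20.0
    drift_rate: float = 5e-4
    trial_gain_jitter_sd: float = 0.1

    def __post_init__(self):
        for name in ("breathing_amp", "heartbeat_amp", "electrical_noise_sd",
                     "drift_rate", "trial_gain_jitter_sd", "phase_noise_sd",
                     "harmonic_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")

    def validate_against(self, acq: AcquisitionConfig) -> None:
        nyq = acq.per_wavelength_rate_hz / 2.0
        for name in ("breathing_hz", "heartbeat_hz"):
            f = getattr(self, name)
            if f >= nyq:
                raise ValueError(
                    f"{name}={f} Hz is at or above the per-wavelength Nyquist "
                    f"frequency ({nyq} Hz)"
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DisturbanceConfig":
        return cls(**d)


@dataclass(frozen=True)
class ResponseConfig:
    """Forward model of the stimulus-evoked haemodynamic response.

    The response is an isotropic 2-D Gaussian blob (``center_xy`` in
    (row, col) pixels, ``spatial_sigma`` pixels) times a causal gamma-variate
    temporal kernel that is zero before ``onset_s``, peaks ``time_to_peak_s``
    after onset with unit amplitude, and decays with time constant
    ``decay_tau_s``.  Peak concentration changes are signed and in the same
    molar units as the chromophore table (so the Beer-Lambert round trip is
    exact): oxygenated haemoglobin rises while deoxygenated falls.
    """

    center_xy: tuple | None = None  # None -> frame centre
    spatial_sigma: float = 32.5     # px; 0.65 mm at 20 um/px
    delta_hbo_peak: float = 6e-7
    delta_hbr_peak: float = -2e-7
    onset_s: float = 1.5
    time_to_peak_s: float = 2.0
    decay_tau_s: float = 1.2

    def __post_init__(self):
        if self.center_xy is not None:
            object.__setattr__(self, "center_xy",
                               tuple(int(v) for v in self.center_xy))
        if self.spatial_sigma <= 0:
            raise ValueError("spatial_sigma must be positive")
        if self.time_to_peak_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("time_to_peak_s and decay_tau_s must be positive")
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")

    def resolve_center(self, frame_shape: Sequence[int]) -> tuple:
        if self.center_xy is not None:
            c = tuple(int(v) for v in self.center_xy)
        else:
            c = (frame_shape[0] // 2, frame_shape[1] // 2)
        if not (0 <= c[0] < frame_shape[0] and 0 <= c[1] < frame_shape[1]):
            raise ValueError(f"response centre {c} lies outside frame {tuple(frame_shape)}")
        return c

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["center_xy"] is not None:
            d["center_xy"] = list(d["center_xy"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseConfig":
        return cls(**d)
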