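"""The seven compared denoising techniques as sklearn-style transformers.

Every technique maps an N-trial single-wavelength stack ``(rows, cols,
frames_per_trial * n_trials)`` to a single-trial-equivalent stack ``(rows,
cols, frames_per_trial)``:

* :class:`TrialAverager` -- plain mean over trials, the baseline everything
  else is compared against.
* :class:`TemporalLowpass` / :class:`TemporalBandpass` -- Butterworth
  filtering of each pixel's continuous N-trial series, then trial
  averaging.  Filtering is zero-phase (forward-backward) by default so the
  two session halves stay comparable; a causal single-pass mode exists.
* :class:`PCADenoiser` -- SVD of the mean-subtracted pixels-by-time matrix,
  reconstruction from the top fraction of components.
* :class:`TruncatedDifference` -- same decomposition, but components are
  kept when their temporal course correlates with the stimulus
  presentation sequence (absolute Pearson correlation over the non-zero
  frames of the sequence) above ``threshold_multiplier`` times the mean
  correlation of all components.
* :class:`GlobalSignalRegressor` -- per-pixel least-squares removal of the
  all-pixel mean time course.
* :class:`SpatialGaussian` -- per-frame 2-D Gaussian smoothing (sigma given
  in micrometres), then trial averaging.

Techniques run on raw intensity stacks before Beer-Lambert conversion, so
outputs must remain valid (positive) intensities.  Operations that remove
the temporal mean (bandpass, GSR) therefore restore each pixel's
pre-processing mean by default; the low-level functions (:func:`gsr`,
:func:`butter_filter`) are the untouched textbook forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, TransformerMixin

from .stacks import WavelengthStack

__all__ = [
    "TechniqueResult",
    "build_stimulus_sequence",
    "svd_components",
    "reconstruct_components",
    "gsr",
    "butter_filter",
    "gaussian_kernel",
    "average_trials",
    "TrialAverager",
    "TemporalLowpass",
    "TemporalBandpass",
    "PCADenoiser",
    "TruncatedDifference",
    "GlobalSignalRegressor",
    "SpatialGaussian",
    "TECHNIQUES",
    "make_technique",
]


# ---------------------------------------------------------------------------
# small shared pieces

@dataclass
class TechniqueResult:
    """A technique's single-trial-equivalent output plus provenance."""

    data: np.ndarray  # (rows, cols, frames_per_trial)
    name: str
    params: dict = field(default_factory=dict)
    n_trials: int = 1


def build_stimulus_sequence(frames_per_trial: int = 150,
                            windows=None) -> np.ndarray:
    """Per-frame stimulus presentation weights w(t) in {-1, 0, +1}.

    The default windows (1-based, inclusive, for a 150-frame trial) are
    -1 on frames 1-22 (baseline), +1 on frames 41-70 (spanning the response
    peak) and 0 elsewhere; for other trial lengths the edges scale
    proportionally.  ``windows`` is a list of ``(first, last, value)``
    triples in 1-based inclusive frame indices.
    """
    if windows is None:
        f = frames_per_trial / 150.0
        windows = [
            (1, max(1, int(np.floor(22 * f))), -1),
            (int(np.ceil(41 * f)), int(np.floor(70 * f)), 1),
        ]
    w = np.zeros(frames_per_trial)
    seen = np.zeros(frames_per_trial, dtype=bool)
    for first, last, value in windows:
        if not (1 <= first <= last <= frames_per_trial):
            raise ValueError(f"window ({first}, {last}) outside trial of "
                             f"{frames_per_trial} frames")
        sl = slice(first - 1, last)  # 1-based inclusive -> 0-based half-open
        if seen[sl].any():
            raise ValueError("stimulus windows overlap")
        seen[sl] = True
        w[sl] = value
    return w


def average_trials(data: np.ndarray, frames_per_trial: int) -> np.ndarray:
    """Mean across trials of a ``(rows, cols, frames_per_trial * N)`` stack."""
    r, c, t = data.shape
    if t % frames_per_trial != 0:
        raise ValueError(
            f"{t} frames is not a whole number of {frames_per_trial}-frame trials"
        )
    n = t // frames_per_trial
    return data.reshape(r, c, n, frames_per_trial).mean(axis=2)


def svd_components(C: np.ndarray):
    """Singular components of a pixels-by-time matrix ``C = U S V'``.

    Returns ``(U, s, P)`` with ``k = min(L, T)`` columns/rows, where
    ``P = U' C = S V'`` holds the (unnormalised) temporal courses; the i-th
    temporal singular vector is ``P[i] / s[i]``.  Computed through the Gram
    matrix on the smaller side, which is exact for reconstruction purposes
    (``U[:, idx] @ P[idx]`` is the orthogonal projection of ``C`` onto the
    selected components) and much faster than a full SVD at imaging sizes.
    Component signs are fixed deterministically (largest-magnitude element
    of each spatial vector made positive).
    """
    C = np.asarray(C)
    L, T = C.shape
    if L <= T:
        G = C @ C.T
        w, U = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        U = U[:, order]
        s = np.sqrt(np.clip(w[order], 0.0, None))
        P = U.T @ C
    else:
        G = C.T @ C
        w, V = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        V = V[:, order]
        s = np.sqrt(np.clip(w[order], 0.0, None))
        tol = s[0] * 1e-12 if s.size and s[0] > 0 else 0.0
        safe = np.where(s > tol, s, np.inf)
        U = (C @ V) / safe[None, :]
        P = s[:, None] * V.T
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    return U * flip[None, :], s, P * flip[:, None]


def reconstruct_components(U: np.ndarray, P: np.ndarray, idx) -> np.ndarray:
    """Rebuild the pixels-by-time matrix from the selected components."""
    idx = np.asarray(idx)
    if idx.size == 0:
        raise ValueError("no components selected")
    return U[:, idx] @ P[idx]


def gsr(C: np.ndarray, g: Optional[np.ndarray] = None):
    """Global signal regression residuals, textbook form.

    ``C`` is pixels-by-time.  The global regressor ``g`` defaults to the
    mean over pixels.  Per pixel ``i``::

        beta_i = (g' g)^-1 g' C_i
        R_i    = C_i - g beta_i

    Returns ``(R, beta)``.
    """
    C = np.asarray(C, dtype=float)
    g = C.mean(axis=0) if g is None else np.asarray(g, dtype=float)
    gg = float(g @ g)
    if gg == 0.0:
        raise ValueError("global signal is identically zero")
    beta = (C @ g) / gg
    return C - beta[:, None] * g[None, :], beta


def butter_filter(x: np.ndarray, fs: float, btype: str, order: int,
                  cutoff, zero_phase: bool = True, axis: int = -1) -> np.ndarray:
    """Butterworth filtering along ``axis``.

    ``order`` is the overall filter order; for a bandpass design the
    underlying prototype uses ``order // 2`` pole pairs, matching the
    convention in which a "20th-order bandpass" has 20 poles.  Zero-phase
    mode applies the filter forward and backward (no group delay; the
    effective magnitude response is squared).
    """
    nyq = fs / 2.0
    if btype == "low":
        fc = float(cutoff)
        if not 0 < fc < nyq:
            raise ValueError(f"cutoff {fc} Hz must lie in (0, {nyq}) Hz")
        sos = signal.butter(order, fc / nyq, btype="low", output="sos")
    elif btype == "band":
        lo, hi = cutoff
        if not 0 < lo < hi < nyq:
            raise ValueError(f"band ({lo}, {hi}) Hz must satisfy 0 < lo < hi < {nyq}")
        if order % 2 != 0:
            raise ValueError("bandpass order must be even")
        sos = signal.butter(order // 2, (lo / nyq, hi / nyq), btype="band",
                            output="sos")
    else:
        raise ValueError(f"unsupported btype {btype!r}")
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=axis)
    return signal.sosfilt(sos, x, axis=axis)


def gaussian_kernel(sigma_px: float, truncate: float = 4.0) -> np.ndarray:
    """Normalised 2-D Gaussian kernel sampled at pixel centres.

    ``F(x, y) = exp(-(x^2+y^2)/(2 sigma^2)) / (2 pi sigma^2)``, truncated at
    ``truncate * sigma`` and renormalised to unit sum so total intensity is
    conserved exactly.
    """
    if sigma_px <= 0:
        raise ValueError("sigma must be positive")
    radius = int(truncate * sigma_px + 0.5)
    ax = np.arange(-radius, radius + 1)
    k = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma_px**2))
    return k / k.sum()


# ---------------------------------------------------------------------------
# transformers

class _Technique(BaseEstimator, TransformerMixin):
    """Shared plumbing: input coercion, trial bookkeeping, fit no-op."""

    name = "technique"

    frames_per_trial: int

    def fit(self, X, y=None):
        return self

    def _coerce(self, X) -> Tuple[np.ndarray, int]:
        if isinstance(X, WavelengthStack):
            return X.data, X.frames_per_trial
        data = np.asarray(X)
        if data.ndim != 3:
            raise ValueError("expected a (rows, cols, time) stack")
        fpt = self.frames_per_trial
        if data.shape[2] % fpt != 0:
            raise ValueError(
                f"{data.shape[2]} frames is not a whole number of "
                f"{fpt}-frame trials"
            )
        return data, fpt

    def describe(self, X) -> TechniqueResult:
        data, fpt = self._coerce(X)
        out = self.transform(X)
        return TechniqueResult(data=out, name=self.name,
                               params=self.get_params(),
                               n_trials=data.shape[2] // fpt)


class TrialAverager(_Technique):
    """Signal averaging over trials: ``R(t) = (1/N) sum_n C_n(t)``."""

    name = "averaging"

    def __init__(self, frames_per_trial: int = 150):
        self.frames_per_trial = frames_per_trial

    def transform(self, X) -> np.ndarray:
        data, fpt = self._coerce(X)
        return average_trials(data, fpt)


class TemporalLowpass(_Technique):
    """Butterworth low-pass of each pixel's continuous series, then trial
    averaging.  Defaults (order 10, 0.5 Hz at 15 Hz sampling) sit just below
    the bulk of the breathing/heartbeat interference."""

    name = "lowpass"

    def __init__(self, frames_per_trial: int = 150, sampling_rate_hz: float = 15.0,
                 order: int = 10, cutoff_hz: float = 0.5, zero_phase: bool = True):
        self.frames_per_trial = frames_per_trial
        self.sampling_rate_hz = sampling_rate_hz
        self.order = order
        self.cutoff_hz = cutoff_hz
        self.zero_phase = zero_phase

    def transform(self, X) -> np.ndarray:
        data, fpt = self._coerce(X)
        fs = X.per_wavelength_rate_hz if isinstance(X, WavelengthStack) else self.sampling_rate_hz
        filt = butter_filter(data, fs, "low", self.order, self.cutoff_hz,
                             zero_phase=self.zero_phase)
        return average_trials(filt, fpt)


class TemporalBandpass(_Technique):
    """Butterworth band-pass (default 0.09-0.5 Hz, overall order 20) of each
    pixel's continuous series, then trial averaging.  Removes offset and
    slow drift as well as the periodic interference; each pixel's temporal
    mean is restored afterwards so the output remains a valid intensity
    stack (disable with ``restore_mean=False`` for the raw filter output).
    """

    name = "bandpass"

    def __init__(self, frames_per_trial: int = 150, sampling_rate_hz: float = 15.0,
                 order: int = 20, low_hz: float = 0.09, high_hz: float = 0.5,
                 zero_phase: bool = True, restore_mean: bool = True):
        self.frames_per_trial = frames_per_trial
        self.sampling_rate_hz = sampling_rate_hz
        self.order = order
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.zero_phase = zero_phase
        self.restore_mean = restore_mean

    def transform(self, X) -> np.ndarray:
        data, fpt = self._coerce(X)
        fs = X.per_wavelength_rate_hz if isinstance(X, WavelengthStack) else self.sampling_rate_hz
        filt = butter_filter(data, fs, "band", self.order,
                             (self.low_hz, self.high_hz),
                             zero_phase=self.zero_phase)
        if self.restore_mean:
            filt = filt + data.mean(axis=2, keepdims=True)
        return average_trials(filt, fpt)


class _SVDTechnique(_Technique):
    """Base for the two PCA-family techniques: reshape to pixels-by-time,
    subtract per-pixel means, decompose, reconstruct from the subclass's
    component selection, add means back, average trials."""

    def _select(self, U, s, P, fpt) -> np.ndarray:
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        data, fpt = self._coerce(X)
        r, c, t = data.shape
        C = data.reshape(r * c, t)
        mu = C.mean(axis=1, keepdims=True)
        U, s, P = svd_components(C - mu)
        idx = self._select(U, s, P, fpt)
        rec = reconstruct_components(U, P, idx) + mu
        return average_trials(rec.reshape(r, c, t), fpt)


class PCADenoiser(_SVDTechnique):
    """Keep the top ``ceil(keep_fraction * n_components)`` singular
    components by variance (at least one)."""

    name = "pca"

    def __init__(self, frames_per_trial: int = 150, keep_fraction: float = 0.25):
        self.frames_per_trial = frames_per_trial
        self.keep_fraction = keep_fraction

    def _select(self, U, s, P, fpt):
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        k = max(1, int(np.ceil(self.keep_fraction * len(s))))
        return np.arange(k)


class TruncatedDifference(_SVDTechnique):
    """Keep components whose temporal course correlates with the stimulus
    presentation sequence.

    The correlation score of component i is the absolute Pearson
    correlation between its temporal course and the trial-tiled sequence
    w(t), restricted to frames where w != 0; components scoring above
    ``threshold_multiplier`` times the mean score are kept.
    """

    name = "truncdiff"

    def __init__(self, frames_per_trial: int = 150, threshold_multiplier: float = 3.0,
                 stimulus: Optional[np.ndarray] = None):
        self.frames_per_trial = frames_per_trial
        self.stimulus = stimulus
        self.threshold_multiplier = threshold_multiplier

    def correlation_scores(self, P: np.ndarray, fpt: int) -> np.ndarray:
        w = self.stimulus if self.stimulus is not None else build_stimulus_sequence(fpt)
        w = np.asarray(w, dtype=float)
        if len(w) != fpt:
            raise ValueError("stimulus sequence length must equal frames_per_trial")
        n_trials = P.shape[1] // fpt
        tiled = np.tile(w, n_trials)
        mask = tiled != 0
        wm = tiled[mask] - tiled[mask].mean()
        wm_norm = np.linalg.norm(wm)
        V = P[:, mask]
        V = V - V.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(V, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(V @ wm) / (norms * wm_norm)
        corr[~np.isfinite(corr)] = 0.0
        return corr

    def _select(self, U, s, P, fpt):
        corr = self.correlation_scores(P, fpt)
        # components below the Gram-decomposition noise floor carry no
        # signal and would contribute meaningless correlations
        if s.size and s[0] > 0:
            tol = s[0] * np.sqrt(np.finfo(float).eps * max(U.shape[0], P.shape[1]))
            corr[s <= tol] = 0.0
        thresh = self.threshold_multiplier * corr.mean()
        idx = np.flatnonzero(corr > thresh)
        if idx.size == 0:
            raise ValueError(
                "no component's stimulus correlation exceeded "
                f"{self.threshold_multiplier} x mean; consider lowering "
                "threshold_multiplier"
            )
        self.selected_components_ = idx
        self.correlation_scores_ = corr
        return idx


class GlobalSignalRegressor(_Technique):
    """Regress the all-pixel mean time course out of every pixel, then
    average trials.

    The regression runs on mean-removed series (equivalently, a constant
    regressor accompanies the global signal) and each pixel's mean is
    restored afterwards, keeping the output a valid intensity stack; set
    ``restore_mean=False`` for the verbatim single-regressor form.
    """

    name = "gsr"

    def __init__(self, frames_per_trial: int = 150, restore_mean: bool = True):
        self.frames_per_trial = frames_per_trial
        self.restore_mean = restore_mean

    def transform(self, X) -> np.ndarray:
        data, fpt = self._coerce(X)
        r, c, t = data.shape
        C = data.reshape(r * c, t)
        if self.restore_mean:
            mu = C.mean(axis=1, keepdims=True)
            resid, beta = gsr(C - mu)
            resid = resid + mu
        else:
            resid, beta = gsr(C)
        self.beta_ = beta.reshape(r, c)
        return average_trials(resid.reshape(r, c, t), fpt)


class SpatialGaussian(_Technique):
    """Smooth each frame with a normalised 2-D Gaussian (sigma in
    micrometres, converted through the pixel pitch), then average trials.
    Boundary handling is reflective; the kernel is truncated at 4 sigma and
    renormalised, so total frame intensity is conserved."""

    name = "gaussian"

    def __init__(self, frames_per_trial: int = 150, sigma_um: float = 200.0,
                 pixel_pitch_um: float = 20.0, truncate: float = 4.0):
        self.frames_per_trial = frames_per_trial
        self.sigma_um = sigma_um
        self.pixel_pitch_um = pixel_pitch_um
        self.truncate = truncate

    @property
    def sigma_px(self) -> float:
        return self.sigma_um / self.pixel_pitch_um

    def transform(self, X) -> np.ndarray:
        if self.sigma_um <= 0:
            raise ValueError("sigma_um must be positive")
        data, fpt = self._coerce(X)
        smoothed = ndimage.gaussian_filter(
            data, sigma=(self.sigma_px, self.sigma_px, 0.0),
            mode="reflect", truncate=self.truncate,
        )
        return average_trials(smoothed, fpt)


TECHNIQUES = {
    cls.name: cls
    for cls in (TrialAverager, TemporalLowpass, TemporalBandpass, PCADenoiser,
                TruncatedDifference, GlobalSignalRegressor, SpatialGaussian)
}

# aliases accepted on the command line
_ALIASES = {"avg": "averaging", "gauss": "gaussian"}


def make_technique(name: str, **params) -> _Technique:
    """Instantiate a technique by name (e.g. ``"bandpass"``)."""
    key = _ALIASES.get(name, name)
    try:
        cls = TECHNIQUES[key]
    except KeyError:
        raise ValueError(
            f"unknown technique {name!r}; choose from {sorted(TECHNIQUES)}"
        ) from None
    return cls(**params)


# ---------------------------------------------------------------------------
# functional wrappers

def average_over_trials(X, frames_per_trial: int = 150) -> TechniqueResult:
    return TrialAverager(frames_per_trial).describe(X)


def temporal_lowpass(X, frames_per_trial: int = 150, sampling_rate_hz: float = 15.0,
                     order: int = 10, cutoff_hz: float = 0.5,
                     zero_phase: bool = True) -> TechniqueResult:
    return TemporalLowpass(frames_per_trial, sampling_rate_hz, order, cutoff_hz,
                           zero_phase).describe(X)


def temporal_bandpass(X, frames_per_trial: int = 150, sampling_rate_hz: float = 15.0,
                      order: int = 20, low_hz: float = 0.09, high_hz: float = 0.5,
                      zero_phase: bool = True, restore_mean: bool = True) -> TechniqueResult:
    return TemporalBandpass(frames_per_trial, sampling_rate_hz, order, low_hz,
                            high_hz, zero_phase, restore_mean).describe(X)


def pca_denoise(X, frames_per_trial: int = 150, keep_fraction: float = 0.25) -> TechniqueResult:
    return PCADenoiser(frames_per_trial, keep_fraction).describe(X)


def truncated_difference(X, frames_per_trial: int = 150,
                         threshold_multiplier: float = 3.0,
                         stimulus: Optional[np.ndarray] = None) -> TechniqueResult:
    return TruncatedDifference(frames_per_trial, threshold_multiplier,
                               stimulus).describe(X)


def global_signal_regression(X, frames_per_trial: int = 150,
                             restore_mean: bool = True) -> TechniqueResult:
    return GlobalSignalRegressor(frames_per_trial, restore_mean).describe(X)


def spatial_gaussian(X, frames_per_trial: int = 150, sigma_um: float = 200.0,
                     pixel_pitch_um: float = 20.0) -> TechniqueResult:
    return SpatialGaussian(frames_per_trial, sigma_um, pixel_pitch_um).describe(X)
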