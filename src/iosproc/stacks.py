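"""Image-stack containers and pure indexing operations.

A recording moves through three representations: the interleaved
:class:`RawStack` straight off the camera, per-wavelength
:class:`WavelengthStack` objects after demultiplexing, and a
:class:`HaemoStack` of chromophore concentration changes after
Beer-Lambert unmixing.  All arrays are ``(rows, cols, time)``.

The operations here (demultiplex, interleave, trial segmentation, crop)
never touch pixel values; they are pure reindexing and invert each other
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np

from .config import AcquisitionConfig


@dataclass
class RawStack:
    """Interleaved multi-wavelength recording: frame ``t`` was taken under
    wavelength ``t mod n_wavelengths`` (positional assignment; no per-frame
    metadata is needed for an LED-cycling acquisition)."""

    data: np.ndarray  # (rows, cols, n_frames), acquisition order
    acquisition: AcquisitionConfig

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("RawStack data must be 3-D (rows, cols, time)")
        w = self.acquisition.n_wavelengths
        if self.data.shape[2] % w != 0:
            raise ValueError(
                f"frame count {self.data.shape[2]} not divisible by the "
                f"wavelength cycle length {w} (remainder {self.data.shape[2] % w})"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def wavelength_of_frame(self, t) -> np.ndarray:
        """Wavelength index of frame ``t`` (cyclic positional mapping)."""
        return np.asarray(t) % self.acquisition.n_wavelengths


@dataclass
class WavelengthStack:
    """Single-wavelength stack of ``frames_per_trial * n_trials`` frames in
    temporal order, sampled at ``per_wavelength_rate_hz``."""

    data: np.ndarray  # (rows, cols, frames_per_trial * n_trials)
    wavelength_nm: float
    per_wavelength_rate_hz: float
    frames_per_trial: int
    n_trials: int

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("WavelengthStack data must be 3-D")
        expect = self.frames_per_trial * self.n_trials
        if self.data.shape[2] != expect:
            raise ValueError(
                f"stack has {self.data.shape[2]} frames, expected "
                f"frames_per_trial * n_trials = {expect}"
            )


@dataclass
class HaemoStack:
    """Per-pixel concentration changes for oxygenated (``dc_o``) and
    deoxygenated (``dc_r``) haemoglobin; total haemoglobin is their sum by
    construction."""

    dc_o: np.ndarray
    dc_r: np.ndarray

    def __post_init__(self):
        if self.dc_o.shape != self.dc_r.shape:
            raise ValueError("dc_o and dc_r must have identical shapes")

    @property
    def dc_t(self) -> np.ndarray:
        return self.dc_o + self.dc_r

    def component(self, which: str) -> np.ndarray:
        which = which.lower()
        if which in ("hbo", "hbo2", "o"):
            return self.dc_o
        if which in ("hbr", "r"):
            return self.dc_r
        if which in ("hbt", "t", "total"):
            return self.dc_t
        raise ValueError(f"unknown chromophore {which!r}")


def demultiplex(raw: RawStack) -> List[WavelengthStack]:
    """Split an interleaved recording into one stack per wavelength.

    Output ``k`` contains frames ``k, k+W, k+2W, ...`` (``W`` the cycle
    length), order preserved, so :func:`interleave` inverts it exactly.
    """
    acq = raw.acquisition
    w = acq.n_wavelengths
    n_per = raw.n_frames // w
    if n_per % acq.frames_per_trial != 0:
        raise ValueError(
            f"{n_per} frames per wavelength not divisible by "
            f"frames_per_trial={acq.frames_per_trial}"
        )
    n_trials = n_per // acq.frames_per_trial
    return [
        WavelengthStack(
            data=raw.data[:, :, k::w],
            wavelength_nm=acq.wavelengths_nm[k],
            per_wavelength_rate_hz=acq.per_wavelength_rate_hz,
            frames_per_trial=acq.frames_per_trial,
            n_trials=n_trials,
        )
        for k in range(w)
    ]


def interleave(stacks: Sequence[WavelengthStack], acquisition: AcquisitionConfig) -> RawStack:
    """Inverse of :func:`demultiplex`: re-interleave per-wavelength stacks
    into acquisition frame order."""
    n = {s.data.shape[2] for s in stacks}
    if len(n) != 1:
        raise ValueError("all wavelength stacks must have equal frame counts")
    n = n.pop()
    w = len(stacks)
    first = stacks[0].data
    out = np.empty((first.shape[0], first.shape[1], n * w), dtype=first.dtype)
    for k, s in enumerate(stacks):
        out[:, :, k::w] = s.data
    return RawStack(data=out, acquisition=acquisition)


def segment_trials(ws: WavelengthStack) -> np.ndarray:
    """View a stack as ``(rows, cols, frames_per_trial, n_trials)``.

    Trial ``n``, frame ``t`` maps to source frame ``n*frames_per_trial + t``;
    the operation is lossless (``flatten_trials`` inverts it).
    """
    r, c, n = ws.data.shape
    if n % ws.frames_per_trial != 0:
        raise ValueError(
            f"{n} frames not divisible by frames_per_trial={ws.frames_per_trial}"
        )
    n_trials = n // ws.frames_per_trial
    return np.moveaxis(
        ws.data.reshape(r, c, n_trials, ws.frames_per_trial), 2, 3
    )


def flatten_trials(trials: np.ndarray) -> np.ndarray:
    """Inverse of :func:`segment_trials` (returns the plain data array)."""
    r, c, fpt, n_trials = trials.shape
    return np.moveaxis(trials, 3, 2).reshape(r, c, fpt * n_trials)


def crop(data: np.ndarray, row_range: tuple, col_range: tuple) -> np.ndarray:
    """Spatially crop a 2-D image or 3-D stack to half-open pixel ranges.

    Time is untouched; pixel values are untouched.
    """
    r0, r1 = row_range
    c0, c1 = col_range
    if not (0 <= r0 < r1 <= data.shape[0] and 0 <= c0 < c1 <= data.shape[1]):
        raise ValueError(
            f"crop ranges rows[{r0}:{r1}] cols[{c0}:{c1}] out of bounds for "
            f"frame shape {data.shape[:2]}"
        )
    return data[r0:r1, c0:c1]


def crop_stack(ws: WavelengthStack, row_range: tuple, col_range: tuple) -> WavelengthStack:
    return replace(ws, data=crop(ws.data, row_range, col_range))
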