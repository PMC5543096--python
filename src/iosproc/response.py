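"""Reduction of a concentration stack to the two study endpoints.

* a temporal response: the mean over a square ROI (default 50 x 50 px,
  centred on the peak response) of each frame, giving one value per frame;
* a spatial response map: the mean over a frame window (default frames
  41-70, 1-based inclusive -- the 30 frames spanning the response peak).

ROI placement on data without ground truth is automated by
:func:`locate_peak_roi` (argmax of the lightly smoothed spatial map over
all fully-contained ROI positions, deterministic first-by-scan-order
tie-break), since manual placement is not reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .stacks import HaemoStack

__all__ = [
    "TemporalResponse",
    "SpatialMap",
    "roi_slices",
    "temporal_response",
    "spatial_map",
    "locate_peak_roi",
]


@dataclass
class TemporalResponse:
    trace: np.ndarray          # (frames_per_trial,)
    roi_center: Tuple[int, int]
    roi_size: int
    component: str = "hbt"


@dataclass
class SpatialMap:
    map: np.ndarray            # (rows, cols)
    frame_window: Tuple[int, int]  # 1-based inclusive
    component: str = "hbt"


def _component(h, component: str) -> np.ndarray:
    if isinstance(h, HaemoStack):
        return h.component(component)
    arr = np.asarray(h)
    if arr.ndim != 3:
        raise ValueError("expected a HaemoStack or (rows, cols, t) array")
    return arr


def roi_slices(frame_shape, center, size: int) -> Tuple[slice, slice]:
    """Row/col slices of a ``size x size`` ROI with top-left corner at
    ``center - size // 2``; raises if the ROI is not fully inside the frame."""
    r0 = int(center[0]) - size // 2
    c0 = int(center[1]) - size // 2
    if not (0 <= r0 and r0 + size <= frame_shape[0]
            and 0 <= c0 and c0 + size <= frame_shape[1]):
        raise ValueError(
            f"{size}x{size} ROI centred at {tuple(center)} lies outside the "
            f"{tuple(frame_shape)} frame"
        )
    return slice(r0, r0 + size), slice(c0, c0 + size)


def temporal_response(h, roi_center, roi_size: int = 50,
                      component: str = "hbt") -> TemporalResponse:
    """Spatially average the ROI through time into a single trace."""
    data = _component(h, component)
    rs, cs = roi_slices(data.shape[:2], roi_center, roi_size)
    trace = data[rs, cs].mean(axis=(0, 1))
    return TemporalResponse(trace=trace, roi_center=tuple(int(v) for v in roi_center),
                            roi_size=roi_size, component=component)


def spatial_map(h, frame_window: Tuple[int, int] = (41, 70),
                component: str = "hbt") -> SpatialMap:
    """Temporally average the frame window into a single image.

    ``frame_window`` is 1-based inclusive, so the default (41, 70) averages
    exactly 30 frames.
    """
    data = _component(h, component)
    first, last = frame_window
    if not (1 <= first <= last <= data.shape[2]):
        raise ValueError(
            f"frame window {frame_window} invalid for a {data.shape[2]}-frame trial"
        )
    img = data[:, :, first - 1:last].mean(axis=2)
    return SpatialMap(map=img, frame_window=(first, last), component=component)


def locate_peak_roi(h, roi_size: int = 50, frame_window: Tuple[int, int] = (41, 70),
                    component: str = "hbt", smooth_sigma_px: float = 2.0,
                    ground_truth_center=None) -> Tuple[int, int]:
    """Centre of the ROI maximising the windowed spatial map's mean.

    The map is lightly Gaussian-smoothed first; only ROI positions fully
    inside the frame are considered; ties resolve to the lowest row then
    column.  Passing ``ground_truth_center`` (synthetic runs) bypasses the
    search.
    """
    if ground_truth_center is not None:
        return tuple(int(v) for v in ground_truth_center)
    data = _component(h, component)
    if data.size == 0:
        raise ValueError("empty stack")
    if roi_size > min(data.shape[:2]):
        raise ValueError("roi_size exceeds frame")
    img = spatial_map(h, frame_window=frame_window, component=component).map
    if smooth_sigma_px > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma_px, mode="reflect")
    means = ndimage.uniform_filter(img, size=roi_size, mode="constant")
    half = roi_size // 2
    valid = np.full(img.shape, -np.inf)
    r_lo, r_hi = half, img.shape[0] - roi_size + half
    c_lo, c_hi = half, img.shape[1] - roi_size + half
    valid[r_lo:r_hi + 1, c_lo:c_hi + 1] = means[r_lo:r_hi + 1, c_lo:c_hi + 1]
    flat = int(np.argmax(valid))
    return (flat // img.shape[1], flat % img.shape[1])
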