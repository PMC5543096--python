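"""Modified Beer-Lambert conversion of intensities to haemoglobin changes.

The change in absorbance at each wavelength relates linearly to the
chromophore concentration changes::

    dA_lam = epsO_lam * lO_lam * dC_O + epsR_lam * lR_lam * dC_R
    dA     = log10(I0 / I_a)

With four wavelengths and two chromophores the system is over-determined
and is solved per pixel per frame by least squares, yielding the
oxygenated (dC_O) and deoxygenated (dC_R) concentration changes; total
haemoglobin is their sum.

Sign convention: the textbook form ``log10(I0 / I_a)`` is the default, so
that an increase in absorber concentration gives a positive ``dA``.  The
inverted ratio sometimes seen in print is available via
``printed_sign=True``.

Molar extinction coefficients at 470/530/588/627 nm ship as a CSV of
approximate compiled haemoglobin-spectra values; pathlengths default to 1,
so concentrations are in relative units unless a per-wavelength pathlength
table is supplied (absolute quantification is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .stacks import HaemoStack, WavelengthStack

__all__ = [
    "ChromophoreTable",
    "compute_baseline",
    "delta_absorbance",
    "unmix",
    "BeerLambertUnmixer",
]


@dataclass(frozen=True)
class ChromophoreTable:
    """Per-wavelength molar absorptivity and pathlength for HbO2 and HbR.

    ``epsilon`` entries are in cm^-1 / M; ``pathlength`` is dimensionless
    relative (default 1) unless calibrated.  The 4x2 product matrix
    ``[eps * l]`` must have rank 2 for unmixing to be possible.
    """

    frame: pd.DataFrame  # columns: wavelength_nm, chromophore, epsilon, pathlength

    def __post_init__(self):
        required = {"wavelength_nm", "chromophore", "epsilon", "pathlength"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"chromophore table needs columns {sorted(required)}")
        if (self.frame["epsilon"] <= 0).any() or (self.frame["pathlength"] <= 0).any():
            raise ValueError("epsilon and pathlength must be positive")

    @classmethod
    def default(cls) -> "ChromophoreTable":
        with resources.files("iosproc.data").joinpath("hb_extinction.csv").open() as fh:
            return cls(pd.read_csv(fh))

    @classmethod
    def from_csv(cls, path) -> "ChromophoreTable":
        return cls(pd.read_csv(path))

    def design_matrix(self, wavelengths_nm: Sequence[float]) -> np.ndarray:
        """The ``(n_wavelengths, 2)`` matrix of eps*l products, columns
        ordered (HbO2, HbR)."""
        out = np.empty((len(wavelengths_nm), 2))
        for i, lam in enumerate(wavelengths_nm):
            for j, chrom in enumerate(("HbO2", "HbR")):
                sel = self.frame[
                    (self.frame["wavelength_nm"] == lam)
                    & (self.frame["chromophore"] == chrom)
                ]
                if len(sel) != 1:
                    raise ValueError(
                        f"chromophore table has {len(sel)} entries for "
                        f"{lam} nm / {chrom}; expected exactly 1"
                    )
                out[i, j] = float(sel["epsilon"].iloc[0] * sel["pathlength"].iloc[0])
        if np.linalg.matrix_rank(out) < 2:
            raise ValueError("eps*l design matrix is rank deficient")
        return out


def compute_baseline(data: np.ndarray, baseline_frames) -> np.ndarray:
    """Per-pixel mean intensity over the baseline frames.

    ``baseline_frames`` is an index array/slice into the time axis (0-based);
    use :meth:`AcquisitionConfig.n_baseline_frames` frames from the trial
    start to reproduce the default 22-frame window.
    """
    base = data[:, :, baseline_frames]
    if base.shape[2] == 0:
        raise ValueError("empty baseline frame set")
    i0 = base.mean(axis=2)
    if (i0 <= 0).any():
        raise ValueError("nonpositive baseline mean; cannot form absorbance ratio")
    return i0


def delta_absorbance(i_a: np.ndarray, i0: np.ndarray,
                     printed_sign: bool = False) -> np.ndarray:
    """Change in absorbance relative to baseline.

    Default is ``log10(I0 / I_a)`` (positive when absorbers increase);
    ``printed_sign=True`` flips the ratio.
    """
    i_a = np.asarray(i_a, dtype=float)
    i0 = np.asarray(i0, dtype=float)
    if (i_a <= 0).any() or (i0 <= 0).any():
        raise ValueError("intensities must be strictly positive to take log10")
    if i_a.ndim == i0.ndim + 1:
        i0 = i0[..., None]
    da = np.log10(i0 / i_a)
    return -da if printed_sign else da


def unmix(delta_a: np.ndarray, table: Optional[ChromophoreTable] = None,
          wavelengths_nm: Sequence[float] = (470.0, 530.0, 588.0, 627.0),
          return_residuals: bool = False):
    """Least-squares unmixing of absorbance changes into (dC_O, dC_R).

    ``delta_a`` has shape ``(n_wavelengths, rows, cols, t)`` (stacks aligned
    in space and time).  Returns a :class:`HaemoStack`; with
    ``return_residuals=True`` also the per-wavelength residual stack.
    """
    table = table or ChromophoreTable.default()
    delta_a = np.asarray(delta_a)
    if delta_a.ndim != 4:
        raise ValueError("delta_a must be (n_wavelengths, rows, cols, t)")
    n_w, rows, cols, t = delta_a.shape
    if n_w != len(wavelengths_nm):
        raise ValueError("first axis of delta_a must match wavelengths_nm")
    M = table.design_matrix(wavelengths_nm)
    b = delta_a.reshape(n_w, -1)
    coef, *_ = np.linalg.lstsq(M, b, rcond=None)  # (2, rows*cols*t)
    dc_o = coef[0].reshape(rows, cols, t)
    dc_r = coef[1].reshape(rows, cols, t)
    h = HaemoStack(dc_o=dc_o, dc_r=dc_r)
    if return_residuals:
        resid = (b - M @ coef).reshape(delta_a.shape)
        return h, resid
    return h


class BeerLambertUnmixer(BaseEstimator, TransformerMixin):
    """Transformer from per-wavelength intensity stacks to a HaemoStack.

    ``transform`` accepts a sequence of aligned single-wavelength arrays (or
    :class:`WavelengthStack` objects), computes each one's baseline from its
    first ``n_baseline_frames`` frames, converts to absorbance change and
    solves the least-squares system.

    Parameters
    ----------
    n_baseline_frames : int
        Frames from the stack start averaged into the baseline image
        (22 at the default 1.5 s baseline, 15 Hz per wavelength).
    table : ChromophoreTable or None
        Extinction/pathlength table; None uses the packaged defaults.
    printed_sign : bool
        Use the inverted absorbance ratio.
    """

    def __init__(self, n_baseline_frames: int = 22, table=None,
                 wavelengths_nm=(470.0, 530.0, 588.0, 627.0),
                 printed_sign: bool = False):
        self.n_baseline_frames = n_baseline_frames
        self.table = table
        self.wavelengths_nm = wavelengths_nm
        self.printed_sign = printed_sign

    def fit(self, X, y=None):
        table = self.table or ChromophoreTable.default()
        self.design_matrix_ = table.design_matrix(self.wavelengths_nm)
        return self

    def transform(self, X) -> HaemoStack:
        arrays = [x.data if isinstance(x, WavelengthStack) else np.asarray(x) for x in X]
        if len({a.shape for a in arrays}) != 1:
            raise ValueError("wavelength stacks must share one shape")
        da = np.stack([
            delta_absorbance(
                a, compute_baseline(a, slice(0, self.n_baseline_frames)),
                printed_sign=self.printed_sign,
            )
            for a in arrays
        ])
        table = self.table or ChromophoreTable.default()
        return unmix(da, table=table, wavelengths_nm=self.wavelengths_nm)
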