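"""Reading and writing image stacks and sidecar configs.

Stacks travel as multi-page TIFF in acquisition frame order with a YAML
sidecar recording the acquisition (and, for simulations, disturbance and
response) configs plus the seed, so any stack on disk can be re-interpreted
or re-generated bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from .config import AcquisitionConfig, DisturbanceConfig, ResponseConfig
from .stacks import RawStack, WavelengthStack

__all__ = [
    "write_raw_stack",
    "read_raw_stack",
    "write_wavelength_stack",
    "read_config",
    "write_config",
]


def write_config(path, acquisition: AcquisitionConfig,
                 disturbance: Optional[DisturbanceConfig] = None,
                 response: Optional[ResponseConfig] = None,
                 seed: Optional[int] = None, extra: Optional[dict] = None) -> None:
    doc = {"acquisition": acquisition.to_dict()}
    if disturbance is not None:
        doc["disturbance"] = disturbance.to_dict()
    if response is not None:
        doc["response"] = response.to_dict()
    if seed is not None:
        doc["seed"] = int(seed)
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path) -> dict:
    """Load a sidecar/run config; returns a dict with dataclass instances
    under 'acquisition'/'disturbance'/'response' where present."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    out = dict(doc)
    if "acquisition" in doc:
        out["acquisition"] = AcquisitionConfig.from_dict(doc["acquisition"])
    if "disturbance" in doc:
        out["disturbance"] = DisturbanceConfig.from_dict(doc["disturbance"])
    if "response" in doc:
        out["response"] = ResponseConfig.from_dict(doc["response"])
    return out


def write_raw_stack(path, raw: RawStack, sidecar: bool = True, **sidecar_kwargs) -> None:
    """Write frames in acquisition order as a multi-page TIFF; pages are
    (rows, cols) images.  A YAML sidecar <stem>.yaml records the configs."""
    path = Path(path)
    frames = np.moveaxis(raw.data, 2, 0)  # pages first for TIFF
    tifffile.imwrite(path, frames.astype(np.float32), photometric="minisblack")
    if sidecar:
        write_config(path.with_suffix(".yaml"), raw.acquisition, **sidecar_kwargs)


def read_raw_stack(path, acquisition: Optional[AcquisitionConfig] = None) -> RawStack:
    """Read a multi-page TIFF; the acquisition comes from the sidecar unless
    given explicitly."""
    path = Path(path)
    if acquisition is None:
        sidecar = path.with_suffix(".yaml")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no acquisition config: sidecar {sidecar} missing and none given"
            )
        acquisition = read_config(sidecar)["acquisition"]
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return RawStack(data=np.moveaxis(frames, 0, 2), acquisition=acquisition)


def write_wavelength_stack(path, ws: WavelengthStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(ws.data, 2, 0).astype(np.float32),
                     photometric="minisblack")
    meta = dict(wavelength_nm=ws.wavelength_nm,
                per_wavelength_rate_hz=ws.per_wavelength_rate_hz,
                frames_per_trial=ws.frames_per_trial, n_trials=ws.n_trials)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
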