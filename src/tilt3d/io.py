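"""Serialization: multi-page TIFF stacks with YAML sidecars, CSV tables.

Image stacks (PSF calibrations, simulated acquisitions) are written as
32-bit float or 16-bit integer multi-page TIFFs with a YAML sidecar of the
same stem recording the grid geometry (pixel size, z grid, wavelength,
NA).  Localization and track tables are plain CSV with documented headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from tilt3d import optics

__all__ = [
    "save_stack",
    "load_stack",
    "save_frames",
    "load_frames",
    "save_table",
    "load_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yaml")


def save_stack(path: str | Path, stack: optics.PSFStack, extra: dict | None = None) -> None:
    """Write a PSF z-stack as float32 TIFF + YAML metadata."""
    path = Path(path)
    tifffile.imwrite(path, stack.images.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "kind": "psf_stack",
        "pixel_nm": float(stack.pixel_nm),
        "z_um": [float(z) for z in stack.z_um],
    }
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(yaml.safe_dump(meta))


def load_stack(path: str | Path) -> optics.PSFStack:
    path = Path(path)
    images = tifffile.imread(path).astype(float)
    meta = yaml.safe_load(_sidecar(path).read_text())
    return optics.PSFStack(
        z_um=np.asarray(meta["z_um"], dtype=float),
        images=images,
        pixel_nm=float(meta["pixel_nm"]),
    )


def save_frames(path: str | Path, frames: np.ndarray, meta: dict | None = None) -> None:
    """Write an acquisition stack as uint16 TIFF + optional YAML metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.uint16),
                     photometric="minisblack")
    if meta is not None:
        _sidecar(path).write_text(yaml.safe_dump(meta))


def load_frames(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    frames = tifffile.imread(path)
    side = _sidecar(path)
    meta = yaml.safe_load(side.read_text()) if side.exists() else {}
    return frames, meta


def save_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write a localization/track table as CSV (nm units, see dhloc docs)."""
    table.to_csv(path, index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
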