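"""Readers and writers for the on-disk formats of the pipeline.

Decay and inversion-recovery series travel as two-column CSV
(``time_ms|time_s, signal``); voxel stacks either as wide CSV (one row
per voxel, columns named by echo time) or as NIfTI 3-D/4-D stacks with a
2-D/3-D ROI mask; histology as TIFF/PNG grayscale.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_decay_csv",
    "read_sir_csv",
    "read_voxels_csv",
    "read_nifti_stack",
    "read_image",
    "load_config",
]


def read_decay_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read (times_s, signal) from a ``time_ms,signal`` CSV."""
    d = pd.read_csv(path)
    if "time_ms" in d:
        t = d["time_ms"].to_numpy() / 1e3
    elif "time_s" in d:
        t = d["time_s"].to_numpy()
    else:
        raise ValueError(f"{path}: expected a time_ms or time_s column")
    return t, d["signal"].to_numpy(dtype=float)


read_sir_csv = read_decay_csv


def read_voxels_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read (times_s, signals[n_voxels, n_times]) from a wide CSV whose
    column names are echo times in ms."""
    d = pd.read_csv(path)
    t = np.array([float(c) for c in d.columns]) / 1e3
    return t, d.to_numpy(dtype=float)


def read_nifti_stack(
    image_path: str | Path, mask_path: str | Path
) -> np.ndarray:
    """Extract a (n_voxels, n_times) signal array from a 4-D (or 3-D with
    the last axis as time) NIfTI stack and a mask volume."""
    import nibabel as nib

    img = np.asanyarray(nib.load(str(image_path)).dataobj, dtype=float)
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    if img.ndim != mask.ndim + 1:
        raise ValueError("image must have one more (time) axis than the mask")
    return img[mask]


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG as float in [0, 1]."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = np.asarray(tifffile.imread(p), dtype=float)
    else:
        from skimage import io as skio

        img = np.asarray(skio.imread(p), dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if img.max() > 1.0:
        img = img / (255.0 if img.max() <= 255 else 65535.0)
    return img


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML run configuration."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    import json

    return json.loads(text)
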