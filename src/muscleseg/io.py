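"""NIfTI-1 readers/writers and cohort manifests.

Volumes are stored one channel per file with voxel spacing in the header
(diagonal affine). Axis convention matches the rest of the package:
in-plane axes first, slice axis last, 0-based indices.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .volumes import FatWaterVolume, MuscleLabelVolume

__all__ = [
    "read_channel",
    "read_fat_water",
    "read_labels",
    "write_channel",
    "write_fat_water",
    "write_labels",
]


def write_channel(data: np.ndarray, voxel_spacing, path: str | Path) -> Path:
    """Write one scalar 3D field as NIfTI-1 with spacing in the affine."""
    path = Path(path)
    affine = np.diag(list(voxel_spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(float(s) for s in voxel_spacing))
    nib.save(img, str(path))
    return path


def read_channel(path: str | Path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    """Read one 3D scalar field and its voxel spacing from a NIfTI file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: voxel spacing absent or non-positive in header: {zooms}")
    return data, tuple(float(z) for z in zooms)


def read_fat_water(
    water_path: str | Path, fat_path: str | Path, side_label: str = "bilateral"
) -> FatWaterVolume:
    water, sp_w = read_channel(water_path)
    fat, sp_f = read_channel(fat_path)
    if not np.allclose(sp_w, sp_f):
        raise ValueError(f"water/fat spacing mismatch: {sp_w} vs {sp_f}")
    return FatWaterVolume(water, fat, sp_w, side_label=side_label)


def write_fat_water(vol: FatWaterVolume, water_path: str | Path, fat_path: str | Path) -> None:
    write_channel(vol.water, vol.voxel_spacing, water_path)
    write_channel(vol.fat, vol.voxel_spacing, fat_path)


def read_labels(path: str | Path) -> MuscleLabelVolume:
    """Read a label volume; values are validated to {0..4}."""
    data, spacing = read_channel(path)
    if not np.all(data == np.round(data)):
        raise ValueError(f"{path}: label volume contains non-integer values")
    return MuscleLabelVolume(data.astype(np.int16), spacing)


def write_labels(labels: MuscleLabelVolume, path: str | Path) -> Path:
    return write_channel(labels.labels.astype(np.int16), labels.voxel_spacing, path)


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    return pd.read_csv(path)
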