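"""Core in-memory containers for fat-water MRI volumes and label maps.

Axis convention throughout the package: the first two axes are in-plane
(axial), the last axis is the slice (through-plane) axis. Voxel indices are
0-based. ``voxel_spacing`` is millimetres per axis in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

ROI_LABELS = (1, 2, 3, 4)
ROI_NAMES = {1: "quadriceps", 2: "sartorius", 3: "gracilis", 4: "hamstrings"}
SIDE_LABELS = ("left", "right", "bilateral")


@dataclass
class FatWaterVolume:
    """Co-registered 3D water and fat magnitude images.

    Both channels share one voxel grid and spacing; values are signal
    magnitudes and therefore non-negative.
    """

    water: np.ndarray
    fat: np.ndarray
    voxel_spacing: Tuple[float, float, float]
    side_label: str = "bilateral"

    def __post_init__(self) -> None:
        self.water = np.asarray(self.water, dtype=np.float64)
        self.fat = np.asarray(self.fat, dtype=np.float64)
        if self.water.ndim != 3 or self.fat.ndim != 3:
            raise ValueError("water and fat must be 3D arrays")
        if self.water.shape != self.fat.shape:
            raise ValueError(
                f"water shape {self.water.shape} != fat shape {self.fat.shape}"
            )
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be 3 positive floats, got {self.voxel_spacing}")
        if self.side_label not in SIDE_LABELS:
            raise ValueError(f"side_label must be one of {SIDE_LABELS}, got {self.side_label!r}")
        if np.any(self.water < 0) or np.any(self.fat < 0):
            raise ValueError("negative intensities: water/fat are signal magnitudes")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.water.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def copy(self) -> "FatWaterVolume":
        return replace(self, water=self.water.copy(), fat=self.fat.copy())


@dataclass
class MuscleLabelVolume:
    """Integer label field over a fat-water grid.

    Label semantics are fixed: 0 background, 1 quadriceps femoris (ROI1),
    2 sartorius (ROI2), 3 gracilis (ROI3), 4 hamstrings (ROI4).
    """

    labels: np.ndarray
    voxel_spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise ValueError("labels must be integer-valued")
            labels = labels.astype(np.int16)
        bad = np.setdiff1d(np.unique(labels), np.arange(5))
        if bad.size:
            raise ValueError(f"invalid label value(s) {bad.tolist()}: labels must be in 0..4")
        self.labels = labels.astype(np.int16)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def roi_mask(self, roi: int) -> np.ndarray:
        if roi not in ROI_LABELS:
            raise ValueError(f"roi must be in {ROI_LABELS}, got {roi}")
        return self.labels == roi

    def copy(self) -> "MuscleLabelVolume":
        return replace(self, labels=self.labels.copy())


@dataclass
class FatFractionMap:
    """Per-voxel fat fraction fat/(water+fat) with an undefined-voxel mask.

    ``defined`` marks voxels with water + fat > 0; elsewhere the fat fraction
    carries no information and ``ff`` is stored as 0 but must not be read.
    """

    ff: np.ndarray
    defined: np.ndarray
    voxel_spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.ff = np.asarray(self.ff, dtype=np.float64)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.ff.shape != self.defined.shape:
            raise ValueError("ff and defined must share one grid")
        d = self.ff[self.defined]
        if d.size and (d.min() < 0 or d.max() > 1):
            raise ValueError("fat fraction outside [0,1] on defined voxels")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)


def check_same_grid(a, b) -> None:
    """Raise if two volume-like objects differ in shape or spacing."""
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: shapes {a.shape} vs {b.shape}")
    sa = getattr(a, "voxel_spacing", None)
    sb = getattr(b, "voxel_spacing", None)
    if sa is not None and sb is not None and not np.allclose(sa, sb):
        raise ValueError(f"grid mismatch: spacings {sa} vs {sb}")
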