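"""Preprocessing: thigh splitting and automatic subcutaneous fat/skin removal.

The muscle-region mask is derived from the water image alone, in three steps:

1. K-means clustering (k = 2 by default) of the nonzero water intensities of
   the whole volume; the cluster with the highest centroid is kept. On water
   images subcutaneous fat is dark (its signal lives in the fat channel), so
   this step removes the fat ring.
2. An order-statistic (rank) filter applied slice-wise to the binary mask
   strips the thin residual skin/boundary rim: a voxel survives only if
   enough of its in-plane neighbourhood is inside the mask.
3. Slice-wise binary hole filling (the bone region and any interior
   dropouts are restored) followed by an in-plane dilation to recover muscle
   voxels eroded by step 2.

All three steps are parameterized by :class:`PreprocessConfig` and seeded,
so the pipeline is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .volumes import FatWaterVolume, check_same_grid

__all__ = [
    "PreprocessConfig",
    "MuscleRegionMask",
    "split_thighs",
    "muscle_mask_from_water",
    "apply_mask",
]


@dataclass
class PreprocessConfig:
    kmeans_clusters: int = 2
    kmeans_seed: int = 0
    ostat_window: Tuple[int, int] = (5, 5)  # in-plane window (odd per axis)
    ostat_rank: int = 7  # 0-based ascending rank within the window
    dilation_radius: int = 2  # in-plane disc radius, voxels
    split_axis: int = 1

    def __post_init__(self) -> None:
        if self.kmeans_clusters < 2:
            raise ValueError("kmeans_clusters must be >= 2")
        w = tuple(int(v) for v in self.ostat_window)
        if len(w) != 2 or any(v < 1 or v % 2 == 0 for v in w):
            raise ValueError(f"ostat_window must be two odd sizes, got {self.ostat_window}")
        self.ostat_window = w
        if not 0 <= self.ostat_rank < w[0] * w[1]:
            raise ValueError(f"ostat_rank {self.ostat_rank} outside window of {w[0] * w[1]} voxels")
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be >= 0")
        if self.split_axis not in (0, 1):
            raise ValueError("split_axis must be an in-plane axis (0 or 1)")


@dataclass
class MuscleRegionMask:
    """Binary muscle-region mask plus the provenance of how it was built."""

    mask: np.ndarray
    voxel_spacing: Tuple[float, float, float]
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self):
        return self.mask.shape


def split_thighs(
    vol: FatWaterVolume, cfg: PreprocessConfig | None = None
) -> Tuple[FatWaterVolume, FatWaterVolume]:
    """Split a bilateral volume into (left, right) thigh half-volumes.

    The in-plane extent along ``cfg.split_axis`` is partitioned at its
    midline; for an odd extent the extra column goes to the right half.
    Lower indices along the split axis are labelled "left", higher "right"
    (image-order convention, recorded in ``side_label``).

    An already-split volume is returned unchanged (twice) with a warning.
    """
    cfg = cfg or PreprocessConfig()
    if vol.side_label != "bilateral":
        warnings.warn(f"volume already split (side_label={vol.side_label!r}); no-op")
        return vol, vol
    ax = cfg.split_axis
    n = vol.shape[ax]
    m = n // 2
    sl_left = [slice(None)] * 3
    sl_right = [slice(None)] * 3
    sl_left[ax] = slice(0, m)
    sl_right[ax] = slice(m, n)
    left = FatWaterVolume(
        vol.water[tuple(sl_left)].copy(), vol.fat[tuple(sl_left)].copy(),
        vol.voxel_spacing, side_label="left",
    )
    right = FatWaterVolume(
        vol.water[tuple(sl_right)].copy(), vol.fat[tuple(sl_right)].copy(),
        vol.voxel_spacing, side_label="right",
    )
    return left, right


def split_labels(
    labels: "MuscleLabelVolume", cfg: PreprocessConfig | None = None
) -> Tuple["MuscleLabelVolume", "MuscleLabelVolume"]:
    """Split a bilateral label volume with the same midline convention as
    :func:`split_thighs` (extra column to the right half for odd extents)."""
    from .volumes import MuscleLabelVolume

    cfg = cfg or PreprocessConfig()
    ax = cfg.split_axis
    m = labels.shape[ax] // 2
    sl_left = [slice(None)] * 3
    sl_right = [slice(None)] * 3
    sl_left[ax] = slice(0, m)
    sl_right[ax] = slice(m, labels.shape[ax])
    return (
        MuscleLabelVolume(labels.labels[tuple(sl_left)].copy(), labels.voxel_spacing),
        MuscleLabelVolume(labels.labels[tuple(sl_right)].copy(), labels.voxel_spacing),
    )


def _kmeans_high_cluster(water: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Boolean mask of voxels in the highest-centroid K-means cluster."""
    nz = water > 0
    vals = water[nz].reshape(-1, 1)
    if vals.size == 0 or np.ptp(vals) == 0:
        raise ValueError("clustering-degenerate water field (constant or empty)")
    km = KMeans(
        n_clusters=cfg.kmeans_clusters, n_init=10, random_state=cfg.kmeans_seed
    ).fit(vals)
    high = int(np.argmax(km.cluster_centers_.ravel()))
    mask = np.zeros(water.shape, dtype=bool)
    mask[nz] = km.labels_ == high
    if not mask.any():
        raise ValueError("empty retained cluster after K-means step")
    return mask


def muscle_mask_from_water(water: np.ndarray, cfg: PreprocessConfig | None = None) -> MuscleRegionMask:
    """Derive the muscle-region mask from a water image.

    Pipeline: K-means keep-highest-cluster -> slice-wise rank filter ->
    slice-wise hole filling -> in-plane disc dilation. Raises on a constant
    water field or if any step empties the mask.
    """
    cfg = cfg or PreprocessConfig()
    water = np.asarray(water, dtype=np.float64)
    if water.ndim != 3:
        raise ValueError("water must be a 3D field")
    prov = []

    mask = _kmeans_high_cluster(water, cfg)
    prov.append(f"kmeans(k={cfg.kmeans_clusters}): kept {int(mask.sum())} voxels")

    # rank filter per axial slice: ascending rank r returns the (r+1)-th
    # smallest value; on a binary mask the output is 1 iff at least
    # (window_size - rank) neighbours are 1, eroding the thin skin rim.
    wy, wx = cfg.ostat_window
    filtered = np.empty_like(mask)
    for z in range(mask.shape[2]):
        filtered[:, :, z] = ndimage.rank_filter(
            mask[:, :, z].astype(np.uint8), rank=cfg.ostat_rank, size=(wy, wx)
        ).astype(bool)
    mask = filtered
    if not mask.any():
        raise ValueError("empty mask after order-statistic filtering step")
    prov.append(f"rank_filter(window={cfg.ostat_window}, rank={cfg.ostat_rank}): {int(mask.sum())} voxels")

    for z in range(mask.shape[2]):
        mask[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    prov.append(f"fill_holes: {int(mask.sum())} voxels")

    if cfg.dilation_radius > 0:
        disc = _disc(cfg.dilation_radius)
        for z in range(mask.shape[2]):
            mask[:, :, z] = ndimage.binary_dilation(mask[:, :, z], structure=disc)
    prov.append(f"dilation(radius={cfg.dilation_radius}): {int(mask.sum())} voxels")

    return MuscleRegionMask(mask, (1.0, 1.0, 1.0), provenance=prov)


def _disc(radius: int) -> np.ndarray:
    n = 2 * radius + 1
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return (y * y + x * x) <= radius * radius


def apply_mask(vol: FatWaterVolume, mask: MuscleRegionMask) -> FatWaterVolume:
    """Zero both channels outside the muscle-region mask."""
    if vol.shape != mask.shape:
        raise ValueError(f"grid mismatch: volume {vol.shape} vs mask {mask.shape}")
    m = mask.mask
    return FatWaterVolume(
        vol.water * m, vol.fat * m, vol.voxel_spacing, side_label=vol.side_label
    )
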