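"""Fat-fraction maps and per-ROI summary statistics.

The fat-fraction (FF) map is the voxel-wise ratio fat / (water + fat) of
the decomposed signal magnitudes; voxels with zero total signal carry no
fat fraction and are marked undefined rather than set to zero. Per-ROI
statistics report the mean FF in percent over defined ROI voxels and the
ROI volume from the voxel count and spacing.

FF must be computed on the original intensities: min-max normalization
(which is for the CNN only) does not preserve the fat/water ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .volumes import FatFractionMap, FatWaterVolume, MuscleLabelVolume, ROI_LABELS, check_same_grid

__all__ = ["RoiStats", "fat_fraction_map", "roi_stats", "roi_stats_table"]


@dataclass
class RoiStats:
    roi: int
    n_voxels: int
    volume_mm3: float
    mean_ff_percent: float  # NaN for an empty/all-undefined ROI
    n_undefined: int
    flagged: bool = False


def fat_fraction_map(vol: FatWaterVolume) -> FatFractionMap:
    """FF = fat / (water + fat) where the total signal is positive."""
    if np.any(vol.water < 0) or np.any(vol.fat < 0):
        raise ValueError("negative intensities: water/fat must be magnitudes")
    total = vol.water + vol.fat
    defined = total > 0
    ff = np.zeros_like(total)
    np.divide(vol.fat, total, out=ff, where=defined)
    return FatFractionMap(ff, defined, vol.voxel_spacing)


def roi_stats(ffmap: FatFractionMap, labels: MuscleLabelVolume, roi: int) -> RoiStats:
    """Mean FF (percent) and volume of one ROI.

    Undefined voxels are excluded from the mean and counted separately. An
    empty ROI (or one with no defined voxel) yields NaN meanFF and is
    flagged.
    """
    if roi not in ROI_LABELS:
        raise ValueError(f"roi must be in {ROI_LABELS}, got {roi}")
    check_same_grid(ffmap.ff, labels.labels)
    m = labels.labels == roi
    n_vox = int(m.sum())
    vol_mm3 = n_vox * labels.voxel_volume_mm3
    m_def = m & ffmap.defined
    n_undef = n_vox - int(m_def.sum())
    if m_def.any():
        mean_ff = float(ffmap.ff[m_def].mean() * 100.0)
        flagged = False
    else:
        mean_ff = float("nan")
        flagged = True
    return RoiStats(roi, n_vox, vol_mm3, mean_ff, n_undef, flagged)


def roi_stats_table(
    vol: FatWaterVolume, labels: MuscleLabelVolume, volume_id: str = ""
) -> pd.DataFrame:
    """Per-ROI stats of one volume as a tidy DataFrame."""
    ffmap = fat_fraction_map(vol)
    rows: List[dict] = []
    for roi in ROI_LABELS:
        s = roi_stats(ffmap, labels, roi)
        rows.append(
            {
                "volume_id": volume_id,
                "roi": s.roi,
                "n_voxels": s.n_voxels,
                "volume_mm3": s.volume_mm3,
                "mean_ff_percent": s.mean_ff_percent,
                "n_undefined": s.n_undefined,
            }
        )
    return pd.DataFrame(rows)
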