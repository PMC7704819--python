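"""Largest-3D-connected-component postprocessing of predicted label volumes.

Stacked 2D predictions can contain spurious islands; for each ROI only the
largest region in 3D is kept as the final automated mask. Connectivity is
voxel-topological (anisotropic spacing is ignored), default 26.
"""

from __future__ import annotations

import logging
from typing import Dict

import numpy as np
from scipy import ndimage

from .volumes import MuscleLabelVolume, ROI_LABELS

__all__ = ["keep_largest_component", "finalize"]

log = logging.getLogger(__name__)

_STRUCTS: Dict[int, np.ndarray] = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def keep_largest_component(
    labels: MuscleLabelVolume, roi: int, connectivity: int = 26
) -> MuscleLabelVolume:
    """Keep only the largest 3D connected component of one ROI.

    Other ROIs are untouched; voxels of ``roi`` outside its largest
    component become background. Size ties break to the component whose
    first voxel comes earliest in C-order raster scan. An empty ROI is
    returned unchanged (logged, not an error).
    """
    if roi not in ROI_LABELS:
        raise ValueError(f"roi must be in {ROI_LABELS}, got {roi}")
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
    mask = labels.labels == roi
    if not mask.any():
        log.info("ROI %d is empty; nothing to postprocess", roi)
        return labels.copy()
    comp, ncomp = ndimage.label(mask, structure=_STRUCTS[connectivity])
    if ncomp == 1:
        return labels.copy()
    sizes = np.bincount(comp.ravel())[1:]  # component ids 1..ncomp
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if best.size > 1:
        # size tie: keep the component whose seed voxel comes first in
        # C-order raster scan (smallest lexicographic coordinate)
        firsts = [int(np.argmax((comp == b).ravel())) for b in best]
        keep = int(best[int(np.argmin(firsts))])
    else:
        keep = int(best[0])
    out = labels.labels.copy()
    out[mask & (comp != keep)] = 0
    return MuscleLabelVolume(out, labels.voxel_spacing)


def finalize(labels: MuscleLabelVolume, connectivity: int = 26) -> MuscleLabelVolume:
    """Apply :func:`keep_largest_component` to every ROI.

    Idempotent; never increases any ROI's voxel count; every nonempty ROI
    of the result has exactly one 3D connected component.
    """
    out = labels
    for roi in ROI_LABELS:
        out = keep_largest_component(out, roi, connectivity)
    return out
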