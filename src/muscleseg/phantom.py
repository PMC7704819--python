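"""Synthetic bilateral-thigh fat-water phantoms with known ground truth.

The phantom emulates the statistical structure of an axial fat-water
decomposition (Dixon) acquisition of the mid-thigh: for each thigh a skin
ring, a subcutaneous fat ring, a muscle compartment holding four disjoint
muscle-group regions (quadriceps, sartorius, gracilis, hamstrings) arranged
as angular sectors, and a central bone. Geometry is analytic, with a linear
through-plane taper of the cross-section (thighs narrow towards the knee),
so ground-truth masks are exact at voxel resolution.

Signal model: every tissue class has a nominal total signal amplitude ``T``
and a fat fraction ``FF``; the noise-free channels are

    water = T * (1 - FF),    fat = T * FF,

so that fat / (water + fat) equals ``FF`` exactly at every voxel. Optional
i.i.d. Gaussian noise (standard deviation expressed as a fraction of the
nominal muscle amplitude) is added to both channels and clipped at zero,
mimicking magnitude images. No MR physics (echoes, T2*, chemical shift) is
simulated.

Subject repositioning between repeated scans is modelled as a small in-plane
rigid transform of the analytic geometry (the scene is re-rendered, not
resampled, so masks stay crisp and fat fractions exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .volumes import FatWaterVolume, MuscleLabelVolume, ROI_LABELS

__all__ = ["PhantomSpec", "CohortScan", "generate_phantom", "generate_cohort"]

# default per-ROI angular sectors (degrees, counter-clockwise, anterior = 0).
# Widths loosely follow relative muscle-group sizes: quadriceps and
# hamstrings large, sartorius and gracilis small, with 4 deg septa of
# unlabelled muscle between groups.
_DEFAULT_SECTORS = {1: (-68.0, 72.0), 2: (76.0, 121.0), 3: (125.0, 170.0), 4: (174.0, 288.0)}

_DEFAULT_INTENSITY = {"muscle": 100.0, "subcut_fat": 100.0, "skin": 30.0, "bone": 40.0}
_DEFAULT_TISSUE_FF = {"muscle_other": 0.10, "subcut_fat": 0.90, "skin": 0.20, "bone": 0.50}


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic scan.

    Lengths are millimetres. ``roi_geometry`` maps ROI label -> (theta_start,
    theta_end, r_inner, r_outer); if None, default sectors spanning the
    muscle annulus are derived from the radii. ``reposition_shift_mm`` /
    ``reposition_rot_deg`` encode the in-plane rigid placement of the thigh
    relative to the grid centre (used by :func:`generate_cohort` to emulate
    repositioning between repeated scans).
    """

    grid_shape: Tuple[int, int, int] = (64, 128, 12)
    voxel_spacing: Tuple[float, float, float] = (1.0, 1.0, 6.0)
    thigh_radius: float = 28.0
    skin_thickness: float = 2.0
    subcut_fat_thickness: float = 5.0
    bone_radius: float = 5.0
    roi_geometry: Optional[Dict[int, Tuple[float, float, float, float]]] = None
    roi_fat_fraction: Dict[int, float] = field(
        default_factory=lambda: {1: 0.10, 2: 0.10, 3: 0.10, 4: 0.10}
    )
    tissue_intensity: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_INTENSITY))
    tissue_fat_fraction: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_TISSUE_FF))
    noise_sigma: float = 0.0
    taper: float = 0.1  # fractional radius decrease from first to last slice
    seed: int = 0
    side: str = "bilateral"
    reposition_shift_mm: Tuple[float, float] = (0.0, 0.0)
    reposition_rot_deg: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def muscle_outer_radius(self) -> float:
        return self.thigh_radius - self.skin_thickness - self.subcut_fat_thickness

    def validate(self) -> None:
        for name in ("thigh_radius", "skin_thickness", "subcut_fat_thickness", "bone_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.muscle_outer_radius <= self.bone_radius:
            raise ValueError(
                "non-nested geometry: bone_radius "
                f"({self.bone_radius}) must be smaller than the muscle compartment outer "
                f"radius thigh_radius - skin_thickness - subcut_fat_thickness "
                f"({self.muscle_outer_radius})"
            )
        for roi, ff in self.roi_fat_fraction.items():
            if roi not in ROI_LABELS:
                raise ValueError(f"unknown ROI label {roi} in roi_fat_fraction")
            if not 0.0 <= ff <= 1.0:
                raise ValueError(f"roi_fat_fraction[{roi}] = {ff} outside [0,1]")
        if set(self.roi_fat_fraction) != set(ROI_LABELS):
            raise ValueError("roi_fat_fraction must specify all four ROIs")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.taper < 1.0:
            raise ValueError("taper must be in [0, 1)")
        if self.side not in ("bilateral", "left", "right"):
            raise ValueError(f"side must be bilateral/left/right, got {self.side!r}")
        if self.side == "bilateral" and self.grid_shape[1] % 2 != 0:
            raise ValueError("bilateral phantoms need an even in-plane extent on axis 1")
        geom = self.resolved_roi_geometry()
        for roi, (t0, t1, r0, r1) in geom.items():
            if not (0 < r0 < r1):
                raise ValueError(f"ROI {roi}: radial extent ({r0}, {r1}) must satisfy 0 < inner < outer")
        # pairwise disjointness of angular sectors (checked modulo 360)
        for a in ROI_LABELS:
            for b in ROI_LABELS:
                if a < b and _sectors_overlap(geom[a][:2], geom[b][:2]):
                    raise ValueError(f"ROI sectors {a} and {b} overlap")

    def resolved_roi_geometry(self) -> Dict[int, Tuple[float, float, float, float]]:
        if self.roi_geometry is not None:
            return self.roi_geometry
        r0 = self.bone_radius + 1.0
        r1 = self.muscle_outer_radius - 1.0
        return {roi: (t0, t1, r0, r1) for roi, (t0, t1) in _DEFAULT_SECTORS.items()}


@dataclass
class CohortScan:
    """One scan of a synthetic cohort, with its provenance."""

    volume: FatWaterVolume
    labels: MuscleLabelVolume
    subject_id: str
    repeat_id: int
    spec: PhantomSpec


def _sectors_overlap(a: Tuple[float, float], b: Tuple[float, float]) -> bool:
    def norm(t0, t1):
        t0m = t0 % 360.0
        return [(t0m, t0m + (t1 - t0))]

    for a0, a1 in norm(*a):
        for b0, b1 in norm(*b):
            for shift in (-360.0, 0.0, 360.0):
                if a0 < b1 + shift and b0 + shift < a1:
                    return True
    return False


def _in_sector(theta_deg: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Membership of angles (deg) in the CCW sector [t0, t1), any branch."""
    width = t1 - t0
    rel = (theta_deg - t0) % 360.0
    return rel < width


def _render_thigh(spec: PhantomSpec, shape2d: Tuple[int, int], scale: float = 1.0):
    """Render one thigh cross-section (noise-free water, fat, labels).

    ``scale`` multiplies every radius (the through-plane taper of the
    thigh); angular geometry is unchanged. Returns float64 water/fat planes
    and an int16 label plane.
    """
    nx, ny = shape2d
    sx, sy = spec.voxel_spacing[0], spec.voxel_spacing[1]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = (ix - cx) * sx - spec.reposition_shift_mm[0]
    y = (iy - cy) * sy - spec.reposition_shift_mm[1]
    th = np.deg2rad(spec.reposition_rot_deg)
    # rotate into the thigh frame
    xr = np.cos(th) * x + np.sin(th) * y
    yr = -np.sin(th) * x + np.cos(th) * y
    r = np.hypot(xr, yr)
    theta = np.rad2deg(np.arctan2(yr, xr))

    T = spec.tissue_intensity
    TF = spec.tissue_fat_fraction
    amp = np.zeros(shape2d)
    ff = np.zeros(shape2d)
    labels = np.zeros(shape2d, dtype=np.int16)

    inner = spec.muscle_outer_radius * scale
    outer = spec.thigh_radius * scale
    skin_in = (spec.thigh_radius - spec.skin_thickness) * scale
    bone_r = spec.bone_radius * scale
    masks = {
        "skin": (r <= outer) & (r > skin_in),
        "subcut_fat": (r <= skin_in) & (r > inner),
        "muscle": (r <= inner) & (r > bone_r),
        "bone": r <= bone_r,
    }
    for name, m in masks.items():
        amp[m] = T["muscle"] if name == "muscle" else T[name]
        ff[m] = TF["muscle_other"] if name == "muscle" else TF[name]

    for roi, (t0, t1, r0, r1) in spec.resolved_roi_geometry().items():
        m = masks["muscle"] & (r >= r0 * scale) & (r <= r1 * scale) & _in_sector(theta, t0, t1)
        labels[m] = roi
        ff[m] = spec.roi_fat_fraction[roi]

    water = amp * (1.0 - ff)
    fat = amp * ff
    return water, fat, labels


def generate_phantom(spec: PhantomSpec) -> Tuple[FatWaterVolume, MuscleLabelVolume]:
    """Generate one synthetic scan with its ground-truth label volume.

    For a bilateral spec the right thigh is the exact voxel-wise mirror of
    the left about the midline of axis 1 (before noise). With
    ``noise_sigma = 0`` the voxel-wise fat fraction inside ROI ``r`` equals
    ``spec.roi_fat_fraction[r]`` exactly.
    """
    spec.validate()
    nx, ny, nz = spec.grid_shape
    water = np.empty((nx, ny, nz))
    fat = np.empty((nx, ny, nz))
    labels = np.empty((nx, ny, nz), dtype=np.int16)
    for z in range(nz):
        # linear through-plane taper of the whole cross-section
        scale = 1.0 - spec.taper * (z / (nz - 1) if nz > 1 else 0.0)
        if spec.side == "bilateral":
            w2, f2, l2 = _render_thigh(spec, (nx, ny // 2), scale)
            water[:, :, z] = np.concatenate([w2, np.flip(w2, axis=1)], axis=1)
            fat[:, :, z] = np.concatenate([f2, np.flip(f2, axis=1)], axis=1)
            labels[:, :, z] = np.concatenate([l2, np.flip(l2, axis=1)], axis=1)
        else:
            water[:, :, z], fat[:, :, z], labels[:, :, z] = _render_thigh(
                spec, (nx, ny), scale
            )

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_sigma * spec.tissue_intensity["muscle"]
        water = np.clip(water + rng.normal(0.0, sigma, water.shape), 0.0, None)
        fat = np.clip(fat + rng.normal(0.0, sigma, fat.shape), 0.0, None)

    vol = FatWaterVolume(water, fat, spec.voxel_spacing, side_label=spec.side)
    return vol, MuscleLabelVolume(labels, spec.voxel_spacing)


def generate_cohort(
    n_subjects: int,
    repeats: int,
    spec_distribution: Optional[Dict[str, Tuple[float, float]]] = None,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
    reposition_shift_mm: float = 3.0,
    reposition_rot_deg: float = 5.0,
) -> List[CohortScan]:
    """Generate a cohort of subjects with repeated (repositioned) scans.

    Each subject draws its per-ROI fat fractions (and any scalar geometry
    fields listed in ``spec_distribution``) once; each repeat of that subject
    re-renders the same anatomy under a fresh small in-plane rigid transform
    (|shift| <= ``reposition_shift_mm`` per axis, |rotation| <=
    ``reposition_rot_deg``) with fresh noise, emulating repositioning
    between scans.

    ``spec_distribution`` maps PhantomSpec field names to (low, high) uniform
    ranges; the key ``"roi_fat_fraction"`` draws one value per ROI.
    """
    if n_subjects < 1 or repeats < 1:
        raise ValueError("n_subjects and repeats must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    dist = dict(spec_distribution or {})
    rng = np.random.default_rng(seed)

    scans: List[CohortScan] = []
    for s in range(n_subjects):
        overrides: Dict[str, object] = {}
        if "roi_fat_fraction" in dist:
            lo, hi = dist["roi_fat_fraction"]
            overrides["roi_fat_fraction"] = {roi: float(rng.uniform(lo, hi)) for roi in ROI_LABELS}
        for name, (lo, hi) in dist.items():
            if name == "roi_fat_fraction":
                continue
            overrides[name] = float(rng.uniform(lo, hi))
        subject_spec = replace(base, **overrides)
        subject_id = f"S{s:03d}"
        for rep in range(repeats):
            shift = (
                float(rng.uniform(-reposition_shift_mm, reposition_shift_mm)),
                float(rng.uniform(-reposition_shift_mm, reposition_shift_mm)),
            )
            rot = float(rng.uniform(-reposition_rot_deg, reposition_rot_deg))
            scan_seed = int(rng.integers(0, 2**31 - 1))
            scan_spec = replace(
                subject_spec,
                reposition_shift_mm=shift,
                reposition_rot_deg=rot,
                seed=scan_seed,
            )
            vol, labels = generate_phantom(scan_spec)
            scans.append(CohortScan(vol, labels, subject_id, rep, scan_spec))
    return scans
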