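"""Contrast-bolus volumetry from T1-weighted MRI volumes.

Both gadolinium-based (live imaging) and manganese-based (next-day
imaging) contrast agents appear hyperintense on T1, so the infusion
bolus is a bright connected blob over a darker tissue background. The
extraction here operationalizes the shrink-wrap workflow: place a
spherical region of interest over the bolus, threshold inside it at an
intensity below the bolus but above tissue, and keep the 26-connected
set of voxels reachable from the seed. Volume is the voxel count times
the voxel volume (mm³ ≡ µL), with anisotropic spacing respected and no
resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from cedphantom.errors import RangeError, SegmentationError, ValidationError
from cedphantom.calib_stats import Trajectory, TrajectoryPoint

__all__ = [
    "VolumeGrid",
    "RoiSpec",
    "BolusExtraction",
    "extract_bolus_volume",
    "scans_to_trajectory",
    "auto_threshold",
    "load_nifti",
    "save_mask_nifti",
]

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D intensity grid with per-axis voxel spacing in mm.

    ``acquisition_time`` is minutes since infusion start for live scans
    or the string "next-day" for delayed imaging.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    acquisition_time: Union[float, str, None] = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 3 or vals.size == 0:
            raise ValidationError(f"grid must be non-empty 3-D, got shape {vals.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive mm values, got {self.spacing}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume_ul(self) -> float:
        """Volume of one voxel in µL (= mm³)."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class RoiSpec:
    """Spherical region of interest: seed voxel, radius (mm), threshold."""

    center: tuple[int, int, int]
    radius: float
    threshold: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError(f"radius must be > 0 mm, got {self.radius}")


@dataclass(frozen=True)
class BolusExtraction:
    """Shrink-wrapped bolus mask and its voxel-count volume (µL)."""

    mask: np.ndarray
    volume: float
    threshold_used: float

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _sphere_mask(shape, spacing, center, radius) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    d2 = np.zeros(shape, dtype=float)
    for axis in range(3):
        d2 += ((idx[axis] - center[axis]) * spacing[axis]) ** 2
    return d2 <= radius * radius


def extract_bolus_volume(grid: VolumeGrid, roi: RoiSpec) -> BolusExtraction:
    """Threshold shrink-wrap within a spherical ROI, seeded at its center.

    The mask is the set of voxels inside the sphere with intensity
    ≥ threshold (seed-inclusive comparison) that are 26-connected to
    the seed; its volume is voxel count × voxel volume. Raising the
    threshold can only shrink the mask.

    Raises
    ------
    RangeError
        If the seed voxel lies outside the grid.
    SegmentationError
        If the seed intensity is below the threshold ("seed outside
        bolus").
    """
    shape = grid.values.shape
    cx, cy, cz = roi.center
    if not (0 <= cx < shape[0] and 0 <= cy < shape[1] and 0 <= cz < shape[2]):
        raise RangeError(f"ROI center {roi.center} outside grid of shape {shape}")
    if grid.values[cx, cy, cz] < roi.threshold:
        raise SegmentationError(
            f"seed outside bolus: intensity {grid.values[cx, cy, cz]:g} "
            f"< threshold {roi.threshold:g}"
        )
    sphere = _sphere_mask(shape, grid.spacing, roi.center, roi.radius)
    candidate = sphere & (grid.values >= roi.threshold)
    labels, _ = ndimage.label(candidate, structure=_STRUCTURE_26)
    mask = labels == labels[cx, cy, cz]
    return BolusExtraction(
        mask=mask,
        volume=float(mask.sum()) * grid.voxel_volume_ul,
        threshold_used=float(roi.threshold),
    )


def auto_threshold(grid: VolumeGrid, roi_center, roi_radius: float) -> float:
    """Midpoint of seed-neighbourhood mean and outside-sphere background mean.

    A convenience starting point; the manual, iteratively adjusted
    threshold remains the primary interface.
    """
    sphere = _sphere_mask(grid.values.shape, grid.spacing, roi_center, roi_radius)
    if not sphere.any() or sphere.all():
        raise ValidationError("ROI sphere must cover part of the grid, not all of it")
    inner = _sphere_mask(grid.values.shape, grid.spacing, roi_center, roi_radius / 4.0)
    seed_mean = grid.values[inner].mean() if inner.any() else grid.values[tuple(roi_center)]
    background_mean = grid.values[~sphere].mean()
    return float((seed_mean + background_mean) / 2.0)


def scans_to_trajectory(
    extractions: Sequence[tuple[BolusExtraction, float]],
    trial_id: str,
    region: str,
    times: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Assemble successive in-trial scans into an NHP volume trajectory.

    ``extractions`` pairs each scan's extraction with its infused
    volume (µL); infused volumes must be non-decreasing. ``times`` are
    optional acquisition times in minutes (NaN when unknown, e.g. a
    single next-day scan).
    """
    infused = [float(v) for _, v in extractions]
    if any(a > b for a, b in zip(infused, infused[1:])):
        raise ValidationError("infused volumes must be non-decreasing across scans")
    if times is None:
        times = [np.nan] * len(extractions)
    if len(times) != len(extractions):
        raise ValidationError("times and extractions length mismatch")
    points = tuple(
        TrajectoryPoint(time_min=float(t), infused_ul=v, measured_ul=ext.volume)
        for (ext, v), t in zip(extractions, times)
    )
    return Trajectory(trial_id=trial_id, group="nhp", region=region, points=points)


def load_nifti(path, acquisition_time=None) -> VolumeGrid:
    """Read a .nii/.nii.gz volume; spacing taken from the header zooms."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(values=data, spacing=spacing, acquisition_time=acquisition_time)


def save_mask_nifti(extraction: BolusExtraction, grid: VolumeGrid, path) -> None:
    """Write the bolus mask as NIfTI with the grid's voxel spacing."""
    import nibabel as nib

    affine = np.diag(list(grid.spacing) + [1.0])
    img = nib.Nifti1Image(extraction.mask.astype(np.uint8), affine)
    nib.save(img, str(path))
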