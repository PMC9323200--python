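"""Dye-bolus segmentation from agar-phantom photographs.

The processing chain mirrors a bench imaging workflow: a single 8-bit
color component is pulled from each RGB photograph, thresholded into a
binary mask, the connected cluster covering the bolus is isolated, any
cannula pixels merged with it are erased above a user-chosen row, and
the bolus extents are converted to a volume by assuming an ellipsoid
that is radially symmetric about the (vertical) cannula axis:

    v = (π/6) · h · w²

with h the extent along the cannula, w the extent perpendicular to it,
both in mm (1 mm³ ≡ 1 µL). Yellow dye absorbs blue light and, at high
concentration, depresses green, so bolus pixels are *low* in the chosen
channel; the default threshold direction is therefore ``below``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from cedphantom.errors import RangeError, SegmentationError, ValidationError
from cedphantom.protocols import InfusionProtocol, cumulative_volume
from cedphantom.calib_stats import Trajectory, TrajectoryPoint

__all__ = [
    "ImageRaster",
    "IntensityPlane",
    "BinaryMask",
    "SegmentationParams",
    "BolusMeasurement",
    "extract_component",
    "threshold_mask",
    "select_bolus_cluster",
    "erase_cannula",
    "measure_bolus",
    "segment_series",
    "ellipsoid_volume",
    "read_image",
]

_COMPONENTS = {"red": 0, "green": 1, "blue": 2}

#: 8-connectivity: robust to 1-px diagonal gaps along thresholded dye edges.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ImageRaster:
    """A 24-bit RGB photograph, channels ordered red, green, blue.

    ``capture_time`` is minutes since infusion start (None if unknown).
    """

    pixels: np.ndarray
    capture_time: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(
                f"image must be H×W×3, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class IntensityPlane:
    """One 8-bit value per pixel, extracted from a named color component."""

    values: np.ndarray
    source_component: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BinaryMask:
    """Boolean segmentation mask with a provenance trail of applied steps."""

    bits: np.ndarray
    provenance: tuple[str, ...] = field(default_factory=tuple)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape

    @property
    def count(self) -> int:
        return int(self.bits.sum())

    def with_step(self, bits: np.ndarray, step: str) -> "BinaryMask":
        return BinaryMask(bits=bits, provenance=self.provenance + (step,))


@dataclass(frozen=True)
class SegmentationParams:
    """Everything needed to segment one infusion series.

    Parameters
    ----------
    component : {"red", "green", "blue"}
        Color component used for thresholding.
    threshold : int
        8-bit threshold, 0–255. Ties are excluded in both directions.
    direction : {"below", "above"}
        Which side of the threshold is dye. Default ``below`` (yellow
        dye darkens the blue/green channels).
    cut_row : int or None
        Row index above which (smaller row = image top) marked pixels
        are erased as cannula; None disables erasure.
    scale : float
        Pixels per mm, measured from the in-frame ruler; > 0.
    """

    component: str = "blue"
    threshold: int = 67
    direction: str = "below"
    cut_row: Optional[int] = None
    scale: float = 10.0

    def __post_init__(self) -> None:
        if self.component not in _COMPONENTS:
            raise ValidationError(f"unknown component {self.component!r}")
        if not (0 <= int(self.threshold) <= 255):
            raise RangeError(f"threshold {self.threshold} outside [0, 255]")
        if self.direction not in ("below", "above"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class BolusMeasurement:
    """Bolus extents and the ellipsoid volume derived from them.

    h, w in mm; v in µL; v = (π/6)·h·w².
    """

    h: float
    w: float
    v: float
    capture_time: Optional[float] = None


def ellipsoid_volume(h: float, w: float) -> float:
    """Volume (µL) of an ellipsoid radially symmetric about its h-axis.

    Equivalent to the closed form (4/3)π·a·b² with semi-axes a = h/2,
    b = w/2.
    """
    return pi / 6.0 * h * w * w


def read_image(path, capture_time: Optional[float] = None) -> ImageRaster:
    """Load an 8-bit RGB PNG/TIFF photograph."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return ImageRaster(pixels=arr, capture_time=capture_time)


def extract_component(image: ImageRaster, component: str) -> IntensityPlane:
    """Pull one color channel, values untouched (no luminance mixing)."""
    try:
        idx = _COMPONENTS[component]
    except KeyError:
        raise ValidationError(
            f"unknown component {component!r}; choose red, green or blue"
        ) from None
    return IntensityPlane(
        values=image.pixels[:, :, idx].copy(), source_component=component
    )


def threshold_mask(
    plane: IntensityPlane, threshold: int, direction: str = "below"
) -> BinaryMask:
    """Binarize a plane by a strict 8-bit threshold.

    ``below`` marks value < threshold, ``above`` marks value >
    threshold; pixels exactly at the threshold are excluded either way,
    so calibration grids are reproducible.
    """
    if not (0 <= threshold <= 255):
        raise RangeError(f"threshold {threshold} outside [0, 255]")
    if direction == "below":
        bits = plane.values < threshold
    elif direction == "above":
        bits = plane.values > threshold
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    return BinaryMask(
        bits=bits,
        provenance=(f"threshold[{plane.source_component}{'<' if direction == 'below' else '>'}{threshold}]",),
    )


def select_bolus_cluster(
    mask: BinaryMask, seed: Optional[tuple[int, int]] = None
) -> BinaryMask:
    """Keep one 8-connected cluster and erase every other one.

    With a ``seed`` (row, col) the cluster containing it is kept;
    without one, the largest cluster by pixel count is kept.
    """
    if mask.count == 0:
        raise SegmentationError("mask is empty: no cluster to select")
    labels, n = ndimage.label(mask.bits, structure=_STRUCTURE_8)
    if seed is not None:
        row, col = seed
        if not (0 <= row < mask.shape[0] and 0 <= col < mask.shape[1]):
            raise RangeError(f"seed {seed} outside image {mask.shape}")
        target = labels[row, col]
        if target == 0:
            raise SegmentationError(f"seed {seed} lies on an unmarked pixel")
    else:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        target = int(counts.argmax())
    return mask.with_step(labels == target, f"select_cluster[{'seed' if seed else 'largest'}]")


def erase_cannula(mask: BinaryMask, cut_row: int) -> BinaryMask:
    """Clear all marked pixels strictly above ``cut_row`` (image top).

    Row 0 is the top of the image; rows ``>= cut_row`` are untouched.
    ``cut_row`` may equal H (everything cleared, degenerate bound).
    """
    h = mask.shape[0]
    if not (0 <= cut_row <= h):
        raise RangeError(f"cut_row {cut_row} outside [0, {h}]")
    bits = mask.bits.copy()
    bits[:cut_row, :] = False
    return mask.with_step(bits, f"erase_cannula[row<{cut_row}]")


def measure_bolus(
    mask: BinaryMask, scale: float, capture_time: Optional[float] = None
) -> BolusMeasurement:
    """Convert a bolus mask to physical extents and an ellipsoid volume.

    h = row extent of the marked pixels / scale, w = column extent /
    scale (axis-aligned bounding extents, in pixels spanned); an empty
    mask measures h = w = v = 0.
    """
    if scale <= 0:
        raise ValidationError(f"scale must be > 0, got {scale}")
    rows, cols = np.nonzero(mask.bits)
    if rows.size == 0:
        return BolusMeasurement(0.0, 0.0, 0.0, capture_time)
    h = float(rows.max() - rows.min() + 1) / scale
    w = float(cols.max() - cols.min() + 1) / scale
    return BolusMeasurement(h=h, w=w, v=ellipsoid_volume(h, w), capture_time=capture_time)


def segment_frame(
    image: ImageRaster,
    params: SegmentationParams,
    seed: Optional[tuple[int, int]] = None,
) -> BolusMeasurement:
    """Run the full single-frame chain and measure the bolus."""
    plane = extract_component(image, params.component)
    mask = threshold_mask(plane, params.threshold, params.direction)
    mask = select_bolus_cluster(mask, seed=seed)
    if params.cut_row is not None:
        mask = erase_cannula(mask, params.cut_row)
    return measure_bolus(mask, params.scale, image.capture_time)


def segment_series(
    frames: Sequence[ImageRaster],
    params: SegmentationParams,
    protocol: InfusionProtocol,
    trial_id: str = "agar",
    region: str = "cortical",
) -> Trajectory:
    """Segment a timed photo series into a volume trajectory.

    Each frame runs the chain extract → threshold → cluster select →
    cannula erasure → measure; the measured volume is paired with the
    protocol's cumulative infused volume at the capture time (clamped
    at the total for post-infusion frames). Frames where no cluster is
    found become missing points rather than aborting the series — early
    diffusion frames often have no identifiable bolus.
    """
    times = [f.capture_time for f in frames]
    if any(t is None for t in times):
        raise ValidationError("every frame in a series needs a capture_time")
    if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
        raise ValidationError("frames must be sorted by capture_time")
    total_time = protocol.total_time
    points = []
    for frame in frames:
        t = float(frame.capture_time)
        infused = cumulative_volume(protocol, min(t, total_time))
        try:
            meas = segment_frame(frame, params)
            measured = meas.v
        except SegmentationError:
            measured = np.nan
        points.append(TrajectoryPoint(time_min=t, infused_ul=infused, measured_ul=measured))
    return Trajectory(trial_id=trial_id, group="agar", region=region, points=tuple(points))
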