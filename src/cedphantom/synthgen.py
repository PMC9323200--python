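"""Synthetic phantom photographs, MRI grids and trajectory sets.

No raw study images are distributed, so every pipeline stage is
exercised against generated data with known ground truth: a bench
scene (white backdrop, agar block, vertical cannula, millimetre ruler
ticks, yellow dye bolus with radial concentration falloff), a 3-D
contrast bolus of elevated intensity over tissue background, and
per-trial linear volume trajectories with normally distributed random
slopes. All generators are deterministic given their seed.

The dye rendering depresses the blue channel most strongly — yellow
dye absorbs blue — and the green channel in proportion to simulated
concentration, so blue is the natural segmentation channel for
high-contrast (cortical-style) frames and green tracks concentration
as in deeper infusions. Post-infusion bolus growth uses a saturating
exponential, a stand-in with the right qualitative behaviour
(diffusion keeps growing the bolus in agar after pumping stops), not a
physical diffusion solver.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import pi
from typing import Optional

import numpy as np

from cedphantom.errors import ValidationError
from cedphantom.photo_seg import ImageRaster, ellipsoid_volume
from cedphantom.protocols import InfusionProtocol, cumulative_volume
from cedphantom.mri_vol import VolumeGrid
from cedphantom.calib_stats import Trajectory, TrajectoryPoint

__all__ = [
    "PhotoTruth",
    "MriTruth",
    "make_photo_frame",
    "make_photo_series",
    "make_mri_volume",
    "make_trajectories",
]


@dataclass(frozen=True)
class PhotoTruth:
    """Ground truth for one rendered phantom photograph.

    ``h_true``/``w_true`` are the bolus extents (mm) along and across
    the cannula axis; the implied volume is (π/6)·h·w². ``tip`` is the
    (row, col) pixel of the cannula tip; the bolus hangs below it.
    Colors are 8-bit RGB triples; ``noise_sd`` is the per-channel
    Gaussian noise level in intensity units.
    """

    h_true: float = 6.0
    w_true: float = 3.0
    tip: tuple[int, int] = (60, 120)
    scale: float = 10.0
    dye_color: tuple[int, int, int] = (235, 200, 8)
    agar_color: tuple[int, int, int] = (244, 246, 247)
    backdrop_color: tuple[int, int, int] = (255, 255, 255)
    noise_sd: float = 0.0
    seed: int = 0
    frame_shape: tuple[int, int] = (320, 240)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError("scale must be > 0 px/mm")
        if self.h_true < 0 or self.w_true < 0:
            raise ValidationError("bolus extents must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    @property
    def v_true(self) -> float:
        """Ground-truth ellipsoid volume, µL."""
        return ellipsoid_volume(self.h_true, self.w_true)


@dataclass(frozen=True)
class MriTruth:
    """Ground truth for one synthetic contrast-bolus volume.

    ``center`` and ``semi_axes`` are in mm (grid coordinates =
    voxel index × spacing); analytic volume is (4/3)π·a·b·c.
    """

    center: tuple[float, float, float] = (16.0, 16.0, 16.0)
    semi_axes: tuple[float, float, float] = (4.0, 4.0, 6.0)
    bolus_intensity: float = 200.0
    background_intensity: float = 100.0
    noise_sd: float = 0.0
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if any(a < 0 for a in self.semi_axes):
            raise ValidationError("semi-axes must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    @property
    def v_true(self) -> float:
        """Analytic ellipsoid volume, µL."""
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * pi * a * b * c


def make_photo_frame(truth: PhotoTruth) -> ImageRaster:
    """Render one bench-scene photograph from ground truth.

    The scene: backdrop, agar block, vertical cannula line ending at
    ``tip``, ruler ticks at 1 mm spacing along the left edge, and a
    dye ellipse of extents (h·scale, w·scale) centred below the tip.
    Dye opacity falls off radially as 0.3 + 0.7·(1 − r²)^¼ —
    near-saturated over most of the bolus, thinning toward the rim but
    keeping the sharp optical edge that concentrated food coloring
    shows against clear gel. Zero-mean Gaussian noise with
    ``noise_sd`` is added per channel. Deterministic given the seed.
    """
    H, W = truth.frame_shape
    tip_row, tip_col = truth.tip
    h_px = truth.h_true * truth.scale
    w_px = truth.w_true * truth.scale
    if h_px > 0 and (
        tip_row + h_px >= H
        or tip_col - w_px / 2 < 0
        or tip_col + w_px / 2 >= W
    ):
        raise ValidationError(
            f"bolus of {truth.h_true}×{truth.w_true} mm at scale "
            f"{truth.scale} px/mm extends outside the {H}×{W} frame"
        )

    img = np.empty((H, W, 3), dtype=float)
    img[:] = truth.backdrop_color

    # agar block: cannula inserted ~2 mm deep, block reaches near frame bottom
    agar_top = max(0, int(tip_row - 2 * truth.scale))
    agar_left, agar_right = 16, W - 6
    img[agar_top: H - 4, agar_left:agar_right] = truth.agar_color

    # ruler: vertical bar with dark ticks every scale px (1 mm)
    img[4: H - 4, 2:7] = (230, 230, 228)
    for r in range(4, H - 4, max(1, int(round(truth.scale)))):
        img[r, 2:7] = (30, 30, 30)

    # cannula: 2-px dark vertical line from frame top to the tip
    img[: tip_row + 1, tip_col: tip_col + 2] = (40, 40, 40)

    if h_px >= 1 and w_px >= 1:
        # centers offset by half a pixel so the rasterized spans equal
        # h_px and w_px pixel counts (bolus top row = tip row)
        c_row = tip_row - 0.5 + h_px / 2.0
        c_col = tip_col + 0.5
        rows = np.arange(H, dtype=float)[:, None]
        cols = np.arange(W, dtype=float)[None, :]
        r2 = ((rows - c_row) / (h_px / 2.0)) ** 2 + ((cols - c_col) / (w_px / 2.0)) ** 2
        inside = r2 <= 1.0
        alpha = np.zeros((H, W))
        alpha[inside] = 0.3 + 0.7 * (1.0 - r2[inside]) ** 0.25
        dye = np.asarray(truth.dye_color, dtype=float)
        img = alpha[:, :, None] * dye[None, None, :] + (1.0 - alpha[:, :, None]) * img

    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        img = img + rng.normal(0.0, truth.noise_sd, size=img.shape)

    return ImageRaster(pixels=np.clip(np.round(img), 0, 255).astype(np.uint8))


def _extents_from_volume(v: float) -> tuple[float, float]:
    """Invert v = (π/6)·h·w² under the fixed aspect ratio h = 2w."""
    if v <= 0:
        return 0.0, 0.0
    w = (3.0 * v / pi) ** (1.0 / 3.0)
    return 2.0 * w, w


def make_photo_series(
    protocol: InfusionProtocol,
    slope_true: float,
    frame_interval: float,
    diffusion_tau: Optional[float] = None,
    truth: Optional[PhotoTruth] = None,
    post_duration: float = 0.0,
) -> list[tuple[ImageRaster, PhotoTruth]]:
    """Render a timed infusion series with known Vd/Vi slope.

    During infusion the true bolus volume is slope_true × cumulative
    infused volume. After infusion end (t′ = t − T), if
    ``diffusion_tau`` is set, the volume keeps growing as
    v_end·(2 − e^(−t′/τ)), saturating at twice the end-of-infusion
    volume; ``post_duration`` minutes of post-infusion frames are
    rendered at the same interval. Extents follow the fixed aspect
    ratio h = 2w. Each frame carries its capture time.
    """
    if slope_true <= 0:
        raise ValidationError("slope_true must be > 0")
    if frame_interval <= 0:
        raise ValidationError("frame_interval must be > 0")
    if truth is None:
        truth = PhotoTruth()
    total_time = protocol.total_time
    end = total_time + (post_duration if diffusion_tau is not None else 0.0)
    times = np.arange(0.0, end + 1e-9, frame_interval)
    if times[-1] < total_time:
        times = np.append(times, total_time)
    v_end = slope_true * protocol.total_volume

    out = []
    for i, t in enumerate(times):
        if t <= total_time:
            v = slope_true * cumulative_volume(protocol, float(t))
        else:
            v = min(v_end * (2.0 - np.exp(-(t - total_time) / diffusion_tau)), 2.0 * v_end)
        h, w = _extents_from_volume(v)
        frame_truth = replace(truth, h_true=h, w_true=w, seed=truth.seed + i)
        frame = make_photo_frame(frame_truth)
        out.append((ImageRaster(frame.pixels, capture_time=float(t)), frame_truth))
    return out


def make_mri_volume(truth: MriTruth) -> VolumeGrid:
    """Voxelize an ellipsoidal contrast bolus over tissue background.

    Voxels whose centres (index × spacing) fall inside the ellipsoid
    get ``bolus_intensity``; all others ``background_intensity``;
    zero-mean Gaussian noise is added on top. Deterministic given the
    seed.
    """
    shape = truth.grid_shape
    extent = [(n - 1) * s for n, s in zip(shape, truth.spacing)]
    for c, a, e in zip(truth.center, truth.semi_axes, extent):
        if a > 0 and (c - a < 0 or c + a > e):
            raise ValidationError(
                f"ellipsoid (center {truth.center} mm, semi-axes {truth.semi_axes} mm) "
                f"extends outside the grid extent {extent} mm"
            )
    coords = [np.arange(n, dtype=float) * s for n, s in zip(shape, truth.spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    values = np.full(shape, float(truth.background_intensity))
    if all(a > 0 for a in truth.semi_axes):
        a, b, c = truth.semi_axes
        inside = (
            ((xx - truth.center[0]) / a) ** 2
            + ((yy - truth.center[1]) / b) ** 2
            + ((zz - truth.center[2]) / c) ** 2
        ) <= 1.0
        values[inside] = float(truth.bolus_intensity)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        values = values + rng.normal(0.0, truth.noise_sd, size=shape)
    return VolumeGrid(values=values, spacing=truth.spacing)


def make_trajectories(
    n_per_group: tuple[int, int],
    group_slopes: tuple[float, float],
    slope_sd: float = 0.3,
    noise_sd: float = 2.0,
    n_points: int = 20,
    seed: int = 0,
    infused_max: float = 50.0,
    region: str = "cortical",
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Simulate (agar, nhp) trial sets with random per-trial slopes.

    Each trial draws its Vd/Vi slope from Normal(group mean, slope_sd)
    and observes measured = slope × infused + Normal(0, noise_sd) on an
    evenly spaced infused-volume grid up to ``infused_max`` µL
    (negative draws are floored at zero). Deterministic given the seed.
    """
    n_agar, n_nhp = n_per_group
    if n_agar < 1 or n_nhp < 1:
        raise ValidationError("need at least one trial per group")
    if slope_sd < 0 or noise_sd < 0:
        raise ValidationError("standard deviations must be non-negative")
    if n_points < 1:
        raise ValidationError("need at least one point per trial")
    rng = np.random.default_rng(seed)
    infused = np.linspace(infused_max / n_points, infused_max, n_points)
    times = np.arange(1, n_points + 1, dtype=float)

    def simulate(group: str, n: int, mean_slope: float) -> list[Trajectory]:
        trials = []
        for i in range(n):
            slope = rng.normal(mean_slope, slope_sd) if slope_sd > 0 else mean_slope
            noise = rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else 0.0
            measured = np.maximum(slope * infused + noise, 0.0)
            points = tuple(
                TrajectoryPoint(float(t), float(x), float(y))
                for t, x, y in zip(times, infused, measured)
            )
            trials.append(Trajectory(f"{group}{i + 1:02d}", group, region, points))
        return trials

    agar = simulate("agar", n_agar, group_slopes[0])
    nhp = simulate("nhp", n_nhp, group_slopes[1])
    return agar, nhp
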