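"""Statistical calibration of the agar phantom against in vivo data.

The central quantity is the Vd/Vi slope: the ratio of measured
distribution volume to infused volume, estimated per trial by a
least-squares line restricted to pass through the origin (zero in,
zero out). Groups of trials (agar bench runs vs non-human-primate
MRI runs) are compared with a linear mixed-effects model with random
slopes and no intercepts; its group-by-infused interaction coefficient
approximates the difference in average slope between the groups, and
driving |interaction| to a grid minimum is how the segmentation
threshold and color component are calibrated.

Also here: the single-pass 1.1× noise filter for small-volume series,
diffusion-time matching of post-infusion bolus growth against a
reference mean, percent error, and the pooled two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from cedphantom.errors import (
    CalibrationError,
    FitError,
    RangeError,
    ValidationError,
)

__all__ = [
    "Trajectory",
    "TrajectoryPoint",
    "MixedFit",
    "CalibrationResult",
    "DiffusionMatch",
    "slope_through_origin",
    "filter_noise",
    "fit_mixed_model",
    "calibrate_segmentation",
    "match_diffusion",
    "percent_error",
    "pooled_t_test",
    "threshold_as_percent",
]

GROUPS = ("agar", "nhp")
REGIONS = ("cortical", "thalamic", "mtl")


@dataclass(frozen=True)
class TrajectoryPoint:
    """One observation: time (min), infused volume and measured bolus volume (µL).

    ``measured_ul`` may be NaN for frames where no bolus was found.
    """

    time_min: float
    infused_ul: float
    measured_ul: float

    @property
    def usable(self) -> bool:
        return np.isfinite(self.measured_ul)


@dataclass(frozen=True)
class Trajectory:
    """One infusion trial's series of (time, infused, measured) points."""

    trial_id: str
    group: str
    region: str
    points: tuple[TrajectoryPoint, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"trial {self.trial_id!r}: unknown group {self.group!r}"
            )
        if self.region not in REGIONS:
            raise ValidationError(
                f"trial {self.trial_id!r}: unknown region {self.region!r}"
            )
        infused = [p.infused_ul for p in self.points]
        if any(v < 0 for v in infused):
            raise ValidationError(f"trial {self.trial_id!r}: negative infused volume")
        if any(a > b for a, b in zip(infused, infused[1:])):
            raise ValidationError(
                f"trial {self.trial_id!r}: infused volumes must be non-decreasing"
            )
        if any(p.measured_ul < 0 for p in self.points if p.usable):
            raise ValidationError(f"trial {self.trial_id!r}: negative measured volume")

    @property
    def usable_points(self) -> tuple[TrajectoryPoint, ...]:
        return tuple(p for p in self.points if p.usable)

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """(infused, measured) arrays over usable points."""
        pts = self.usable_points
        return (
            np.array([p.infused_ul for p in pts], dtype=float),
            np.array([p.measured_ul for p in pts], dtype=float),
        )


@dataclass(frozen=True)
class MixedFit:
    """A fitted through-origin random-slope model comparing two groups.

    ``base_slope`` is the reference-group mean Vd/Vi slope;
    ``interaction`` is the non-reference minus reference mean slope
    (µL/µL) with standard error ``interaction_se``. ``trial_slopes``
    are per-trial fitted slopes (fixed effect + predicted random
    effect). ``method`` records whether the mixed model converged or
    the per-trial-slope fallback was used.
    """

    base_slope: float
    interaction: float
    interaction_se: float
    trial_slopes: dict
    reference_group: str
    method: str = "mixed"


@dataclass(frozen=True)
class CalibrationResult:
    """Winning point of a segmentation-calibration grid search."""

    component: str
    threshold: int
    objective: float
    slope_table: dict
    grid: tuple = ()


@dataclass(frozen=True)
class DiffusionMatch:
    """Post-infusion diffusion time at which agar matches a reference mean."""

    t_star: float
    agar_mean: float
    ref_mean: float
    percent_error: float


def slope_through_origin(points: Iterable[tuple[float, float]]) -> float:
    """Least-squares slope of a line through the origin: Σxy / Σx².

    ``points`` are (infused, measured) pairs; pairs with NaN measured
    volume are ignored. At least one point must have infused > 0.
    """
    arr = np.asarray(list(points), dtype=float)
    if arr.size == 0:
        raise FitError("no points: through-origin slope undefined")
    arr = arr[np.isfinite(arr[:, 1])]
    if arr.size == 0 or not np.any(arr[:, 0] > 0):
        raise FitError(
            "through-origin slope undefined: no usable point with infused > 0"
        )
    x, y = arr[:, 0], arr[:, 1]
    return float(np.sum(x * y) / np.sum(x * x))


def trajectory_slope(traj: Trajectory) -> float:
    """Per-trial through-origin Vd/Vi slope."""
    x, y = traj.xy()
    return slope_through_origin(zip(x, y))


def filter_noise(traj: Trajectory, factor: float = 1.1) -> Trajectory:
    """Single-pass outlier removal against the through-origin fit.

    Fits one line to all usable points and drops those with measured
    volume strictly greater than ``factor`` times the fitted value;
    points at exactly the cutoff are retained. Missing points pass
    through unchanged. Never iterated: one fit, one sweep.
    """
    slope = trajectory_slope(traj)
    kept = tuple(
        p
        for p in traj.points
        if not p.usable or p.measured_ul <= factor * slope * p.infused_ul
    )
    return Trajectory(traj.trial_id, traj.group, traj.region, kept)


def _fallback_fit(
    agar: Sequence[Trajectory],
    nhp: Sequence[Trajectory],
    reference: str,
) -> MixedFit:
    """Group-mean of per-trial slopes; used when the mixed fit is degenerate."""
    slopes = {"agar": {}, "nhp": {}}
    for traj in list(agar) + list(nhp):
        slopes[traj.group][f"{traj.group}:{traj.trial_id}"] = trajectory_slope(traj)
    other = "nhp" if reference == "agar" else "agar"
    ref_vals = np.array(list(slopes[reference].values()))
    oth_vals = np.array(list(slopes[other].values()))
    se = np.nan
    if len(ref_vals) > 1 and len(oth_vals) > 1:
        se = float(
            np.sqrt(
                ref_vals.var(ddof=1) / len(ref_vals)
                + oth_vals.var(ddof=1) / len(oth_vals)
            )
        )
    return MixedFit(
        base_slope=float(ref_vals.mean()),
        interaction=float(oth_vals.mean() - ref_vals.mean()),
        interaction_se=se,
        trial_slopes={**slopes[reference], **slopes[other]},
        reference_group=reference,
        method="trial-mean",
    )


def fit_mixed_model(
    agar: Sequence[Trajectory],
    nhp: Sequence[Trajectory],
    reference: str = "agar",
) -> MixedFit:
    """Fit measured = (β + γ·[group ≠ reference] + b_trial)·infused + ε.

    A linear mixed-effects model with per-trial random slopes b_trial
    and *no* intercepts, fixed or random — every best-fit line passes
    through the origin. Estimated by maximum likelihood. γ (the
    interaction) approximates the difference in average Vd/Vi slope
    between the non-reference and reference groups.

    If the likelihood fit is degenerate (zero residual variance,
    singular covariance, a single trial per group with exact data), the
    estimate falls back to group means of per-trial through-origin
    slopes, which preserves the defining property that with one
    noiseless trial per group the interaction equals the difference of
    the two trial slopes.
    """
    if reference not in GROUPS:
        raise ValidationError(f"reference must be one of {GROUPS}")
    if not agar or not nhp:
        raise FitError("need at least one trial in each group")
    for traj in list(agar) + list(nhp):
        if not traj.usable_points:
            raise FitError(f"trial {traj.trial_id!r} has no usable points")

    rows_x, rows_y, rows_ind, rows_trial = [], [], [], []
    for traj in list(agar) + list(nhp):
        x, y = traj.xy()
        rows_x.append(x)
        rows_y.append(y)
        rows_ind.append(np.full(len(x), float(traj.group != reference)))
        rows_trial.extend([f"{traj.group}:{traj.trial_id}"] * len(x))
    x = np.concatenate(rows_x)
    y = np.concatenate(rows_y)
    ind = np.concatenate(rows_ind)
    trial = np.asarray(rows_trial)
    if len(x) < 3:
        raise FitError("too few points for a mixed fit")

    try:
        import statsmodels.api as sm

        exog = np.column_stack([x, x * ind])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=trial, exog_re=x[:, None])
            result = model.fit(reml=False)
            base = float(result.fe_params[0])
            gamma = float(result.fe_params[1])
            gamma_se = float(result.bse_fe[1])
            re = result.random_effects
        if not (np.isfinite(base) and np.isfinite(gamma) and np.isfinite(gamma_se)):
            raise FitError("mixed fit produced non-finite estimates")
        trial_slopes = {}
        for tid in np.unique(trial):
            is_other = float(tid.split(":", 1)[0] != reference)
            b = float(np.asarray(re[tid]).ravel()[0]) if tid in re else 0.0
            trial_slopes[str(tid)] = base + gamma * is_other + b
        return MixedFit(
            base_slope=base,
            interaction=gamma,
            interaction_se=gamma_se,
            trial_slopes=trial_slopes,
            reference_group=reference,
            method="mixed",
        )
    except FitError:
        return _fallback_fit(agar, nhp, reference)
    except Exception:
        # np.linalg.LinAlgError, statsmodels convergence failures, ...
        return _fallback_fit(agar, nhp, reference)


def calibrate_segmentation(
    frames_by_trial: Mapping[str, Sequence],
    protocol,
    nhp_reference: Sequence[Trajectory],
    components: Sequence[str] = ("red", "green", "blue"),
    thresholds: Sequence[int] = tuple(range(40, 241, 10)),
    base_params=None,
    region: str = "cortical",
) -> CalibrationResult:
    """Grid-search the (color component, threshold) that aligns agar with reference.

    For every grid point all agar photo series are segmented and the
    alignment objective |interaction| from the mixed model against the
    reference trajectories is computed (falling back to the absolute
    difference of group-mean slopes when the mixed fit is degenerate).
    The grid minimizer is returned; ties break to the lowest threshold,
    then to channel order red < green < blue. This is a deterministic,
    reproducible surrogate for manual iterative threshold alignment.
    """
    from cedphantom.photo_seg import SegmentationParams, segment_series
    from dataclasses import replace

    if not frames_by_trial:
        raise ValidationError("need at least one agar trial")
    if not nhp_reference:
        raise ValidationError("need at least one reference trajectory")
    if not components or len(thresholds) == 0:
        raise ValidationError("calibration grid is empty")
    if base_params is None:
        base_params = SegmentationParams()

    order = {"red": 0, "green": 1, "blue": 2}
    best = None
    grid_log = []
    for component in components:
        for threshold in thresholds:
            params = replace(base_params, component=component, threshold=int(threshold))
            trajs = [
                segment_series(frames, params, protocol, trial_id=tid, region=region)
                for tid, frames in frames_by_trial.items()
            ]
            # drop zero-volume points (empty masks) alongside missing ones
            usable = [t for t in trajs if any(p.usable and p.measured_ul > 0 for p in t.points)]
            if not usable:
                continue
            try:
                fit = fit_mixed_model(usable, list(nhp_reference), reference="agar")
                objective = abs(fit.interaction)
                slope_table = dict(fit.trial_slopes)
            except FitError:
                try:
                    agar_mean = np.mean([trajectory_slope(t) for t in usable])
                    ref_mean = np.mean([trajectory_slope(t) for t in nhp_reference])
                except FitError:
                    continue
                objective = abs(float(ref_mean - agar_mean))
                slope_table = {}
            key = (objective, int(threshold), order[component])
            grid_log.append((component, int(threshold), objective))
            if best is None or key < best[0]:
                best = (key, component, int(threshold), objective, slope_table)
    if best is None:
        raise CalibrationError("every grid point produced an empty segmentation")
    _, component, threshold, objective, slope_table = best
    return CalibrationResult(
        component=component,
        threshold=threshold,
        objective=objective,
        slope_table=slope_table,
        grid=tuple(grid_log),
    )


def _running_median3(values: np.ndarray) -> np.ndarray:
    """Centered 3-point running median; endpoints use the available window."""
    out = np.empty_like(values, dtype=float)
    n = len(values)
    for i in range(n):
        out[i] = np.median(values[max(0, i - 1): i + 2])
    return out


def match_diffusion(
    post_infusion_series: Sequence[Sequence[tuple[float, float]]],
    ref_volumes: Sequence[float],
    tolerance: float = 5.0,
) -> DiffusionMatch:
    """Find the post-infusion diffusion time where agar matches the reference.

    ``post_infusion_series`` holds, per trial, (minutes since infusion
    end, bolus volume µL) samples. Each series is smoothed with a
    centered 3-point running median to sidestep noise spikes, the
    across-trial mean is formed on the common time support, and the
    earliest common time where the percent error against
    ``mean(ref_volumes)`` is ≤ ``tolerance`` (in percent) is returned —
    or, if no time qualifies, the global percent-error minimizer.
    """
    if not post_infusion_series:
        raise ValidationError("need at least one trial series")
    if len(ref_volumes) == 0:
        raise ValidationError("need at least one reference volume")
    ref_mean = float(np.mean(ref_volumes))
    if ref_mean <= 0:
        raise ValidationError("reference mean must be > 0")

    smoothed = []
    for series in post_infusion_series:
        arr = np.asarray(list(series), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
            raise ValidationError("each series needs (time, volume) samples")
        order = np.argsort(arr[:, 0])
        arr = arr[order]
        smoothed.append(dict(zip(arr[:, 0], _running_median3(arr[:, 1]))))

    common = set(smoothed[0])
    for s in smoothed[1:]:
        common &= set(s)
    if not common:
        raise ValidationError("trials share no common time support")

    times = sorted(common)
    t_star, best_pe, best_mean = None, np.inf, np.nan
    for t in times:
        mean_v = float(np.mean([s[t] for s in smoothed]))
        pe = percent_error(ref_mean, mean_v)
        if pe <= tolerance:
            return DiffusionMatch(t, mean_v, ref_mean, pe)
        if pe < best_pe:
            t_star, best_pe, best_mean = t, pe, mean_v
    return DiffusionMatch(float(t_star), best_mean, ref_mean, best_pe)


def percent_error(ref_mean: float, test_mean: float) -> float:
    """|ref − test| / ref × 100, the reference-relative percent error."""
    if ref_mean <= 0:
        raise ValidationError(f"reference mean must be > 0, got {ref_mean}")
    return abs(ref_mean - test_mean) / ref_mean * 100.0


def pooled_t_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided pooled-variance (equal-variance) two-sample t-test p-value."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least two values")
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def threshold_as_percent(threshold: int) -> int:
    """Express an 8-bit threshold as an integer percent of the 0–255 range."""
    if not (0 <= threshold <= 255):
        raise RangeError(f"threshold {threshold} outside [0, 255]")
    return int(round(threshold / 255.0 * 100.0))
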