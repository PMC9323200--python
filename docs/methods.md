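# Methods

## The model

The package treats a CED infusion trial as a pair of volume series: the
infused volume V_i(t), known exactly from the pump schedule, and a measured
distribution volume V_d(t), estimated from imaging. The working assumption —
well supported for pressure-driven delivery into both agar and brain
parenchyma — is proportionality, V_d ≈ β·V_i with β on the order of 3–6
µL/µL, so each trial is summarized by a single through-origin slope and
groups of trials are compared through their mean slopes.

### Protocols

A protocol is an ordered list of (rate, duration) pump steps. Rates are
constant within a step (no ramping), time zero is infusion start, and step
boundaries belong to the later step, so cumulative volume is continuous,
piecewise linear and non-decreasing, with the right-derivative at any time
equal to the active step's rate. The three presets are the bench gel
schedules for cortical, thalamic and MTL infusions; post-infusion dwell time
is not part of a protocol.

### Photo volumetry

Each photograph is reduced to one 8-bit value per pixel by *selecting* a
color component rather than converting to luminance: yellow dye absorbs blue
light almost completely and depresses green in proportion to concentration,
so the dye signal is cleanest in a single channel. Bolus pixels are *low* in
that channel; the threshold direction therefore defaults to `below`, with
`above` available for differently lit setups. Ties at the threshold are
excluded in both directions so that calibration grids are exactly
reproducible.

Cluster isolation uses 8-connectivity (tolerant of single-pixel diagonal
gaps along dye edges); without a seed pixel the largest cluster is kept.
Cannula erasure clears all marked pixels strictly above a user-chosen row
(row 0 is the image top; the cannula is assumed vertical). Bolus height and
width are the axis-aligned bounding extents of the mask in pixels spanned,
divided by the user-supplied pixel scale (px/mm, read off the in-frame
ruler — no automatic ruler detection). The volume follows from the
ellipsoid of revolution about the cannula axis, v = (π/6)·h·w², identical to
(4/3)π·a·b² with semi-axes a = h/2, b = w/2. Bounding extents were chosen
over fitted-ellipse axes as the simplest defensible reading of "height and
width of the bolus"; a fitted-ellipse mode is deliberately out of scope.

### MRI volumetry

Both contrast agents in scope (gadoteridol live, Mn²⁺ next-day) are
T1-hyperintense, so the bolus is a bright blob over darker tissue.
"Shrink-wrapping" is operationalized deterministically: voxels inside a
user-placed sphere, with intensity ≥ threshold (seed-inclusive, so raising
the threshold can only shrink the result), 26-connected to the sphere
center. Volume is voxel count × voxel volume, with anisotropic spacing taken
from the NIfTI header and no resampling. Interactive viewers compute volumes
from an interpolated surface instead; voxel counting is the contract here
because no published definition of that interpolation exists, and the two
differ only by a surface-voxel fraction that vanishes as spacing shrinks.
An `auto_threshold` helper proposes the midpoint of the seed-region and
background means, but threshold choice is fundamentally manual/iterative.

### Statistics

*Through-origin slope.* β̂ = Σxy/Σx². Forcing the origin encodes the physical
constraint that zero infused volume produces zero bolus.

*Mixed model.* Groups are compared with measured = (β + γ·[group ≠
reference] + b_trial)·infused + ε, b_trial ~ N(0, σ_b²) a per-trial random
slope, with **no intercepts**, fixed or random. γ — the interaction between
group and infused volume — approximates the difference in mean V_d/V_i slope
(non-reference minus reference; reference defaults to agar). Estimation is
maximum likelihood via statsmodels MixedLM. When the likelihood fit is
degenerate (zero residual variance, singular covariance, one trial per
group) the estimate falls back to group means of per-trial through-origin
slopes, which preserves the exact identity that with one noiseless trial per
group the interaction equals the difference of the two trial slopes. The
fallback's standard error is the usual two-sample SE of the per-trial slope
means (undefined with a single trial in a group).

*Threshold calibration.* The manual "adjust and re-plot until aligned" loop
is replaced by an explicit grid search over (component, threshold): each
grid point segments all agar series and scores |γ| against the reference
trajectories (falling back to |difference of group-mean slopes| when the
mixed fit degenerates). Ties break to the lowest threshold, then channel
order red < green < blue. Deterministic and reproducible by construction.

*Noise filter.* Small-volume (MTL-style) agar series carry proportionally
more segmentation noise. The filter fits one through-origin line to all
points and removes those strictly greater than 1.1× the fitted value —
one fit, one sweep, never iterated, and points below the line are never
removed.

*Diffusion matching.* Next-day in vivo imaging gives the bolus ~20 h to
diffuse, while agar diffuses much faster; the package finds the agar
diffusion time t\* whose across-trial mean volume matches the reference mean.
Each post-infusion series is smoothed with a centered 3-point running median
(the minimal operator that suppresses isolated noise spikes without biasing
a monotone trend), the across-trial mean is formed on the common time
support, and t\* is the earliest time with percent error ≤ tolerance
(default 5 %), else the global minimizer.

*Scalar tests.* Percent error is |ref − test|/ref × 100. The two-sample
t-test uses the pooled (equal-variance) form; on the packaged MTL reference
volumes the pooled form gives p = 0.56 at two decimals, which is the
printed precision used for reporting (percent error to 1 dp, thresholds as
integer percent of the 0–255 range).

## Synthetic data

The generators define the study conditions for all tests.

*Photographs* render a white backdrop, an agar block (blue value ≈ 247), a
2-px dark vertical cannula ending at the tip, 1-mm ruler ticks, and a dye
ellipse with extents (h·scale, w·scale) directly below the tip. Dye opacity
falls off radially as 0.3 + 0.7·(1 − r²)^¼: near-saturated over most of the
bolus and thinning toward the rim, but keeping the sharp optical edge that
concentrated food coloring shows against clear gel — so a threshold anywhere
between the rim value (~175 in blue) and the agar value captures the full
extent. Ellipse centers are offset half a pixel so rasterized spans equal
the true pixel extents; residual round-trip error is the ±1 px quantization
of non-integer extents (<5 % at the default 10 px/mm, shrinking with
resolution). Series rendering uses a fixed aspect ratio h = 2w (a bolus
elongated along the cannula) to invert v → (h, w); post-infusion growth
follows v_end·(2 − e^(−t′/τ)), a saturating stand-in for continued dye
diffusion in agar, not a physical diffusion solver.

*MRI grids* assign bolus intensity 200 inside an analytic ellipsoid and
background 100 outside (defaults), on isotropic 0.5 mm voxels by default,
plus optional Gaussian noise.

*Trajectories* draw per-trial slopes from N(group mean, slope_sd) and
observe slope·infused + N(0, noise_sd) over an even infused grid (defaults:
slope_sd 0.3 µL/µL, noise_sd 2 µL, 20 points to 50 µL — magnitudes matching
bench-scale cortical trials; negative draws are floored at zero, which is
immaterial at these signal-to-noise ratios).

What the generators deliberately do **not** emulate: lighting gradients,
lens distortion, reflux along the cannula track, failed trials, partial-
volume effects at the MRI bolus rim, and scanner intensity nonuniformity.
Passing round-trip tests therefore demonstrates correctness of the
measurement chain, not robustness to every bench artifact; the direction
parameter, seeded cluster selection and manual thresholds are the knobs a
user would turn for real imagery.

## Numerical choices and degenerate inputs

- Strict inequalities at the segmentation threshold; ≥ at the MRI threshold
  (the seed must be inside its own mask).
- Empty photo masks measure h = w = v = 0; frames where no cluster exists
  become missing trajectory points rather than errors, because early
  diffusion frames routinely lack an identifiable bolus.
- Infused volumes are clamped at the protocol total for post-infusion
  frames.
- The mixed model requires ≥1 trial per group and ≥3 data points overall;
  everything smaller raises a diagnostic error rather than returning NaNs.
- Simulation seeds derive from a single user seed (kept below 2³¹).

## Default problem sizes

Test and reproduction runs use desk-scale sizes chosen so a full pass
completes in seconds on one CPU while leaving the statistical checks
informative: 64³ MRI grids at 0.5 mm, 320×240 photo frames at 10 px/mm,
10+10 simulated trials of 20 points for interaction recovery, and 200
replicates of that design for null calibration. The null 2-SE coverage of
the ML interaction sits near 0.92 — slightly below the nominal 0.95, the
familiar anticonservatism of ML variance components with ~10 groups per
arm; REML would narrow the gap but ML is kept for consistency of the
likelihood across nested comparisons.

## Known limitations

- Bounding-extent measurement overestimates h/w for tilted or irregular
  boluses; the cannula is assumed vertical in frame.
- Voxel-count MRI volumes differ from interpolated-surface volumes by up to
  the surface-voxel fraction at coarse spacing.
- The calibration objective uses |interaction| only; it does not penalize
  mismatch in slope *variance* between groups.
- Packaged reference tables are printed summary values (per-trial slopes and
  final volumes), not raw trajectories, so group comparisons against them
  at full mixed-model resolution require the user's own reference data.
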