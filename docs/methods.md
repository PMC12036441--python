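# Methods

This note documents the models, conventions, and design choices behind
`lucidmap`, and what the synthetic-data tests do and do not establish about
real data.

## Volumes and grids

All volumes are reoriented to RAS+ on load and live on affine-referenced
grids in millimetres. Multi-volume operations require pre-aligned inputs —
identical shapes and affines agreeing to 1e-4 mm — and never resample;
harmonizing differently-gridded maps is the caller's responsibility.
Stat/effect maps are stored as float32 and masks as uint8 on write, with a
JSON sidecar carrying `{stat_type, df, units, space_label}`. A 4D NIfTI
with a single frame is accepted as 3D (a common exporter dialect).
Display-side left/right conventions are applied only at render time;
the default is neurological (image left = subject left).

## Transparent thresholding

The opacity law is

    alpha(v) = floor + (1 - floor) * (|v| / theta)^exponent,  clamped to [0, 1]

with `exponent = 2` (quadratic fade) and `floor = 0` by default; both are
exposed in `AlphaSpec` since only the qualitative law — opaque at and above
threshold, smoothly fading below — is canonical. Opacity is driven by the
statistic magnitude, not signed values, so positive and negative effects
fade symmetrically. Compositing is per-pixel convex blending,
`out = alpha * cmap(overlay) + (1 - alpha) * gray(underlay)`, which keeps
every channel between the underlay and overlay values. Cluster outlines are
one-pixel inner boundaries (mask AND NOT 4-neighbor erosion) drawn per
cluster after blending. The underlay is normalized to its 2nd–98th
percentile; the colorbar applies the same alpha law against a mid-gray
background so the fade itself is depicted. Overlay colors may come from the
effect-estimate map while thresholding stays statistic-driven — the
recommended style, since effect sizes in physical units carry information
statistics do not (a high-Z voxel with negligible effect is likely noise).

## Thresholding and multiplicity

Voxelwise thresholds are two-sided: `theta` is the (1 − p/2) quantile of
the reference distribution (Z, or t with the map's df). The t-to-Z
conversion preserves per-voxel tail probability and is computed in
log-probability space so |t| in the hundreds does not saturate.

Clustering is sign-split: components of {v ≥ theta} and {v ≤ −theta} are
labeled separately, so adjacent positive and negative voxels never join.
Default connectivity is 6 (faces only) — the conservative choice, since
published cluster sizes rarely state their neighborhood — configurable to
18 or 26. Labels are ordered by size (descending), breaking ties by the
smallest flat voxel index, so outputs are diffable.

The cluster-extent threshold for a target FWE rate is calibrated by Monte
Carlo: white Gaussian noise is smoothed to a user-stated FWHM (in voxels;
sigma = FWHM / 2.3548) by separable convolution with mask-edge variance
renormalization (dividing by the pointwise sd that unit-variance white
noise would have, sqrt((k² ∗ mask)(x)), which removes edge attenuation),
standardized to zero mean and unit variance within the mask, and
thresholded two-sided; the maximum surviving component size is recorded per
field. `k_min` is the smallest integer k whose exceedance fraction is at or
below the target rate. Smoothness is an input, not estimated from
residuals. The RNG seed is explicit and recorded in outputs.

**Discreteness caveat.** Cluster extents are integers, so the attainable
FWE operating points form a discrete set. At the documented simulation
conditions (32³ grid, FWHM 2 voxels, voxelwise p = 0.001) the true
exceedance of k = 9 sits almost exactly on the 5% target, so finite
calibrations (2000 fields) land on either side of it: roughly half select
k = 9 (attained FWE ≈ 5%) and half k = 10 (attained ≈ 3%, conservative).
The calibration rule guarantees control (FWE ≤ target), not equality; users
wanting the attained rate should read it off the returned null
distribution via `FweCalibration.exceedance`.

BH-FDR is the standard step-up procedure on two-sided per-voxel p-values
within the mask (via statsmodels), returning the adaptive p-threshold and
the survivor mask.

## Group analysis

The one-sample t-test is the only design: per voxel, t = m / (s / sqrt(n))
with the n−1 denominator and df = n−1. Zero-variance voxels are
statistically undefined; they are set to t = 0 (hence subthreshold
downstream, never ±inf) and surfaced in an `undefined_count` for QC.
Subject values are sorted per voxel before reduction so results are
bit-identical under subject reordering.

## Similarity

Dice, D = 2|A∩B| / (|A|+|B|), compares binarized suprathreshold-cluster
masks (sign-agnostic |v| ≥ theta, extent filter k = 0 by default). Two
empty masks give D = 1 (two null results agree) with a logged flag; one
empty gives 0. Pearson correlation compares unthresholded values within a
caller-supplied mask; a constant map makes the pair undefined (NaN,
reported in `undefined_pairs`), never an imputed number.

## Jackknife stability

Subjects are removed cumulatively — by ascending subject ID unless an
explicit order is given — from the full group down to `n_min`, the
identity stage (`n_min = n`) being a valid single-row analysis. At each
stage the voxelwise threshold is re-resolved for the stage's df; with
`recalibrate=True` (default) the extent threshold is re-simulated at that
theta with a fixed seed, so stages differ only through df. Cluster counts
are reported exactly as observed — they are the instability being measured
— and all stages are compared pairwise under both Dice (on surviving
cluster masks) and Pearson (on unthresholded t maps).

## Synthetic data

Generators are pure functions of configuration and seed.

- `smooth_gaussian_field` smooths white noise under periodic boundaries
  (stationary statistics, so the autocorrelation matches the kernel
  prediction exp(−d²/(4σ²)) everywhere) and standardizes over the grid.
- `simulate_group` builds subject volumes as
  `(1 + sd_b · g_i) · template + noise_i`: Gaussian-bump effects (smooth
  spatial drop-off, not hard spheres), scalar between-subject amplitude
  scatter, and unit-variance smooth noise. Defaults — 24³ grid, 20
  subjects, FWHM 2, a strong right bump of 1.0 effect units (peak t ≈ 4.4)
  plus a weaker mirrored 0.6 bump, sd_b = 0.2 — put the effect deliberately
  near the p = 0.001 threshold, the regime where thresholded summaries are
  least stable. Ground truth is attached to the dataset.
- `make_quartet` constructs four Z maps bitwise identical on the
  suprathreshold set (one right-hemisphere cluster) whose subthreshold
  content realizes: a same-sign mirrored pattern; its mirrored negation
  (exactly −(mirror) wherever both sides are subthreshold); near-zero
  background; and white noise clipped strictly below threshold.
- `make_phantom_fov` fills a small field of view with smooth noise, marks
  an ellipsoid anatomy, and optionally injects a low-effect suprathreshold
  bump; the effect map is `noise_sd` times the Z map, so "significant"
  voxels still carry small physical effects.
- `simulate_map_family` emulates many teams analyzing one dataset: a
  shared brainwide smooth pattern (2 noise-sd) scaled per map by 0.5–2×
  plus independent smooth noise — the regime where correlation stays high
  while binarized overlap collapses.

**What passing tests show.** The generators produce stationary Gaussian
fields with simple blob effects; they have no physiological or scanner
noise structure, no spatial nonstationarity, no registration error, and
between-subject variability is a single scalar. Calibration, recovery, and
stability results on them validate the algorithms under their stated
assumptions; they do not by themselves establish behavior on real
acquisitions.

## Numerical choices

Degenerate inputs are resolved explicitly: zero-variance voxels → t = 0
and counted; empty masks → errors; both-empty Dice → 1.0, flagged;
constant-map Pearson → NaN, reported. Thresholding uses ≥ (a voxel exactly
at theta is suprathreshold, alpha = 1). The FWHM/sigma ratio is
2·sqrt(2·ln 2). Rendering embeds no timestamps; identical inputs produce
byte-identical PNGs. Simulation sizes used by the test suite and the
reproduction script (32³ nulls, 24³ groups, 50-seed ensembles) were chosen
to give stable Monte-Carlo answers in minutes on a single CPU.

## Known limitations

No resampling between grids; volumetric only (no surfaces or ROI
variants); one-sample designs only; smoothness is user-stated rather than
estimated from residuals; random-field-theory and permutation inference
are out of scope; the integer-extent FWE discreteness described above.
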