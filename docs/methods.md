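# Methods

## Coordinate conventions

Image raster coordinates throughout: origin at the top-left pixel, x
rightward (columns), y downward (rows), 0-based floating-point pixels.
"Superior" on the retina is therefore decreasing y. The temporal horizontal
is the horizontal unit vector from the optic disc center toward the side the
fovea is on; deriving it from positions rather than the recorded laterality
makes the code robust to mislabeled files and lets one code path handle both
eyes (the laterality tag is kept for validation only).

## Geometry

**Disc summary.** The disc center is the arithmetic centroid of the clicked
boundary points and the radius their mean distance to it — simple and stable
for the ≥ 8 points an annotator provides, with no ellipse-fit failure modes.

**Ovality ratio.** "Maximum disc diameter / minimum disc diameter" is
operationalized with Feret diameters of the boundary point set: the maximum
Feret diameter is the largest pairwise distance (restricted to convex-hull
vertices; for > 2048 hull points the candidate pairs are the directional
extremes on a 0.25° grid, exact to ~1e-9 relative); the minimum Feret width
is the smallest projection extent over caliper directions sampled every
0.5°. Both choices only overestimate ovality by < 1e-5 relative at that
step size. Note that a *finite sample* of a circle is a regular polygon
whose true min Feret width is below its diameter — a 360-point circle has
ovality ≈ 1.00002 by construction, not 1.0 exactly; dense samples (tens of
thousands of points) reach the circle identity to 1e-6.

**Angles.** Vessel angles are unsigned magnitudes in [0°, 180°] between the
disc-center→crossing ray and the temporal horizontal; supratemporal and
infratemporal measurements are distinguished by which landmark is supplied,
not by sign. PMP is signed: positive when the fovea lies inferior to the
disc center (greater image-y), using |Δx| so the value is invariant under
horizontal mirroring. The sign convention is internal; only its consistency
matters, and the synthetic generator uses the same one.

**ROI layout.** Eight sampling circles ring the disc at
`center_dist_mult × radius` (default 1.7), 45° apart starting temporally and
stepping through supratemporal; the ninth sits on the fovea. All circles
have radius `roi_radius_mult × radius` (default 0.5). Published protocols
for peripapillary color sampling do not fix this ring geometry in pixels, so
both multipliers are exposed in the config; the defaults put eight
non-overlapping circles just outside the disc, and every synthetic ground
truth uses the same config as the extractor, so results are consistent for
any fixed choice.

## Colorimetry

A pixel (integer i, j) belongs to an ROI when its center-to-center distance
to the ROI center is ≤ the radius — no partial-pixel weighting, so every
mean is exactly reproducible and matches a per-pixel enumeration oracle
bit-for-bit. An ROI that extends beyond the image is an error rather than a
clipped mean (clipping would bias means toward the interior; studies instead
exclude eyes with unclear peripheral fundus). Intensities are used as
stored: no gamma linearization or illumination correction. TFI is computed
from the three region means and re-derivable from the stored R, G, B
columns to 1e-12; TFI of a gray region is exactly 1/3, and the index is
invariant to global intensity scaling.

The 42 features are frozen in channel-major order — st_ra, it_ra, st_rv,
it_rv, pmp, ovality, then R, G, B, TFI blocks each over temporal,
supratemporal, superior, supranasal, nasal, infranasal, inferior,
infratemporal, fovea — matching the layout of published selection tables, so
CSV columns are stable across versions.

## Penalized regression

Standardization uses the population SD (divisor N), matching the 1/2N loss
normalization; predictions are invariant to this choice because the
back-transformation uses the same constants. Constant columns raise a named
error. The optimizer is cyclic coordinate descent on the Gram statistics
G = XᵀX/N, c = Xᵀy/N of the standardized design:

    βⱼ ← S(cⱼ − Σ_{k≠j} Gⱼₖ βₖ, λα) / (Gⱼⱼ + λ(1−α)),  S = soft threshold.

Updates run in fixed column order, so fits are bit-reproducible; each
univariate update is exact, so the objective is non-increasing. Convergence:
max absolute standardized-coefficient change < 1e-7 over a sweep, capped at
100,000 sweeps (a non-converged fit is returned flagged, with a warning).
The kernel is JIT-compiled with numba when importable; the NumPy fallback
runs the identical floating-point operations. Working on Gram statistics
makes each sweep O(p²) regardless of N, which is what keeps nested
cross-validation affordable.

**λ path and selection.** The path is log-spaced over
[ratio_min·λ_max, λ_max] with λ_max = maxⱼ|xⱼᵀy|/(Nα), n_lambda = 50 and
ratio_min = 0.01 by default (with n ≫ p the CV curve is flat below that,
and the near-collinearity of the TFI columns with their R, G, B parents
makes very small λ needlessly expensive). The default selection strategy is
10-fold CV over the path *within each training fold*, minimizing validation
MSE, ties broken toward the sparser (larger) λ; a fixed-λ strategy is also
provided. Selection fits use a looser tolerance (1e-4) since only the MSE
ranking matters; the model refitted at the chosen λ uses the strict 1e-7.
Inner fold assignment is derived from the sorted row identifiers and the
seed, never from row positions, so every reported statistic is invariant to
row order.

## Evaluation

LOOCV holds out each eye in turn: N fits, each with its own penalty
selection, statistics computed from the N held-out predictions. The MAE CI
uses the large-sample normal approximation mae ± 1.96·sd(|e|)/√N (the
customary choice when none is stated); a seeded 2000-resample bootstrap is
available for sensitivity. Pearson's r is the sample correlation between
actual and predicted age; it is an error for constant vectors rather than a
silent NaN. The coefficient report flags marginal correlations at p < 0.001
(the conventional threshold for cohorts of this size) but nothing internal
branches on p-values. A binomial/ROC evaluation is deliberately absent:
the response is continuous age, so MAE/CI and r are the appropriate
statistics.

## Synthetic data

**Cohorts.** A latent age is drawn Uniform(40, 80) years — the least
assumptive bounded choice for a ≥ 40 population with that reported range —
and each directly generated feature j follows
baselineⱼ + slopeⱼ·(age−60) + N(0, σⱼ). Slopes are calibrated so the
expected feature–age Pearson r equals the published age-correlation value
for that parameter (signs are the constraint being emulated — e.g. blue
temporal strongly negative, red positive everywhere; magnitudes span ≈ 0 to
≈ 0.49). Channel intensities are clipped to [0, 255] with a logged count.
TFI columns are always recomputed from the generated R, G, B columns, never
sampled independently, so their correlations are emergent exactly as in real
data. The recorded age is c₀ + Xw + N(0, σ) with w the inverse-variance
weights reconstructing the latent age from the noisy features (normalized so
Σ wⱼ slopeⱼ = 1) and σ = 3 years by default: the response is then an *exact*
linear function of the observed design plus known noise, giving LOOCV MAE
the closed-form target σ·√(2/π) and making end-to-end recovery testable.
Note the recorded age consequently has a heavier-tailed, wider distribution
than the latent Uniform(40, 80).

**Renders.** Images contain a smoothly blended background (inverse-square
distance weighting of the nine region colors), nine constant-color sampling
disks painted 2 px beyond the extraction radius, four vessel rays confined
within 1.08× the disc radius, a bright elliptical disc, and a darker fovea
disk. Discs are vertically oval (as real discs are) with ovality sampled in
[1.05, 1.35]; with the default ROI config this guarantees neither disc nor
vessels ever intrude into a sampled circle, so noiseless extraction recovers
region colors exactly and angles to machine precision; boundary landmarks
are 36 exact ellipse points, which bounds the ovality recovery error below
1% (inscribed-polygon effect). Region colors are integer-valued so they
survive the 8-bit raster exactly. Optional Gaussian pixel noise is seeded.

**What the renders do not emulate:** real vessel curvature, width variation
and branching; peripapillary atrophy; media opacity / cataract color casts;
inter-camera color variation; annotator click error. Passing the round-trip
tests therefore shows the *measurement code* is correct given landmarks, not
that landmarks are easy to place on clinical images. Likewise the cohort
generator's independent Gaussian residuals ignore the correlated residual
structure of real colorimetry, so the LOOCV floor result validates the
regression machinery, not clinical attainability of any particular MAE.

## Problem sizes and determinism

The shipped study uses n = 500 eyes, 12 rendered fixtures, and 50-image
recovery sweeps — sizes at which every statistical target is stable across
seeds while the full suite runs in well under a minute of compute per stage.
All randomness flows from one integer seed through one `numpy` Generator per
call; there is no global random state, and identical seed + config reproduce
byte-identical CSV/JSON/PNG outputs.

## Known limitations

- The ROI ring geometry of the original protocol is not published with
  numbers; results depend on the configured multipliers (consistently so).
- The ovality of a sparse boundary sample is a property of the point set,
  not the underlying ellipse (inscribed-polygon bias, < 1% at 36 points).
- The MAE CI's normal approximation is anti-conservative for small N; use
  the bootstrap option below ~50 eyes.
- With α = 0 (pure ridge) there is no finite λ_max; the path top falls back
  to a conventional bound and all-zero fits are not expected there.
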