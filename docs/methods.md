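# Methods

## The model of a trajectory

A trajectory is an ordered per-frame sequence of planar positions in image
coordinates (origin top-left, y down, 0-based frames), with a per-frame
missing flag for frames the tracker lost. Frames default to 25 fps (600 s →
15 000 frames) when the table carries no timing metadata. Calibration is a
single scalar, px_per_cm = 2·radius_px / diameter_cm from the arena circle
(20 cm dish by default); coordinates are never rescaled in place — the
conversion is applied when centimetre metrics are computed, so raster
geometry and metric extraction cannot drift apart.

Missing frames are handled per use: for path length and speed the gap is
bridged by the straight chord (the shortest path consistent with the
observations, hence a lower bound on distance during dropouts); for
rasterization interior gaps are linearly interpolated; segments with more
than 10 % missing frames (configurable) are excluded from dimension
estimation entirely, because interpolation artefacts are straight lines and
bias D downward.

Long recordings are cut into consecutive, non-overlapping 1500-frame
segments; the trailing partial segment is discarded so every analysed
segment has identical length and its scale profile is comparable. An
individual's index is the mean over its full segments ("mean" mode); a
"whole-path" mode estimates on the uncut path instead.

## Rasterization

All three estimators operate on a pixel set, so the path is drawn into a
square binary grid (default 1024, desk-scale analyses use 256). The
affine map is aspect-preserving with a 2-cell margin, making the raster
invariant under uniform scaling of the input coordinates. Consecutive
positions are joined by 8-connected Bresenham segments: inter-frame gaps
are usually larger than one cell, and 8-connectivity keeps a straight path
one cell thick at any angle (D = 1).

Each raster records its *sample spacing* — the median inter-vertex distance
in cells. This is the finest scale at which the raster carries information
about the path's geometry rather than about line drawing.

## Dimension estimators and their scale windows

Every estimator reduces the raster to a (scale, measure) profile and fits
ordinary least squares in log–log space; the dimension is a linear map of
the slope (box: −slope; radial: +slope; dilation: 2 − slope). Reported D is
clamped to [0, 2] with the raw slope retained; fits with r² < 0.95 emit a
warning — empirical paths are only statistically self-similar over a finite
window.

Scale schedules are geometric (powers of two — equal leverage per octave)
and are anchored at the sample spacing, for a reason worth stating plainly:
below the sampling scale *every* polyline is a chain of straight segments
and every estimator converges to D = 1 regardless of the path, so probing
there only dilutes the signal. Upper ends are method-specific:

* **box**: sizes from the sample spacing (≥ 2) to resolution/4. The count
  at each size is the *covering number* — the minimum over four
  deterministically jittered grid origins (always including the aligned
  origin) of the number of boxes containing an occupied cell. The minimum,
  not the mean, is used: averaging inflates counts near the grid border at
  large box sizes (a shifted grid needs up to (k+1)² boxes to span what k²
  cover), which measurably flattens the slope; the minimum is also the
  definition of a covering.
* **dilation**: radii from the sample spacing to resolution/32. The low cap
  on the largest radius avoids the O(r²) end-cap term of the Minkowski
  sausage of a finite path, which otherwise bends the profile upward (a
  straight line read D ≈ 1.15 with radii up to resolution/8). The recorded
  scale is r + ½: the discrete path is already one cell wide, so a thin
  curve's sausage grows like (2r + 1)·L, and without the half-cell
  continuity correction the small-radius slope is biased.
* **radial mass**: radii from the sample spacing (≥ 2) to resolution/16,
  counted around the occupied cell nearest the occupancy centroid plus ten
  occupied cells sampled with a fixed internal seed, restricted where
  possible to cells whose largest disk fits inside the grid. Both caps
  matter: beyond ~resolution/16 the disk starts enclosing the entire set
  (M(r) saturates) and, for dense paths, the estimator reads "2" for every
  input — in development this made radial D *increase* with turning
  concentration, the opposite of the other two methods. With the tighter
  window all three estimators are strictly decreasing across a CRW
  concentration sweep.

Validation anchors (all in the test suite): straight line D = 1 ± 0.05 for
all methods; order-7 Hilbert curve at resolution 1024, box D = 2.000;
order-5 Koch curve D within 0.05 of log 4/log 3 ≈ 1.2619 for box and
dilation; box counts agree exactly with a brute-force nested-loop counter
on ≤ 64×64 grids.

## Locomotor traits

TPL is the sum of Euclidean inter-frame displacements over tracked frames
(cm); mean speed is TPL over the tracked duration; MSR is the maximum of
the per-interval speed series. MSR is unsmoothed by default but exposes an
odd-width median filter, because a single mistracked frame manufactures one
or two huge apparent speeds; a window of 5 removes a one-frame glitch
completely while a window of 3 does not (the glitch produces two deviant
consecutive intervals). Pause metrics are deliberately not computed — no
defensible pause threshold exists without a definition.

## Synthetic experiment

The generator emulates the experiment's hierarchical design so that every
downstream statistic has a ground truth. For each specimen,

    log κ = log 0.5 + β_treatment · (1 − b·complex) + family offset + u_site

with u_site ~ N(0, 0.15²) over six sites, β = +0.6 (+5 °C) and +1.2
(+10 °C) on the log turning-angle concentration, buffering b = 0.8 in
structurally complex microhabitats (boulders, macrophytes), and a small
family offset (+0.1 for Leptophlebiidae). Microhabitats are sampled with
the observed field proportions (50.76 % boulders … 16.03 % sand). The
trajectory is a correlated random walk: turning angles N(0, 1/κ) (wrapped;
κ = 0 means uniform), reflective circular arena of 20 cm at 30 px/cm,
15 000 frames at 25 fps by default. Body length is family-specific
truncated normal (> 0.2 cm, the field inclusion rule); lyophilized weight
scales with length³ times log-normal noise; the per-specimen step length is
log-linearly tied to body length, producing the morphology–speed–complexity
correlations expected of real nymphs.

Warming therefore *raises* κ — straighter paths, lower D — which is the
direction of effect the design encodes; effect sizes were chosen once for
detectability at the design's n under the AIC-selection chain, since no
quantitative effect size is available to emulate. What the generator does
not model: wall-following (thigmotaxis), 3-D swimming, blob-width effects
of tracking the whole body rather than a point, and inter-individual
interaction. Passing tests on synthetic data demonstrate that the chain of
estimators and statistics recovers known structure; they do not certify
behaviour on real video exports beyond the format contract.

## Statistics

* Variance test: Brown–Forsythe (Levene with group medians), robust to
  non-normality.
* Mixed models: Gaussian with a single random intercept for site, fit by
  maximum likelihood (not REML) because AIC comparisons span different
  fixed-effect sets. AIC counts fixed effects + residual variance + the
  random-intercept variance. The optimizer is Powell: derivative-free and
  robust when the intercept variance sits on the boundary (statsmodels'
  L-BFGS returns a spurious infinite likelihood there). Agreement with
  lme4 (ML) is asserted in the test suite to ~1e-3 in log-likelihood.
  The default candidate set is intercept-only, treatment, treatment+family,
  treatment+microhabitat, treatment+family+microhabitat, and
  treatment×microhabitat; candidates whose design is rank-deficient on the
  data at hand (empty interaction cells) are excluded from the comparison.
* Akaike weights: w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2), invariant to adding a
  constant to all AICs.
* MANOVA: Pillai's trace with *sequential* (type-I) sums of squares in the
  declared factor order (family, microhabitat, treatment); a factor fully
  aliased with earlier terms yields a zero-rank increment and is reported
  with NaN F rather than a spurious statistic. Verified against statsmodels
  MANOVA in the single-factor case and against univariate ANOVA in the
  single-response limit.
* Tukey HSD: Tukey–Kramer (unequal n — the microhabitat groups are very
  unbalanced); labels follow the "B−A" convention, positive differences
  meaning the first-listed group is larger.
* PCA: correlation-matrix PCA of the three indices; each specimen is
  labelled by its dominant index (largest value), ties broken by the fixed
  order FDIr > FDIb > FDId and flagged.
* RDA: responses standardized to Z-scores, regressed on the centered
  indicator matrix of the constraining factor; SVD of fitted values gives
  constrained axes, of residuals the unconstrained ones; constrained +
  unconstrained variance equals the total exactly. Axis orientation is
  fixed deterministically (largest-|loading| entry positive).
* Correlations: pairwise-complete Pearson r with two-sided t-based
  p-values and per-cell n; cells with < 3 complete pairs are not estimable.
* No multiplicity correction is applied beyond Tukey HSD — a deliberate
  mirror of the analysis workflow this package reimplements, and a known
  limitation.

## Numerical and reproducibility choices

Every stochastic component takes an explicit seed; fixed seeds give
byte-identical track tables, estimates and statistics tables. The radial
center sampler uses a fixed internal seed so that estimates are a pure
function of the raster. Degenerate inputs fail loudly: duplicate frames,
< 2 tracked frames, uncalibrated metrics, single-level factors, zero-variance
PCA columns, rank-deficient designs.

Default problem sizes in the test suite are desk-scale choices: 256–1024
raster cells, 1500–3000-step walks, 20–50 simulation replicates. These keep
the full suite in the minutes range while leaving every qualitative
conclusion (anchors, monotonicity, effect recovery, calibration)
unchanged at larger sizes.

## Known limitations

* Exact numeric replication of Fractalyse output is out of scope — its
  scale ranges, offsets and fit windows are not public; only the method
  definitions are reimplemented.
* The estimators see a polyline, not the animal's body silhouette; with
  blob tracking the effective path has width, which inflates small-scale
  measures.
* 2-D projection only: vertical movement in the water column is folded
  into the plane.
* Radial mass estimates are center-policy dependent at small n_on; the
  default multi-center average with border-safe centers is stable but not
  canonical.
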