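# Methods

## The measurement

`onlshape` quantifies the three-dimensional deformation of the outer
nuclear layer (ONL) around the macula from segmented SD-OCT surfaces, and
relates its anisotropy to the directional anisotropy of metamorphopsia.

The input for one eye is a pair of segmentation surfaces over a 20° macular
cube (6.7 × 6.7 × 1.5 mm, acquired as 49 B-scans × 512 A-scans × 400 axial
pixels): the ONL/OPL boundary and the RPE line, each a 49 × 512 grid of
axial positions. The processing chain is:

1. **Height image (HI).** ONL thickness = RPE depth − ONL/OPL depth per
   A-scan, then linear interpolation along the B-scan axis from 49 to 512
   rows, giving a 512 × 512 map of ONL height above the RPE. Heights convert
   to micrometres with the axial scale 3.87 μm/px. Interpolation runs on
   pixel heights; the μm view is a pure scalar multiply.
2. **Reference plane.** The height at the mode of the HI histogram — the
   background ONL thickness away from the foveal bump. Histogram bins are
   centred on integer multiples of the bin width (default 1 px, the native
   axial quantization); ties break toward the lower bin so the plane anchors
   the base of the layer.
3. **ONL-Base (ONL-B).** Candidate contours are superlevel-set boundaries
   of the HI, traced at sub-pixel resolution (marching squares with linear
   edge interpolation) around the connected component (8-connectivity) that
   contains the global height maximum — the foveal peak, the only landmark
   available from the height map alone. Interior holes are filled. A
   candidate is admissible when (i) it lies strictly inside the HI, (ii) its
   convex-hull deficit is ≤ 20,000 px², (iii) hull area / region area ≤ 1.2,
   and (iv) its restorability ratio is ≥ 0.95 (below). The ONL-B is the
   lowest admissible level at or above the reference plane, scanned upward
   in 1-px steps to 95% of the peak height; its height is reported as the
   distance from the RPE line in μm.
4. **Ellipse fit and shape parameters.** Area, centroid and second central
   moments of the ONL-B region are computed analytically from the boundary
   polygon by Green's-theorem line integrals (rasterizing first would add
   grid bias; a pixel-covariance oracle guards the implementation in the
   tests). The equivalent ellipse has full axis lengths a = 4√λ₊,
   b = 4√λ₋ from the moment eigenvalues — a disk of radius r gives
   a = b = 2r — and major-axis angle θ = ½·atan2(2μ₁₁, μ₂₀−μ₀₂), reported
   counterclockwise-positive in the fundus view and wrapped to (−90°, 90°].
   Right-eye (OD) angles are mirrored into the left-eye frame so "+" means
   the same anatomical direction in both eyes. The three deformation
   parameters are
   * **circularity** 4πS/L² of the 5-harmonic elliptic-Fourier-smoothed
     boundary (1 for a circle; the statistic is scale-invariant, so the
     usual Fourier size normalization drops out),
   * **area ratio** S/(ab) with the raw region area (π/4 ≈ 0.785 for a
     perfect ellipse; lower for irregular contours),
   * **axis ratio** a/b ≥ 1.
5. **Cohort statistics.** The metamorphopsia anisotropy score is MH/MV from
   the MCHART, with a score of 0 recorded as 0.05 before forming the ratio.
   Group comparisons use Welch's two-sided t-test by default (a pooled-
   variance Student variant is selectable); associations use Pearson
   correlation with the two-sided t-transform p-value, reported for all ERM
   eyes and for the subset with |axis| ≤ 10°, where the chart's
   horizontal/vertical decomposition aligns with the deformation axes.
   p < 0.05 is flagged significant; p-values are reported raw (no
   multiple-testing correction).

## Elliptic Fourier restorability

Contours are represented by Kuhl–Giardina elliptic Fourier descriptors of
the arc-length parameterization, with coefficients computed as exact
integrals of the piecewise-linear boundary. The restorability QC resamples
the boundary to 100, 50 and 25 equally spaced (by arc length) points, fits
five harmonics, reconstructs densely, and asks what fraction of the
original region the reconstruction recovers:

A1/A0 = area(original ∩ reconstruction) / area(original), minimized over
the three point counts.

A1 is deliberately the *recovered overlap*, not the raw area of the
reconstructed curve. A zero-mean boundary ripple leaves the enclosed area
almost unchanged after smoothing (a 12-lobe ±20% radial ripple keeps
~98.5% of the area), so a raw-area quotient passes essentially any contour
and cannot serve as a restorability gate. The overlap fraction instead
drops exactly when five harmonics cannot follow the boundary: ≈ 0.87 for
that 12-lobe ripple, ≈ 0.99 for an ellipse. Note the 0.95 threshold also
absorbs a ~1% inscribed-polygon deficit inherent to the 25-point
resampling, so even perfectly smooth contours score ≈ 0.985, not 1.0.

Because arc length is the parameter, an exact ellipse is not a single pure
harmonic: about 0.6% of the coefficient energy of a 2:1 ellipse leaks into
higher odd harmonics. This is intrinsic to constant-speed traversal and is
why the smoothed-boundary circularity of a 2:1 ellipse evaluates to 0.843
rather than the exact-curve value 0.8412 (both within the tolerance used in
the tests).

## Synthetic eyes

No imaging data accompany the analysis, so the generator renders eyes with
known ground truth. The ONL height surface is a flat base plus an
elliptical Gaussian bump,

h(x, y) = base + peak · exp(−ρ²/2), ρ² = (u/σ_maj)² + (v/σ_min)²,

in coordinates rotated to the true axis angle, with an optional radial
ripple factor 1 + amp·cos(lobes·φ) applied to the level-set radius. Every
level set then shares one shape up to scale, so recovery targets are
independent of which level the ONL-B search selects. The RPE is rendered
flat (only the ONL−RPE difference enters the analysis). OD eyes are
generated mirrored so the left-eye-frame truth equals the nominal angle.
The analytic surface is sampled at the 49 B-scan row positions and at the
512 A-scan columns; segmentation noise is additive Gaussian per grid cell,
iid by default. An optional lateral correlation length turns the noise into
a smooth random field; this displaces the traced contour in coherent lobes
and roughly quadruples angle-recovery errors at the same SD, which is worth
knowing when modelling systematic (rather than random) segmentation error.

Cohort generation draws per-subject bump parameters from group-level
distributions seeded per subject from a master seed. Defaults emulate the
clinical cohort structure the pipeline targets: 39 ERM eyes (thicker base
≈ 21.7 px ≈ 84 μm, axis ratio 1.54 ± 0.37, axis −1.3° ± 29°, stronger
irregularity) versus 21 fellow control eyes (base ≈ 14 px ≈ 54 μm, axis
ratio 1.51 ± 0.35, axis −6.3° ± 22°). Irregularity is low-frequency (3–4
lobes): real ERM contours are irregular at large scale yet restorable by
five harmonics — that is what lets them pass the QC gates — and the
amplitude distributions are calibrated so the *measured* group means land
near circularity 0.79/0.85 and area ratio 0.74/0.76 (ERM/control), with QC
exclusions rare. Cohort segmentation jitter defaults to 0.5 px: surfaces in
the emulated workflow are manually corrected, and larger jitter combined
with strong ripple pushes image-measured hull ratios past the 1.2 gate at a
rate far above clinical QC exclusion rates.

MCHART scores are generated with a controllable link: log(MH/MV) is drawn
with a target correlation ρ (default −0.47) to the standardized ground-truth
area ratio, MV log-normally, MH = ratio × MV; both scores are clipped to the
chart range [0, 2], quantized to 0.1 steps, and zeroed below the 0.2° chart
minimum. Control eyes score 0. The link only needs to produce a
controllable correlation sign and magnitude; it is not a perceptual model.

### What the generator does not emulate

Speckle, B-scan registration error, RPE curvature and tilt, pseudo-hole and
lamellar-hole morphologies, fovea decentration beyond the configurable bump
center, and any realistic psychophysics of the MCHART. Passing tests
therefore show that the measurement chain recovers known geometry and known
statistical structure under the stated noise model — not that it is robust
to every artefact of clinical OCT.

## Numerical choices and degenerate inputs

- Sub-pixel iso-contours (not pixel-boundary tracing): staircase boundaries
  would bias the perimeter, hence circularity, upward by several percent.
- Contours are stored with positive shoelace orientation; degenerate
  slivers (< 8 vertices, zero area — e.g. a clipped corner fragment) are
  skipped in the level scan and recorded in the diagnostics.
- Histogram mode ties break low; an all-zero height image yields reference
  level 0 with a warning.
- The per-subject "ONL height" statistic defaults to the reference-plane
  level in μm (the background layer thickness); `mean` and `max` of the map
  are selectable alternatives.
- Zero-variance vectors raise explicit statistics errors rather than
  returning NaN silently; cohort tables degrade gracefully (NaN cells,
  logged warnings) when a subset is too small.
- Welch's t is the default two-group test: group variances differ in the
  emulated cohorts and Welch is the safer parametric choice.

## Problem sizes used in the verification suite

Analytic fixtures use 1024–2048-point polygons; oracle comparisons use 50
random convex fixtures rasterized at 512²; recovery sweeps use 18 noiseless
(θ from −80° to 80°, axis ratios 1.2 and 2.0) and 8 noisy (2-px noise,
ratios 1.3/1.5) rendered eyes; statistical calibration uses 1000 null
replicates and 100 linked-cohort replicates at n = 39 (metadata-only fast
path); the end-to-end acceptance run analyzes a full 39 + 21 cohort.

## Known limitations

- The ONL-B level is the lowest admissible one; on clean synthetic bumps
  this sits just above the reference plane, so the reported RPE-to-ONL-B
  distance (~90 μm on default cohorts) is governed by the synthetic base
  thickness, not by the ~150 μm typical of clinical eyes whose lower levels
  are rejected by the irregularity criteria.
- A single macular region is assumed (one connected ONL-B); multi-focal
  deformations are out of scope.
- Angles are undefined in the isotropic limit: for axis ratios below ~1.1
  the fitted θ is dominated by residual irregularity, which is why recovery
  guarantees are stated for ratios ≥ 1.2 (noiseless) and ≥ 1.3 (noisy).
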