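# Methods

## The measurement model

A breast tumor imaged by ABUS is represented by its coronal slice stack.
The pixel method estimates volume by the Cavalieri principle: if
*A(z)* is the cross-sectional area at coronal depth *z* and slices are
*t* cm apart, then *V* = Σᵢ *Aᵢ* · *t* approximates ∫ *A(z)* d*z*. Each
*Aᵢ* is measured planimetrically: *Aᵢ* = *nᵢ* · *r*, where *nᵢ* is the
number of raster pixels inside the drawn outline and *r* the calibrated
cm²-per-pixel ratio. The sum carries no end correction — each slice is a
prism of its measured area — so the discretization error is *O(t)* at
the tumor poles and *O(t²)* elsewhere (the slice plane sits at the
layer's mid-height, making the interior sum a midpoint rule).

The comparator is the caliper volume *L*·*W*·*H*/2. For a true ellipsoid
with semi-axes (*a*, *b*, *c*), calipers give 4*abc* while the true
volume is (4/3)π*abc*; the ratio true/caliper is therefore exactly
π/3 ≈ 1.047. This closed form is the analytic analogue of the ≈1.07 mean
pixel/traditional ratio observed on real lesions and anchors the phantom
recovery tests.

## Calibration

Two routes to *r* are provided, because an in-image scale annotation can
be read either as a bar (length ratio = cm/px, area ratio its square) or
as a filled reference square (area ratio = known area / pixel count,
length ratio its square root). On the same image they agree; both are
exposed and the choice is the caller's. Scale extents may be sub-pixel:
quantizing bar endpoints to the grid would bias fine-pitch calibrations.
Automatic bar detection (`detect_scale_bar`) is deliberately minimal — a
longest-run scan on a known row — and intended for images rendered by the
phantom module, where the bar location is controlled; clinical images
are calibrated from caller-supplied extents.

## Rasterization semantics

Hand-drawn outlines arrive as polygons; an image editor's region
selection is not reproducible bit-for-bit, so the package fixes its own
deterministic fill rule: a pixel is counted iff its center lies inside
the polygon under the even-odd (ray-parity) rule, with boundary ties
broken half-open (left/top inclusive, right/bottom exclusive). This is
standard scanline-fill semantics; abutting regions tile without double
counting, and a disc of radius *R* rasterized at pitch *p* ≤ *R*/50 has
< 1% area error. Self-intersecting outlines (hand tracings can
self-touch) are filled under the same even-odd rule with a warning
rather than rejected. The analytic shoelace area is computed only as a
diagnostic; the measurement path is the pixel count, which is the method
under study. The vectorized rasterizer is verified against a brute-force
per-pixel point-in-polygon oracle on random polygons in the test suite.

## Caliper extraction from masks

"Largest diameter" is not algorithmically specified in clinical
practice, so the package defines: length = maximum chord over the corner
points of the occupied pixel footprints (each pixel occupies its full
unit square — a 10-pixel-wide block spans 10 pixel widths), maximized
over coronal slices via the convex hull; width = the perpendicular
extent of the same slice's footprint; height = number of occupied
slices × thickness, matching the layer model of the volume sum. The
footprint convention overestimates each continuous diameter by up to
about one pixel, and the height rounds 2*c* up to a whole number of
slices; phantom tests therefore use a per-phantom discretization
tolerance of 1.5*p*/(2*a*) + 1.5*p*/(2*b*) + *t*/(2*c*) + 1% when
asserting the π/3 ratio.

## Agreement statistics

* **Wilcoxon signed-rank.** Absolute differences are mid-ranked; W₊ and
  W₋ are the rank sums by sign, conserving W₊ + W₋ = n(n+1)/2. Zeros are
  dropped by default (classical test); the Pratt policy (rank zeros,
  discard their ranks) is available because the inter-observer pixel
  data contain two zero differences and the choice changes the result —
  the published p-values are therefore treated as policy-dependent
  diagnostics, not reproduction targets. Exact two-sided p enumerates
  the 2ⁿ sign assignments (computed by convolving the rank generating
  polynomial, identical to enumeration but polynomial-time) when n ≤ 25
  and the nonzero |d| are tie-free; otherwise a normal approximation
  with tie correction (Var = Σrᵢ²/4) and 0.5 continuity correction is
  used. The implementation is cross-checked against brute-force
  enumeration and against `scipy.stats.wilcoxon` in the tests.
* **Bland-Altman.** Bias = mean difference, SD with n−1 denominator,
  limits bias ± k·SD with k = 1.96 by default; points outside the limits
  are flagged by lesion label. By a Chebyshev-type argument at most
  (n−1)/k² points can fall outside sample-moment limits; for Gaussian
  differences coverage is ≈95% at k = 1.96 (verified over 1,000
  simulated panels).
* **Ratio statistics** use per-pair ratios with a mean ± 2·SD interval
  (k = 2, not 1.96, matching the convention of the published interval).
* **Quartiles** use the nearest-order-statistic rule. This convention
  was selected before the tests were frozen by checking which of numpy's
  quantile rules reproduces the published quartiles from the study
  table, and is pinned as the package default.

## The study table

The packaged CSV holds the published per-lesion table: 42 lesions, ages,
tumor lengths, and four volumes each (two physicians × two methods) with
the printed absolute inter-observer differences. Loading verifies a
SHA-256 checksum, the record count, and that each printed difference
equals |d1 − d2| within print rounding. `reproduce_all()` recomputes
every summary statistic under the pinned conventions — differences
oriented Doctor1 − Doctor2, ratios on physician-averaged volumes (both
conventions were checked against the printed values; only these match) —
and reports each with the published value and a match verdict at half a
unit in the last printed digit. Two published items are flagged rather
than matched: the age summary (the printed mean/range is internally
inconsistent with the table itself) and the ratio interval's lower bound
(printed as 1.073 − 2·0.266 on rounded values; full precision gives
0.540 vs the printed 0.541).

## Phantoms

The phantom module generates coronal mask stacks with ground truth known
by construction, emulating the study's conditions: lesion long diameters
in the 1–5 cm inclusion range, 0.1 cm default slice spacing, and
well-defined boundaries. An `ellipsoid` has volume (4/3)π*abc*. A
`perturbed_ellipsoid` multiplies each coronal radius by a band-limited
harmonic series ρ(θ) = 1 + Σₘ εₘ cos(mθ + φₘ) with seeded coefficients
scaled to a requested RMS amplitude; because every coronal area scales
by exactly (1 + Σₘ εₘ²/2), the true volume stays in closed form. A
voxel-sum oracle at 4× finer pitch cross-checks that closed form in the
tests. Observer outlining variability is modelled by `perturb_contour`:
radial Gaussian displacement of contour vertices, smoothed circularly
over a correlation length so neighbouring errors are correlated, with
self-intersecting draws retried at damped amplitude. The noise amplitude
is a tuning parameter, not a claim about physicians — no quantitative
observer model is available.

What the phantoms do **not** emulate: ultrasound speckle and texture,
ill-defined (malignant-type) boundaries, segmentation ambiguity, or any
acquisition physics. Passing phantom tests therefore demonstrates the
correctness of the geometry and statistics pipeline, not clinical
performance on real lesions.

## Problem sizes and numerical choices

Phantom tests and the acceptance script use 0.02 cm pitch and 0.05 cm
slices over six seeded ellipsoids (volume recovery < 2%, typically
< 0.1%), and 0.01 cm pitch for single-phantom convergence checks —
sizes at which every check runs in seconds while the discretization
error sits well below the asserted tolerances. Degenerate inputs are
policed: phantoms smaller than one pixel or slice, all-empty mask
stacks, all-zero difference vectors (reported as a degenerate test with
p = 1 rather than an error), non-positive ratio denominators, and
corrupted fixtures all raise typed exceptions from `abusvol.errors`.

## Known limitations

* The rasterizer's pixel counts will not match any particular image
  editor's anti-aliased selection; editor-derived counts are treated as
  inputs, not reproduction targets.
* Caliper extraction assumes the coronal slicing of the mask stack is
  axis-aligned with the anatomical axes; oblique tumors are measured in
  the slice frame, as on the clinical system.
* No interpolation between slices and no partial-volume handling at the
  tumor poles, matching the clinical protocol's plain slice sum.
* DICOM ingestion, automatic segmentation, and 3-D surface
  reconstruction are out of scope.
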