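# Methods

## Model and assumptions

The estimator treats a cell as a solid of revolution: the 3D shape is assumed
to be generated by rotating the visible silhouette's half-width profile
around the putative symmetry axis, so the hidden depth at every axial
position equals the visible width there.  Under this assumption two results
combine into a single closed form:

1. An ellipsoid occupies exactly two thirds of its circumscribed elliptic
   cylinder, giving V = (2/3)·A·d for a silhouette of area A and width d
   (the cylinder's cross-section is the silhouette, its height the hidden
   depth ≈ d).
2. Real cross-sections are not ellipses.  The coefficient of unellipticity
   U = sqrt(A/E), with E = π·l·d/4 the area of the ellipse sharing the
   silhouette's length and width, rescales the estimate by the square root of
   the areal excess or deficit — the square root because the departure acts
   on the visible section but is assumed to act equally on the hidden one.

The product is V = (4/3)·A·sqrt(A·d/(π·l)).  Exactness holds for every
ellipsoid of revolution (U = 1); for other convex solids the error is a
closed-form constant of the shape family, independent of aspect ratio and
scale: −4.22 % for cylinders (16/(3π^1.5) − 1), +1.59 % for cones, +4.27 %
and +2.80 % for the solids of revolution of y = x² and y = x⁴.  For the
stadium (cylinder with hemispherical ends) the error varies from 0 (sphere
limit) toward the cylinder's −4.22 % asymptote; over aspect ratios 1–5 it
spans [−3.91 %, 0] with mean −3.26 % and sample SD 0.82 %.

Key failure mode: branched or deeply concave silhouettes, where no solid of
revolution resembles the cell.  The concavity index 1 − A/ConvexArea flags
these; above the routing threshold (default 0.2, strict inequality) the
package labels the object `distance_map_recommended` and marks the estimate
unreliable rather than suppressing it.  Curved (bent-axis) cells are also
outside the model unless length is measured along the curved axis, which this
package does not attempt: automated skeleton-based curved-length measurement
is known to be fragile, so curved cells simply carry the straight-axis bias.

## Comparators

- Prolate spheroid: V = (π/6)·l·d², the classic nano-eukaryote formula.  It
  ignores A entirely; its errors on non-spheroidal shapes are large
  (−33.3 % on cylinders, +100 % on cones).
- Slice integration: the silhouette is cut into n slabs of width Δ and the
  volume is Σ π·hᵢ²·Δ with hᵢ the half-width sampled once per slab.  For
  circular cross-sections the package reproduces the hand construction used
  in the original validation: right-endpoint sampling, 20 slabs of width 0.1
  across a unit circle (abscissae −0.9, −0.8, …, 1.0).  Arbitrary profiles
  use midpoint sampling by default, with a `shift` parameter to displace the
  whole point set.

## Conventions and parameters

- Measurements: A > 0, l ≥ d > 0, A ≤ l·d.  Inputs with d > l are rejected
  (`AxisOrderError`) rather than silently reordered; `normalize_axes` is the
  opt-in swapper.  The bounding-box check carries a 2 % relative slack
  because pixel-centre measurement of a rasterised rectangle shortens l and d
  by about one pixel each without reducing A; exact-geometry callers never
  notice it.
- Routing threshold: 0.2 on the concavity index, strict (an index of exactly
  0.2 keeps the closed form).  No universally correct value exists — strictly
  axisymmetric but indented shapes can exceed it — so it is exposed as a
  parameter (`--routing-threshold`).
- Width convention (image pipeline): the default `perpendicular` mode
  measures the maximum extent perpendicular to the putative symmetry axis.
  The axis direction is estimated from the region's second central moments
  (best-fit-ellipse orientation) rather than from the endpoints of the
  max-Feret chord: on blunt elongated shapes the extreme-pixel pair that
  realises the maximum caliper distance can tilt off-axis by pixelation,
  which would inflate the perpendicular extent by several percent, while the
  moment axis is stable to single-pixel effects and coincides with the
  symmetry axis in the continuous limit.  `min-feret` mode instead reports
  the smallest caliper width, the convention of common image-analysis
  software; the two differ for asymmetric shapes (e.g. a cone's min-Feret is
  its slant height projection, not its base).
- Feret diameters are computed on the convex hull of boundary-pixel centres
  (all-pairs over hull vertices for the maximum; minimum over edge-normal
  extents for the minimum).  A pixel belongs to the silhouette when its
  centre is inside; hull and perimeter use pixel centres, a sub-pixel bias
  far below the 1 % tolerances at the recommended ≥ 200 px object widths.
- Connectivity defaults to 8-neighbour; holes are filled before area
  measurement (a vacuole does not reduce cross-sectional area) with an
  opt-out.
- Exactness tolerance: closed-form identities are asserted to 1e−12 relative;
  everything in the core estimators is arithmetic on floats, with no
  iteration except the root bracketing (Brent) used to locate error-level
  crossings (tolerance 1e−6 in aspect ratio).

## Phantoms and what validation does and does not show

The phantom generator produces analytic solids of revolution with closed-form
cross-section area, volume and half-width profile, plus a pixel-centre
rasteriser.  These phantoms define the validation conditions: noise-free,
axis-aligned (for analytic measurements) binary silhouettes with exactly
known ground truth.  Consequences:

- Passing the analytic tests shows the estimator's mathematical properties
  (exactness on spheroids, constant shape-family errors, sweep statistics),
  not robustness to staining, focus, or segmentation errors in real
  micrographs.
- The raster pipeline tests (accuracy < 1 % at ≥ 200 px width, rotation
  stability < 1.5 %) cover pixelation effects only; real images add optical
  blur and thresholding uncertainty that the generator does not emulate.
- Two protist-like outline families (named after *Peridinium* and
  *Ceratium*) have no published proportions; they are constructible only
  with a user-supplied profile, fall back to numerical quadrature for their
  areas/volumes, and carry no asserted numbers.
- Cap proportions of the composite shapes (cylinder with conical ends, cone
  with hemispherical end) are likewise unpublished; the default cap length
  is d/2, exposed via `extra_params`.  Validation targets use only shapes
  whose errors are proportion-independent or fully specified.

The shifted-point study samples n ∈ {5, 10, 20, 30, 40, 50, 100} equidistant
slices and displaces the whole set through 11 positions: the midpoints plus
five steps of one tenth of the spacing toward each side.  For the y = x²
solid the slab integrand is linear in the axial coordinate, so the midpoint
position is exactly optimal and the 11 absolute errors take the closed values
{0, 4, 8, 12, 16, 20}·(5/n) %, giving mean 120/11·(5/n) and sample SD
(n−1 denominator) 6.71·(5/n) %.  For the y = x⁴ solid the integrand is
concave and the midpoint position retains a small positive residual
(+0.69 % at n = 5); its worst-shift errors (17.54 % at n = 5) agree with the
published study, while the published zero minimum corresponds to centring the
shifts on the exact optimum instead — that alternative convention, however,
contradicts the published maximum, so the midpoint convention is used
throughout and only convention-independent quantities are compared for this
shape.

One published figure deserves a note: the aspect ratio at which the stadium's
error magnitude reaches 4 %.  The error curve approaches its −4.22 %
asymptote so flatly that the crossing is extremely sensitive to the level:
the exact |error| = 4.000 % crossing sits at AR ≈ 6.47, while the error first
*rounds* to 4.00 % (two decimals) near AR ≈ 6.36.  The package computes the
exact crossing by root bracketing and the reproduce report shows both values.

## Problem sizes

All validation is closed-form or low-dimensional: sweeps use 1,000 aspect
ratios, slice studies at most 100 points × 11 shifts, and pipeline tests
rasters of a few hundred pixels per side — the full suite and the
reproduction script each run in seconds on one CPU, with no randomness
anywhere in the computation.

## Known limitations

- Single-view inference is fundamentally underdetermined: the method assumes
  the hidden depth equals the visible width everywhere; flattened
  (dorsoventrally compressed) cells are systematically overestimated.
- The concavity criterion is a heuristic trade-off: some strictly
  axisymmetric shapes (e.g. chains of discs) exceed 0.2 yet would be
  estimated well by slice integration.
- Length along the maximum Feret diameter slightly overestimates the axis of
  shapes with oblique corners (a rectangle's max Feret is its diagonal);
  this is inherent to the Feret convention and shared with standard
  image-analysis software.
- The distance-map method referenced by the routing label, and the classic
  perimeter-based prokaryote formulas, are not implemented; the estimator
  registry accepts third-party callables with the measurement contract.
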