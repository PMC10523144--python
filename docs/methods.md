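# Methods

## The relative-radius model

The package quantifies where hormone-positive cells sit within an islet by a
single per-pixel statistic. Given an islet boundary polygon with vertices
`v_1 … v_n` (pixel coordinates, drawn or supplied by the user) and a set of
detected pixels, the computation proceeds:

1. **Center.** The polygon center is the arithmetic mean of the vertex
   coordinates (default). An area-weighted (shoelace) centroid is available
   via configuration; the vertex mean is the simpler reading, is invariant
   under cyclic relabeling of the vertex list, and is the quantity the
   angle-sorting validity rule presupposes. For realistic, roughly convex
   islet outlines the two differ by a fraction of a pixel.
2. **Polar transform.** Every coordinate — polygon vertices and detected
   pixels — is expressed as `(θ, r)` about the center. θ is measured from the
   positive x-axis in image coordinates (origin top-left, y down) and
   normalized to `[0, 2π)`; a point exactly at the center receives θ = 0 by
   convention (its radius, and hence its relative radius, is 0 regardless).
3. **Validity.** The vertex angles must be weakly monotonic — increasing or
   decreasing — *up to one cyclic wraparound*, with a tolerance of 1e-9 rad.
   The wraparound allowance matters: a convex polygon entered from an
   arbitrary start vertex has exactly one angle wrap, and raw monotonicity
   would wrongly reject it. Invalid polygons (possible for strongly concave
   or self-crossing outlines) make the radial projection ambiguous; they are
   repaired by sorting vertices by ascending angle (ties broken by ascending
   radius, deterministically), the repair is flagged in the per-islet record
   and a warning is emitted, since the analyzed shape no longer equals the
   drawn one.
4. **Boundary projection.** `r_boundary(θ)` linearly interpolates vertex
   radius as a function of vertex angle between the two vertices bracketing
   θ, wrapping circularly between the last and first vertex. This is a
   *definition choice*, not an approximation bug: for a square it yields a
   constant-radius boundary through the corners (√2 for the unit square at
   every angle), where an exact ray-edge intersection would trace the edges.
   The two constructions converge as the vertex count grows; for a regular
   256-gon they agree to better than 0.5 %. The exact-intersection variant
   exists only as a clearly named oracle in the test suite, so the shipped
   package has exactly one definition of the statistic.
5. **Relative radius and summary.** `rel_radius = 100·r/r_boundary(θ)` per
   pixel. The per-islet mean covers radii ≤ 100 % only — exactly 100 %
   (a pixel on a vertex) is included; values > 100 %, which arise when an
   invalid polygon was repaired, are excluded and their percentage reported
   so the effect of the repair is visible. Detected pixels outside the
   polygon (detection runs on the whole image) are discarded before the
   radius computation and logged; they are conceptually different from the
   \>100 % exclusions and never enter `pct_excluded`. An islet with zero
   detected pixels is flagged `excluded_no_staining` with a missing (NaN)
   mean — averaging it as 0 would fabricate a maximally central phenotype.
6. **Relative area.** A raster pixel belongs to the islet when its center
   `(x+0.5, y+0.5)` lies inside the polygon by the even-odd rule;
   boundary-grazing centers count as inside. The rule is deterministic and
   cross-checked against shapely's `covers` in the tests. Relative area is
   `100 · n_cell_pixels / n_islet_pixels`.

## Detection

Detection is pure thresholding, with no pre-blur and no morphological
cleanup by default (an optional minimum connected-component filter can be
enabled). IHC images are converted to HSV; a pixel is positive iff its
triple lies in a configured box whose hue interval may wrap through 0°. The
shipped box (hue 0–50°, saturation ≥ 0.2, value 0.1–0.95) describes an
earthy red-brown DAB chromogen and is a heuristic starting point — staining
intensity varies by batch and antibody, and users are expected to tune it.
IF images are grayscale; a pixel is positive iff its normalized intensity is
≥ a threshold, by default computed per image with Otsu's criterion (a fixed
level is configurable). A constant image has no Otsu threshold and yields an
empty mask with a warning.

## Numerical choices

- The angular interpolation is implemented as an explicit
  `r0 + (θ−t0)·(r1−r0)/(t1−t0)` over a wraparound-extended, angle-sorted
  vertex table rather than through `np.interp`, so that the vectorized core
  and a scalar-loop reference implementation execute the identical IEEE
  operations; the test suite asserts bit-for-bit agreement on 1,000 random
  convex polygons.
- Vertices at exactly equal angles would make the interpolation ill-posed;
  after sorting, only the first (smallest radius) of an exactly-equal-angle
  run is kept.
- Consecutive duplicate vertices (including a closing repeat) are dropped on
  polygon construction; fewer than 3 distinct vertices, or a polygon
  enclosing no raster pixel centers, is a degenerate-polygon error.
- θ normalization guards against floating-point `mod` returning exactly 2π.

## Synthetic data generator

The generator renders islets with ground truth known by construction: a
boundary polygon (regular n-gon, default 256 vertices ≈ a circle, radius
80 px in a 201×201 px frame; optionally radially jittered or explicit) and
filled-disc "cells" (default radius 2 px, 40 per islet) placed at a chosen
fraction of the boundary radius in a chosen or uniform-random direction.
Blob centers use the same angular-interpolation boundary radius the analysis
measures, so the intended fraction is exactly the statistic the pipeline
should recover, up to the spatial extent of the disc — the recovery
tolerance is 2 percentage points for circle-like polygons and 5 for
perturbed ones. Three cohort phenotypes emulate the biological regimes the
statistic is meant to separate: `mantle` (fractions ~ U(0.85, 0.95), the
healthy rodent periphery), `core` (~ U(0.2, 0.4), the center-shifted
arrangement of impaired glucose tolerance) and `diffuse` (area-uniform,
fractions ~ √U(0,1), expected relative radius 2/3 on a disc).

IHC blobs sample HSV colors strictly inside the default detection box with a
margin against 8-bit quantization, on a pale bluish background outside the
box on both the hue and saturation axes; IF blobs are bright (0.85) discs on
a dim (0.10) background. Optional additive Gaussian noise is clipped to the
valid range and defaults to 0, so rendered images match the ground-truth
positivity map pixel for pixel.

What the generator does **not** emulate: optical point-spread, uneven
illumination, staining gradients, hematoxylin nuclei texture, touching
islets, or exocrine tissue that resembles weak staining. Passing tests
therefore demonstrate the correctness of the geometry, detection and
bookkeeping on images whose decomposition into foreground and background is
unambiguous — not detection robustness on difficult histology, which in
practice is governed by the user-tuned thresholds and by the manual
exclusion of islets indistinguishable from exocrine tissue.

## Problem sizes

The test suite and the acceptance script work at desk scale, chosen so a
full run completes in about a minute: cohorts of 20 islets (50 for the
diffuse phenotype, where the cohort mean is compared to the analytic 2/3
expectation), 40 cells per islet, 201×201 px frames, and 1,000 random
polygons for the oracle-equivalence sweep. All simulations are seeded and
deterministic end to end; two identical analysis runs produce byte-identical
CSVs (run metadata with the timestamp lives in a separate XLSX sheet).

## Known limitations

- The angular-interpolation boundary under-reaches the true edges of
  low-vertex-count polygons; users should trace islet outlines with
  generously many points (the interactive tools this package's sidecar
  format replaces produce dozens to hundreds).
- The relative radius is a star-shaped-geometry statistic: for strongly
  concave islets the angle-sorted repair changes the shape, and the reported
  excluded percentage should be inspected before trusting the mean.
- Per-pixel averaging weights large cells more than small ones; no
  per-cell (connected component) aggregation is performed.
- Multi-page TIFFs are truncated to their first page, with a warning.
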