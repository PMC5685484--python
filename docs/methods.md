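# Methods

## Coordinate and measurement conventions

All geometry lives in 2D Cartesian µm coordinates with y increasing toward the
pial (superficial) surface, so "depth", "crown" and "fundus" are unambiguous.
Polygon areas are unsigned (shoelace, via shapely): the measures are sizes,
not orientations. Landmarks are annotations snapped to the nearest contour
vertex within a tolerance (default 1 µm; the phantom generator widens this to
two vertex spacings, since its landmarks lie on the analytic curve between
vertices). An annotation farther than the tolerance is an error; a crown that
is not a local height maximum (or a fundus not a minimum) only warns, because
a tilted section can legitimately violate the heuristic.

The three folding scores are purely geometric:

- local GS = area of the polygon formed by the pial contour from the SSS
  fundus to the LS fundus, closed by the straight fundus-to-fundus chord;
- local SD = perpendicular distance from the SSS fundus to the **infinite
  line** through the SSG and MEG crowns. The segment construction presumes the
  perpendicular foot lies between the crowns; if it does not, the value is
  still returned but a warning flags the pathological geometry;
- local GI = pial arc length between the crowns ÷ crown-to-crown chord length.
  On a closed contour the arc is the shorter of the two directions.

Under rigid motions all three are invariant; under uniform scaling by s they
scale as s², s and s⁰ respectively (property-tested). Ratios are computed per
section (electroporated / contralateral), averaged over serial sections to one
value per animal (three sections per animal by default), and groups are
summarised as mean ± SEM (or SD, per-metric configurable) across animals.
Which sections to include is left to the analysis manifest; the package does
not pick sections.

Input areas are treated as hole-free simple polygons; a region containing a
ventricle cross-section must be outlined around it. Self-intersecting input
is rejected with the first crossing segment pair named.

## Thresholding

Both automatic thresholds operate on a 256-bin histogram spanning the declared
bit depth (8 or 16; the bin width is 2^depth/256). A threshold t classifies
bins ≥ t as foreground.

- **Intermeans ("Default")**: iterate t ← round((μ_below + μ_above)/2), where
  μ_below / μ_above are the mean levels of the histogram mass below / at-or-
  above t. Candidates are confined to the occupied level range so both side
  means stay defined; on that range the update map is monotone into itself, so
  a fixed point always exists and the iteration reaches one. A 2-cycle, if one
  ever arose, would be resolved by averaging the cycle's levels and rounding
  down. A single-level histogram returns that level with a degenerate warning.
  This is a deterministic, testable fixed-point rule in the IsoData family; it
  is *not* claimed bit-identical to any particular ImageJ build, whose
  "Default" lineage varies across versions.
- **Maximum entropy (Kapur)**: exhaustive maximisation over all levels of the
  summed Shannon entropies of the normalised background and foreground
  distributions, ties broken toward the lower level. Note that on a symmetric
  bimodal histogram the criterion is numerically flat on a plateau straddling
  the midpoint, so the tie-break deterministically returns the plateau's
  lowest level rather than the midpoint itself.

Both are verified against independent brute-force scans over all 256 levels on
random histograms.

## Cell detection and densities

Manual click-counting is replaced — the one intentional methodological
substitution, made for reproducibility — by: binarise at the chosen automatic
threshold, label connected components with 8-connectivity, drop components
below a minimum area (default 20 px at 1 µm/px, rejecting sub-nuclear specks
for ~5 µm nuclei), and keep centroids inside the region of interest. Touching
cells merge into one component; this undercount is a documented limitation of
connectivity-based counting, not corrected by watershed splitting. Counts are
invariant under monotone affine intensity rescaling (bin order preserved).

Density is count / polygon area, reported per 1000 µm². Zone thickness is
polygon area / tangential length, where the tangential length is the arc
length of the zone's mid-band axis (the average of inner and outer boundaries
at matched arc-length fractions; the phantom provides this axis analytically).
Cells per 10-µm strip = density × thickness × 10 µm, i.e. the strip is taken
to span the full zone thickness. Germinal zones are checked (report-only) for
pairwise disjointness and ventricular→pial ordering VZ → ISVZ → OSVZ → IZ by
centroid height.

## Band straightening and tangential profiles

A curved band (e.g. the OSVZ) is resampled into a rectangle by fitting a
spline through its centerline vertices (interpolating by default; a smoothing
parameter is exposed), re-parameterising by arc length, and sampling the image
by bilinear interpolation along unit normals at one-pixel steps, out to
±half_width. Samples beyond the image are zero-filled and masked. Where the
radius of curvature falls below half_width, normals cross; the affected
tangential positions are masked with a warning rather than averaged — a
conservative choice, since averaging folded samples would fabricate intensity.
Sample coordinates within 1e-9 px of the pixel grid are snapped to it, so a
straight axis-aligned band reproduces the source crop exactly.

The tangential profile is the **mean** (not the sum) intensity per tangential
position over the valid normal extent — the mean is invariant to how much of
the band thickness is sampled; fully masked positions are reported missing
(NaN). Background subtraction is a constant estimate, by default the 10th
percentile of the input — appropriate when most of the field is unstained —
with an explicit level as the alternative; a rolling-ball filter is out of
scope. The intended order of operations is subtract on the full image first,
then straighten and profile: a low percentile of the extracted band alone
would sit inside the signal and over-subtract. Modulation depth is estimated
by least-squares fit of c₀ + a·cos(2πs/P) + b·sin(2πs/P) at the known period
P, with m̂ = √(a²+b²)/c₀.

## The phantom generator

The generator emulates the *measured structure* of a two-hemisphere coronal
section, not its biology. Per hemisphere the pial contour is

    y(x) = a · Σₖ sₖ · exp(−(x − cₖ)² / 2σ²)

with ridges (s = +1) at the SSG and MEG crown positions and troughs (s = −1)
at the SSS and LS fundi, σ = 0.15 × the crown spacing (Gaussians give smooth,
quadrature-friendly arc lengths; the fold shape itself is a modelling choice,
as no canonical one exists). The contralateral hemisphere is the mirror image
(x → −x) with its own amplitude. Landmarks sit at the analytic extrema of the
summed profile — found by bisection of y′, and independent of amplitude since
y ∝ a. Default dimensions approximate a postnatal ferret suprasylvian gyrus:
6 mm of tangential extent, landmarks 0.9–1.2 mm apart, fold amplitude 600 µm
(SSS depth ≈ 1.2 mm), layer thicknesses 350/150/200/250 µm (L2/3–L6), zone
thicknesses 100/150/400 µm (VZ/ISVZ/OSVZ), and progenitor rates of a few
cells per 1000 µm², chosen to match the depth scale and the reported
per-strip counts of ferret-style germinal zones.

Zones and layers are axis-aligned stacked bands (zone stack rising from a
fixed ventricular floor at 3000 µm depth, layers hanging 200 µm below the
deepest fundus); a spec whose amplitude plus band stack exceeds the available
depth is rejected as geometrically impossible. Cell patterns are homogeneous
Poisson per zone and marker, drawn by rejection from the bounding box. The
OSVZ raster follows a gently curved sine centerline (amplitude 120 µm over
3 mm); inside the band the signal is I₀(1 + m·cos(2πs/P)) with s the
centerline arc length (I₀ = 100, m = 0.3, P = 750 µm by default), plus a
constant offset (10) everywhere and Gaussian noise (σ = 2), quantised to
16-bit. The band is delimited by vertical rather than normal distance to the
centerline — at the shallow slopes used (≤ 0.25) the thickness distortion is
≤ 3% and does not touch the tangential signal.

Ground-truth GS/SD/GI are computed by trapezoid quadrature of the generating
functions on a grid 10× denser than the emitted contour (default 2000 vertices
per hemisphere, truth at 20 000), which separates discretisation error from
algorithmic error: the pipeline agrees with truth to ~10⁻⁴ relative at the
default discretisation and tightens ~100× at 10× vertices.

Cohorts add multiplicative log-normal jitter — 6% CV between animals and 2%
between serial sections, applied independently per hemisphere and to cell
rates — so side ratios fluctuate realistically around their spec value; these
levels give control-group ratio SDs of a few percent, comparable to the
animal-to-animal spread of published within-section ratio designs. All
randomness derives from one master seed through numpy `SeedSequence` spawn
keys indexed (group, animal, section, channel), making every output
byte-identical for a fixed seed regardless of generation order.

What the phantom does **not** emulate: real fold shapes and asymmetric
sections, staining artifacts and intensity inhomogeneity, clustered (non-
Poisson) cell patterns, annotation error in landmarks and region outlines,
and section-to-section registration effects. Passing tests therefore
demonstrate correctness of the *measurements* under known geometry, not
robustness to histological mess.

## Statistics

Classical equal-variance Student's t (two-sample between conditions;
one-sample against a ratio of 1), two-sided throughout — the conservative
default where sidedness is not specified — with Welch's variant behind a
flag. Significance stars at p < 0.05 and p < 0.01. Zero-variance degenerate
inputs return t = 0, p = 1 when means agree and p = 0 otherwise. No
multiple-testing correction is applied across layers/zones, matching the
source design; the test count is small and the readouts correlated.
Calibration is property-tested: on null cohorts (identical group specs) the
type-I error of both tests stays within binomial 99% bounds of α = 0.05 over
200 replicates.

One phantom-specific caveat: because both GS and SD are exactly linear in the
fold amplitude of this phantom family, their side ratios coincide exactly on
phantom data (both equal a_ep/a_contra up to jitter). This is a property of
the Gaussian-bump geometry, not of the measures; on real contours the two
ratios differ.

## Problem sizes

Defaults were chosen so the full validation runs comfortably on a laptop
core: 2000-vertex contours, 200-replicate Monte-Carlo/calibration ensembles,
10⁶-sample area oracles, and a ~750×180 px intensity raster. All are
parameters, not constants, and scale up freely.
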