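# Methods

This note documents the models, conventions and numerical choices behind
`ricecanopy`, in the order data flows through the package.

## Coordinate and unit conventions

All lengths are centimetres, all angles radians internally (degrees at the
CLI). Pixels are addressed as (column *i*, row *j*) with *j* increasing
downward; calibration maps into a y-up real frame. 3D canopy coordinates
are right-handed with *z* up; each hill has a local frame with its axis at
the origin, and hill (*rn*, *cn*) of a block with row spacing *rs* and
plant spacing *ps* sits at ((*cn*−1)·*ps*, (*rn*−1)·*rs*) — column index
along *x*, row index along *y*. Interval indices are 1-based with the
floor(·)+1 convention, so boundary values fall into the upper interval.

## Calibration

The pixel→real map is one full binary quadratic per axis (12 coefficients),
fitted by ordinary least squares from grid correspondences; at least six
points in general position are required (a lattice with only two distinct
rows leaves the pure quadratic terms unidentifiable and is rejected as
rank-deficient). The fit reports its residual RMSE and checks injectivity
numerically: the Jacobian determinant must keep one sign over all fitted
points, otherwise a warning is raised. The local "pixel pitch" — the real
size of one pixel at a given location — is used throughout as the natural
binning width ε wherever the extraction operators need "a sufficiently
small" tolerance.

## Binarization

Plant/background contrast uses the excess-green gray `G − R/3 − B/3`,
clamped at zero: the clamp suppresses backgrounds redder or bluer than
green, which is the evident intent of the transform. Leaf photos are
thresholded globally by Otsu's method and smoothed with a 3×3 mean filter;
because the filter output is fractional the mask is re-thresholded at 0.5.
Tiller photos span a larger bench area with uneven lighting, so they are
split into 4×4 = 16 equal sub-blocks, each thresholded independently
(edge-padded when dimensions do not divide, cropped back), then smoothed
with a 2×2 mean filter. A sub-block whose contrast is under 5% of the
global range is declared background: Otsu applied to pure background noise
would otherwise label half of it foreground.

## Leaf image analysis

Foreground pixels are mapped to real coordinates, rotated so the principal
axis of the second-moment matrix parallels the abscissa (the tie between
the two ends is broken by putting the end nearer the image's left edge at
the origin), and shifted so the centre of the blade base is (0, 0). Widths
are collected in bins one pixel pitch wide; each bin's width is
max(y) − min(y) plus one pitch, accounting for pixel extent, and the leaf
length is the x-extent plus one pitch (a one-pixel-wide feature thus
reports one pitch, not zero). The half-widths are fitted by a 6th-degree
polynomial; the constant term absorbs the fit residual. The *reported*
maximum width is taken from the fitted polynomial rather than the raw bin
maximum: the raw maximum rides on one pixel of quantization noise, while
the fit averages it away. Blade area is the trapezoid sum of the sampled
full widths.

## Tiller image analysis

The stem is found as a near-vertical corridor. The run of foreground in the
bottom row seeds a track that follows, row by row upward, the run
containing the previous centre; because a stem only tapers with height, the
first width increase beyond pixel noise marks the lowest leaf node, and the
corridor line (least-absolute-deviation fit, solved by iteratively
reweighted least squares) uses only this clean prefix. The corridor then
extends along the fitted line: each row contributes the run the line passes
through, with its local half-width capped at twice the median so leaf bases
merging in at nodes are not swallowed; the stem ends where the line stops
hitting foreground (gaps of up to 5 rows are tolerated). Remaining
connected components of at least 50 pixels are leaves, ordered bottom-up by
their attachment height.

Stem length and the radius profile are binned at one pixel pitch in the
tiller frame (stem vertical, base centre at the origin), again with
one-pitch extent corrections. Each leaf's node is the point nearest the
stem axis (per-bin mean height at the smallest |x|); the midrib is the
per-x-bin mean height, shifted to the node, with the radial coordinate
taken as non-negative outward distance. The two quadratics x(l), y(l) are
fitted by least squares against the cumulative chord length of the binned
midline — at pixel density chord length approximates arc length to well
below the fit residual. Strongly drooping leaves whose image-plane x is
non-monotone fold distinct blade parts into shared bins; such fixtures are
outside the supported regime (see Limitations). Base angle is the angle
between the fitted tangent at l = 0 and the stem axis; dropping angle is
the bend between the tangents at l = 0 and l = L.

## 3D reconstruction

Coordinatograph points are stem *surface* points (r, a, h); each is pulled
inward by the stem radius at its height before the axis is fitted — exactly
for two points, by total least squares (SVD) for more. The axis is
normalized to start on the ground plane with |top − bottom| equal to the
stem length. A leaf node interpolates along the axis at height fraction
y/S_l and moves out by its radial offset in the azimuth direction; this
reduces to the plain (x cos θ, x sin θ, y) form for a vertical stem but
also handles tilted stems consistently. The planar midrib is placed in the
vertical plane of the azimuth through the node, its height run scaled by
the stem-tilt factor z_t/S_l, and — so the blade connects to the stem in
rendered scenes — anchored at the node's height. Blade margins offset the
midrib by ±half-width along the unit normal of the venation plane (cross
product of the first-half and second-half chords); a perfectly straight
midrib falls back to the horizontal unit vector perpendicular to its chord.
Stems render as closed 12-segment cylinders of their mean radius and leaves
as quad strips split into triangles; scenes export as ASCII OBJ or PLY.

## Virtual blade trait extraction

Instead of solving surface–surface intersections, every leaf is divided
into `fnum` fragments on an equal-parameter grid along its midrib; a
fragment carries the trapezoid area of its local full widths and belongs
*wholly* to the interval containing its midrib midpoint. This midpoint rule
makes refinement exact at the fragment level (halving `Dns` and re-summing
interval pairs reproduces the coarse profile bit-for-bit) and conserves
total area to machine precision in every mode.

* **Horizontal slabs**: index ⌊z_mid/Dns⌋+1; density divides by
  Dns·pm·rs·ps (pm = hills aggregated), probability density further by the
  total area.
* **Concentric shells**: the distance is the full 3D Euclidean norm of the
  fragment midpoint from the hill-axis origin, exactly as the interval
  formula prescribes it (the shells are therefore spheres about the hill
  base in this metric, which coincides with cylinder distance for the
  mid-canopy where fragments sit well off the axis); density divides by the
  annulus area π((nD)² − ((n−1)D)²) and pm.
* **Voxels**: each fragment splits into four width-wise strips of a quarter
  of its area, with strip centres interpolated between the two blade
  margins at cross-width weights 1/8, 3/8, 5/8, 7/8 at the fragment's
  along-length midpoint; the vertical index follows the midrib midpoint. As
  printed, the strip-position formula references only one margin, which
  would collapse all four strips onto it; the two-margin interpolation is
  the reading consistent with "divided by the midrib and the two midlines".
* **Azimuth**: the fragment azimuth is atan2 of the horizontal midrib step
  taken mod 2π — algebraically identical to the four-quadrant case table,
  and defined on the axes; a 10⁻⁹-sector snap absorbs interpolation noise
  at exact sector boundaries. Vertical steps fall back to the leaf azimuth.
* **Inclination**: arcsin(|Δz|/chord) ∈ [0, π/2], aggregated as the
  area-weighted mean per interval. Empty intervals report NaN, never 0 — a
  missing value is not a horizontal leaf.

Defaults are `fnum = 100` and `Dns = 5` cm — the combination at which the
profiles are stable (at `fnum = 10` and `Dns = 1` cm the profile jumps
between adjacent intervals several times more than at `fnum = 100`; the
test suite asserts this qualitative regime) — and 36 azimuth sectors of
10°.

## Light distribution

The projection factor A = cos θ_s cos θ_l + sin θ_s sin θ_l cos(φ_s − φ_l)
equals the cosine between two unit directions whose polar angles from the
vertical are θ_s and θ_l. It is signed; the projected area uses |A|, since
a blade lit from behind still intercepts the beam. Each slab's interception
coefficient is LIC = 1 − PSAREA/D, clamped into [0, 1] (a warning reports
clamping). The default normalization D is the ground area of the sampled
block, (rows·rs)·(cols·ps) — an interception coefficient compares
projected leaf area to ground area; the literal plant-count form
plantnum·rows·cols is available behind a switch for comparability. Relative
light at slab n is PAR₀ times the product of LIC over all slabs strictly
above n (Beer-law layering; the top slab receives full PAR₀), which is
non-increasing downward by construction. An empty canopy returns PAR₀ at
every requested level.

## Synthetic canopies and render fixtures

The generator's defaults describe transplanted rice near heading: 20×20 cm
spacing, a 2×4-hill sampling block, 10 tillers per hill and 4 expanded
blades per tiller (module tests use fewer for speed), stem length
N(50, 5²) cm tapering from radius ≈ 0.35 cm by 40%, tilt uniform up to 8°,
blade length N(35, 5²) cm, maximum half-width N(0.7, 0.1²) cm, node heights
uniform in 0.45–0.95 of the stem, azimuths uniform on the circle. Midribs
are quadratics whose tangent turns from a base angle (15–50° off vertical)
at the node to base+droop (droop 10–50°) at the tip; because the tangent
interpolates two unit vectors, the curve parameter stays within a few
percent of arc length, keeping generated truth commensurable with the
chord-length parameterization the image analysis recovers. The half-width
profile is a quadratic lanceolate — 60% of maximum width at the collar,
widest near 0.39 L, straight taper to a sharp tip — chosen both for
realism and because a profile with a flat (higher-order) tip approach
genuinely loses several percent of its length below pixel resolution in
any photograph. Coordinatograph fixtures place surface points radially
outward from the hill axis, the way an operator orients the probe. All
randomness flows through one `numpy.random.default_rng(seed)` per call.

Leaf photos are rasterized by evaluating the blade region in real
coordinates through the true calibration at 2× supersampling (giving
anti-aliased edges) on a 2200×300 px canvas at 0.02 cm/px; tiller photos
use 1800×2200 px at 0.05 cm/px, draw the midrib at a minimum visible
thickness of 2 px where the blade tapers below it, and assign leaves to
image sides by an analytic clearance check so drawn bands do not touch
(when no assignment keeps 0.3 cm of clearance a warning marks the fixture
as occlusion-stressed; such fixtures are excluded from round-trip
accuracy statistics, as extraction through overlapping organs is out of
scope). An optional illumination gradient dims the green channel across the
frame — global Otsu then loses the dim side while blockwise thresholding
does not, which the tests assert on crisply rendered (supersample = 1)
fixtures where recovery can be counted pixel-exactly.

## What the synthetic data does and does not show

Passing round trips demonstrate that the geometry pipeline is
self-consistent: calibration, segmentation, shape/midrib fitting,
reconstruction and trait extraction invert the generator within stated
tolerances (≤2% on leaf dimensions, ≤2° on angles, machine precision on
conservation). Real bench photographs add phenomena the fixtures omit —
specular highlights, soil debris, torn or rolled blades, leaf sheaths,
overlapping organs, lens distortion beyond the quadratic family — so field
accuracy must be validated against physical measurements, as the
underlying technique was. The fragment approximation itself is exact only
in the limit `fnum → ∞`; at the default `fnum = 100` fragments are a few
millimetres long and profile errors from midpoint assignment are far below
the sampling noise of a 10⁵-point Monte-Carlo surface reference.

## Numerical details worth knowing

* Archive CSVs store floats at 17 significant digits; round trips agree to
  better than 10⁻⁶ cm.
* Degenerate inputs: constant images warn and return empty masks; stems
  with all coordinatograph points at one height, nodes above the stem tip,
  sub-3-bin midribs and rank-deficient calibration grids raise typed
  errors; zero-norm venation normals use the documented fallback and never
  raise.
* The small-component filter discards sub-50 px specks during organ
  separation.
* LAD line fits run 30 IRLS iterations with a 10⁻⁶ residual floor.

## Limitations

Leaf sheaths and panicles are not modelled; the blade attaches directly at
the node. Occluded tillers (overlapping leaves in the image plane) are
detected and warned about, not resolved. The light model is direct-beam
only — no diffuse sky, no scattering, no penumbra — and treats each slab's
interception as area-proportional, ignoring within-slab clumping. The
cylindrical blade mode inherits the printed 3D-norm distance, which differs
from true cylinder distance for fragments far above the canopy base near
the axis.
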