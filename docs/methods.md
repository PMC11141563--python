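# Methods

## Model

`crossvol` treats an animal's main body as a stack of *slabs* cut by
parallel planes perpendicular to the sagittal axis.  A slab is bounded
by two fully measured cross-sections (identity segment *d*, area *S*,
perimeter *C*) and subdivided into *n* equal-length *subslabs*; the
silhouette supplies *d* at the n−1 interior subslab stations.  The
modelling assumptions are:

1. the shape ratios φ = S/d² and ψ = C/d vary linearly across a slab
   (between the measured values at its two bases);
2. within each subslab, *d* itself varies linearly (linearity as a
   local approximation — body depth profiles fluctuate irregularly at
   slab scale, but not at subslab scale);
3. sections are parallel and vertical; curved bodies must be
   straightened or sectioned vertically before measurement.

Under 1–2 the section area S(l) = φ(l) d(l)² is cubic in the axial
coordinate l and the circumference C(l) = ψ(l) d(l) quadratic, so the
per-subslab volume ∫S dl, lateral area ∫C dl and first moment ∫S·l dl
are exact polynomial antiderivatives (quartic, cubic, quintic).  All
are evaluated in Horner form to limit cancellation.  Consequences worth
knowing:

- **Cylinder/cone/frustum exactness.**  For constant sections, and for
  linear d with constant φ/ψ, the integrands are exactly polynomial, so
  the estimate is exact for every subslab count (machine precision,
  verified at 1e−12 relative for n = 1…50).
- **Cone mode.**  At an apex d = 0 makes φ undefined; terminal slabs
  flagged `cone` freeze φ and ψ at the measured base and taper d to
  zero.  The constant-ratio antiderivatives integrate the quadratic/
  linear integrands exactly, so cone results are independent of n.
- **Area definition.**  The method's "surface area" is the
  circumference integral ∫C dl.  On tapering solids this is
  systematically below the true slant area (cone r = 1, h = 3: 3π
  versus π√10, about −5.1%); the fixtures store both quantities
  (`method_area` vs `exact_lateral_area`) and accuracy claims against
  true area are made only where the two coincide (untapered solids).

Mass properties: each subslab's mass is its closed-form volume times
the slab density; zero-density ellipsoid voids are subtracted per
subslab interval with the exact ellipsoid-segment antiderivatives
(volume πqr[u − u³/3p²], first moment πqr[u²/2 − u⁴/4p²]), never by
sampling — exactness and determinism were preferred over generality of
void shape.  The centre of mass is reported only as the axial station
of the vertical plane containing it; the method has no transverse
coordinates.  Appendages (fins, limbs) are measured as independent
bodies: they add to volume, area and mass, but are excluded from the CM
because their axial placement is not part of their own measurement
table.

## Comparators

**GDI** slices the body into equal parts (default 120) and treats each
as an elliptical cylinder with semi-axes averaged between its two ends,
read from two orthogonal silhouettes.  The ellipse perimeter uses
Ramanujan's second approximation (relative error < 1e−9 at biological
aspect ratios); its accuracy is tested against the complete elliptic
integral.  On sections of superellipse exponent k the volume bias is
the area ratio π / [4Γ(1+1/k)²/Γ(1+2/k)] — about +10% at k = 1.6 —
which is the quantitative reason the CSM outperforms it on
non-elliptical bodies.

**Superellipse bracketing** builds per-station superellipses
|x/a|^k + |y/b|^k = 1 at both ends of a k range (defaults 2–2.3 for
cetacean-like bodies, 1.6–2.4 general) and integrates section area and
perimeter along the axis by the trapezoidal rule over the profile
stations.  Superellipse area is strictly increasing in k, so any body
whose section exponents lie inside the range is bracketed (up to the
axial-integration error of the trapezoidal rule, which is why the
default profile carries 121 stations).  The point estimate is the
arithmetic mean of the two bounds.  Axial integration here is
station-based rather than per-pixel voxel counting; the difference is
bounded by station density and is negligible at the defaults.  The
hydrodynamic-foil treatment of fins used by some bitmap-based programs
is not implemented; fins are handled as ordinary bodies.

## Silhouette measurement

Masks are binary grids with a physical scale; foreground is nonzero,
the sagittal axis runs along columns unless declared otherwise, and a
station maps to the nearest pixel-centre column.  Identity segments are
inclusive pixel spans ((max − min + 1)·scale) to avoid systematic
half-pixel shrinkage.  Interior holes are filled before measurement: S
and C refer to the outer profile.

Perimeter is the length of a sub-pixel contour polygon (marching
squares at level 0.5), *not* pixel-edge counting, which overestimates
smooth boundaries by up to ~27%.  Contouring raw binary data still
carries a staircase bias of about +2.6% on digitized circles, so the
filled mask is smoothed with a 1 px Gaussian before the 0.5-level
contour is taken; this moves the boundary by well under a pixel and
recovers a digitized circle of radius ≥ 100 px within ~0.3% (the
package asserts 1%).  Regions too small to survive smoothing fall back
to the raw contour.  At slab boundaries the identity segment can be
read from the section mask itself (its full transverse extent), which
the CLI does, using the silhouette value as a cross-check
(`consistency_check`, default 1% tolerance) — the same physical segment
appears in both views, and the section-mask reading is immune to the
half-pixel ambiguity of an exact body-edge station.

## Synthetic validation suite

The fixture generator replaces the third-party 3-D models that a full
empirical validation would need.  Five solid families with closed-form
(or quadrature-grade) truths: cylinder, cone, frustum, constant
superellipse lofts (k = 1.6 "boxy" and k = 2.3), and a body of
revolution r(l) = 0.5 + 0.1 sin(2πl) emulating the irregular
fluctuation of body depth along a real axis.  `sample_measurements`
emulates the data-collection workflow (analytic d/S/C at stations,
optional multiplicative Gaussian noise, one draw per measurement,
seeded); `render_masks` rasterises side views and sections (default
6000×4000 px, reducible) for end-to-end image tests.

What passing these tests shows: the integration engine is exact on
polynomial profiles, converges below 0.5% volume error at 12 slabs ×
10 subslabs on the smooth fixture, and survives the full image
round-trip within 1%.  What they do not show: performance on real
animals, where section acquisition (dissection plane obliquity,
reconstruction subjectivity, soft-tissue uncertainty) dominates the
error budget; the suite has no analogue of those effects beyond the
multiplicative noise model.

## Defaults and numerical choices

| parameter | default | rationale |
|---|---|---|
| subslabs per slab | 10 | error stabilises by ~10 on smooth bodies; cheap to raise (1000 used in the large-body CM example) |
| slabs | 12 | stabilisation point across the validation fixtures; unequal lengths allowed |
| GDI slices | 120 | standard practice for the comparator; discretisation error ~1e−5 there |
| k ranges | 2–2.3 / 1.6–2.4 | cetacean-like vs general-purpose brackets |
| boundary-sharing tolerance | 1% relative on d, S, C | measurement-noise allowance; slabs cut from one figure coincide exactly |
| closed-form vs quadrature tolerance | 1e−10 relative | oracle-equivalence bound used throughout the tests |
| mask resolution | 6000×4000 px | common practice for bitmap silhouettes; tests use reduced resolutions, which the API supports directly |
| units | caller-defined, consistent | no implicit conversion; `rescale_body` normalises total length when wanted |

Degenerate inputs are rejected loudly: shape ratios at d = 0 raise
(cone mode is the remedy), zero-volume subslabs have no centroid, voids
must lie inside the body's axial range, and adjacent slabs must agree
on their shared boundary within the tolerance above.  Sections carry
two soft sanity checks as warnings, not errors, because noisy
measurements may trip them legitimately: C ≥ 2d (the identity segment
is a chord) and the isoperimetric inequality C² ≥ 4πS (1% slack for
rasterised inputs).

## Known limitations

- Sections must be parallel; no curvature correction.
- Lateral area is the circumference integral (see above); do not read
  it as slant area on strongly tapering bodies.
- The CM is a single axial plane; limbs without axial placement are
  excluded from it.
- Raster measurement differs from vector (CAD) measurement by up to
  ~1% at moderate resolutions; the contour smoothing trades a small
  boundary displacement for the removal of staircase bias.
- The superellipse point estimate (mean of bounds) is only as good as
  the centring of the true exponent in the chosen k range.
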