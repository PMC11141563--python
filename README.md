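# crossvol

Body volume, surface area, mass and centre-of-mass estimation for
animals — extant or extinct — from a single-view silhouette plus a
series of cross-sectional profiles.

Estimating body mass volumetrically means reconstructing the animal's
volume and multiplying by an assumed density.  Most two-dimensional
volumetric approaches replace the animal's cross-sections with ellipses
(Graphic Double Integration, GDI) or superellipses; that approximation
breaks down on boxy, keeled or winglike structures.  `crossvol`
implements the **cross-sectional method (CSM)**, which integrates the
*measured* section profiles directly and therefore handles any section
shape, together with the two comparator methods and the synthetic-solid
machinery needed to validate all three.  It is aimed at vertebrate
morphologists and palaeontologists who have (or can reconstruct) a side
or dorsal silhouette and a handful of body cross-sections.

## The method

The body is cut by parallel planes into *slabs*, each bounded by two
measured sections; each slab is subdivided into *n* equal *subslabs*.
Every measured section contributes three numbers: its **identity
segment** *d* (the maximum section height in side view — the one
measurement shared by silhouette and section), its area *S* and its
perimeter *C*.  Two dimensionless shape ratios carry the section shape
along the axis:

    φ = S / d²      (π/4 for a circle, 1 for a square)
    ψ = C / d       (π  for a circle, 4 for a square)

Within a slab, φ and ψ are interpolated linearly between the bounding
sections; within each subslab, *d* (read off the silhouette at the
subslab stations) is also linear.  The section area
S(l) = φ(l)·d(l)² is then cubic in the axial coordinate and the
circumference C(l) = ψ(l)·d(l) quadratic, so each subslab's volume
∫S dl and lateral area ∫C dl have exact closed forms — no numerical
quadrature enters the estimate.  Terminal slabs that taper to a point
use *cone mode*: φ and ψ are frozen at the measured base (S/d² is
undefined at the apex) while *d* tapers to zero.

Subslab centroids ∫S·l dl / ∫S dl are also closed-form, so assigning a
density model (uniform, per-slab overrides, and zero-density ellipsoid
voids for lungs) yields the mass and the axial station of the vertical
plane containing the centre of mass.  The method deliberately has no
transverse coordinate system, so only that plane — not a 3-D CM point —
is resolved.

Note on areas: the method's "surface area" is the circumference
integral ∫C dl.  On tapering solids this understates the true slant
area (cone r, h: πrh versus πr√(r²+h²)); the fixtures carry both truths
separately so the two are never conflated.

## Worked example

Twelve slabs of unequal length over a 1 m dolphin-like spindle with
circular sections, ten subslabs each (`examples/01_spindle_volume.py`):

```
slabs: 12 (unequal lengths), 10 subslabs each
estimated volume      : 0.426899 m^3
reference volume      : 0.426979 m^3 (dense trapezoidal rule)
volume error          : -0.019 %
estimated lateral area: 2.134513 m^2 (circumference integral)
```

The estimate is exact up to discretisation of the axial profile; slab
lengths need not be equal, only dense where the shape changes quickly.
Applying a density model (`examples/02_mass_and_cm.py`) converts volume
to mass and locates the CM plane — a 17.2 m³ main body at 1000 kg/m³
weighs 17,155 kg, and carving out a 0.60 m³ lung ellipsoid removes
exactly 603 kg and shifts the CM plane aft from 3.757 m to 3.792 m.

The other examples compare the three estimators on the synthetic suite
(`03`), run the full image-based workflow from rendered mask bitmaps
(`04`), and bracket a volume with superellipse sections (`05`).

## Command line

```
crossvol measure   --side side.png --section 0.2=sec1.png ... --scale 0.001 \
                   --bounds 0,0.2,0.5,1.0 --out measurements.csv
crossvol estimate  --measurements measurements.csv --method csm --density 1027 \
                   --out report.json
crossvol fixtures  --out-dir fixtures/
crossvol validate  --out table.csv
```

`measure` turns binary mask images into a `station,d,S,C` table;
`estimate` runs the CSM (or `gdi` / `superellipse` on a two-view
profile CSV); `fixtures` materialises the synthetic validation solids;
`validate` prints the three-method error table with a mean
absolute-error row.

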