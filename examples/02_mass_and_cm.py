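"""Convert a body volume to mass and locate the centre-of-mass plane.

A large terrestrial-vertebrate-style main body (8 slabs, 1000 subslabs
each) gets a uniform 1000 kg/m^3 density except for a zero-density
ellipsoidal lung cavity in the chest; the mass lost to the cavity and
the resulting aft shift of the CM plane are computed analytically.
"""

import math

import numpy as np

import crossvol as cv

# tapering 10 m main body: deep chest, narrowing tail
stations = np.array([0.0, 1.2, 2.5, 3.8, 5.0, 6.5, 8.0, 9.2, 10.0])
depths = np.array([0.6, 1.6, 2.2, 2.1, 1.7, 1.2, 0.8, 0.5, 0.3])  # d (m)
phi, psi = 0.78, 3.3  # oval sections, a bit fuller than an ellipse

sections = [
    cv.CrossSection(station=s, d=d, S=phi * d**2, C=psi * d)
    for s, d in zip(stations, depths)
]
n_sub = 1000
slabs = []
for ant, post in zip(sections, sections[1:]):
    interior = tuple(
        ant.d + (post.d - ant.d) * k / n_sub for k in range(1, n_sub)
    )
    slabs.append(cv.Slab(anterior=ant, posterior=post, n=n_sub,
                         interior_d=interior))
body = cv.BodyMeasurement(slabs=slabs, name="main body")

lung = cv.EllipsoidVoid(center=2.8, p=0.8, q=0.45, r=0.4)
solid_model = cv.DensityModel(default_density=1000.0)
lunged_model = cv.DensityModel(default_density=1000.0, voids=(lung,))

solid = cv.apply_density(body, solid_model)
lunged = cv.apply_density(body, lunged_model)

print(f"body volume          : {solid.volume:.4f} m^3")
print(f"mass, no air spaces  : {solid.mass:,.0f} kg")
print(f"lung cavity volume   : {lung.volume():.4f} m^3")
print(f"mass with lungs      : {lunged.mass:,.0f} kg"
      f"  (exactly rho x cavity volume lighter)")
print(f"CM plane, uniform    : {solid.cm_station:.4f} m from the snout")
print(f"CM plane, with lungs : {lunged.cm_station:.4f} m"
      f"  (air in the chest shifts the CM aft)")
# Only the axial station of the vertical plane containing the CM is
# resolved; the method has no transverse coordinate system.
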