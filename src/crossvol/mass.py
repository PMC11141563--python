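"""Mass properties: density application, centre-of-mass plane, error metrics.

The method works in one axial coordinate only, so the centre of mass is
reported as the *station of the vertical plane containing the CM*, never
as a 3D point.  Density is uniform by default, overridable per slab, and
zero-density ellipsoidal voids (e.g. a lung cavity) can be subtracted
analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BodyMeasurement,
    SubslabCoefficients,
    body_area,
    body_volume,
    slab_area,
    subslab_first_moment,
    subslab_volume,
)
from .exceptions import ValidationError

__all__ = [
    "EllipsoidVoid",
    "DensityModel",
    "CentroidRecord",
    "MassProperties",
    "subslab_centroid",
    "cm_plane",
    "apply_density",
    "volume_to_mass",
    "error_rate",
    "mean_error",
]


@dataclass(frozen=True)
class EllipsoidVoid:
    """A zero-density ellipsoid inside the body (axis-aligned).

    ``center`` is the axial station of the ellipsoid centre, ``p`` the
    semi-axis along the body axis, ``q`` and ``r`` the transverse
    semi-axes.  Models air-filled cavities such as lungs.
    """

    center: float
    p: float
    q: float
    r: float

    def __post_init__(self) -> None:
        if min(self.p, self.q, self.r) <= 0:
            raise ValidationError("void semi-axes must be > 0")

    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.p * self.q * self.r

    # Cross-sectional area at axial offset u from the centre is
    # pi q r (1 - u^2/p^2); its antiderivative gives exact slice volumes
    # and first moments between any two axial planes.

    def _F(self, u: float) -> float:  # volume antiderivative
        return math.pi * self.q * self.r * (u - u**3 / (3 * self.p**2))

    def _G(self, u: float) -> float:  # first-moment antiderivative
        return math.pi * self.q * self.r * (u * u / 2 - u**4 / (4 * self.p**2))

    def slice(self, s0: float, s1: float) -> tuple[float, float]:
        """(volume, first moment about station 0) of the void between the
        axial planes at stations ``s0 <= s1`` (exact closed form)."""
        a = max(s0 - self.center, -self.p)
        b = min(s1 - self.center, self.p)
        if b <= a:
            return 0.0, 0.0
        vol = self._F(b) - self._F(a)
        moment_local = self._G(b) - self._G(a)
        return vol, moment_local + self.center * vol


@dataclass(frozen=True)
class DensityModel:
    """Uniform density with optional per-slab overrides and voids.

    ``default_density`` applies to every slab (and appendages); entries in
    ``per_slab`` (main-body slab index -> density) override it; ``voids``
    remove mass at the local density.
    """

    default_density: float
    per_slab: dict[int, float] = field(default_factory=dict)
    voids: tuple[EllipsoidVoid, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "voids", tuple(self.voids))
        if self.default_density < 0 or any(v < 0 for v in self.per_slab.values()):
            raise ValidationError("densities must be >= 0")

    def density_of(self, slab_index: int) -> float:
        return self.per_slab.get(slab_index, self.default_density)


@dataclass(frozen=True)
class CentroidRecord:
    """Centroid bookkeeping for one subslab: index ``k``, local centroid
    ``l_bar`` within the subslab, absolute station ``x`` of its centroid
    plane, and mass ``m``."""

    k: int
    l_bar: float
    x: float
    m: float


@dataclass
class MassProperties:
    """Aggregate mass properties of a body under a density model.

    ``cm_station`` is the axial station of the vertical plane containing
    the centre of mass of the *main body* (appendages enter ``mass`` but
    not the CM, since their axial placement relative to their own slab
    tables is not part of the measurement).
    """

    volume: float
    area: float
    mass: float
    cm_station: float
    per_slab: pd.DataFrame


def subslab_centroid(coeff: SubslabCoefficients) -> float:
    """Local centroid of a subslab: ``integral(S l dl) / integral(S dl)``.

    Both integrals are exact polynomial antiderivatives (quintic over
    quartic).  Raises on zero-volume subslabs, where the centroid is
    undefined.
    """
    v = subslab_volume(coeff)
    if v <= 0:
        raise ValidationError("centroid undefined for zero-volume subslab")
    return subslab_first_moment(coeff) / v


def cm_plane(records: list[CentroidRecord]) -> float:
    """Mass-weighted mean centroid station: ``sum(m x) / sum(m)``."""
    total = sum(r.m for r in records)
    if total <= 0:
        raise ValidationError("cm_plane needs positive total mass")
    return sum(r.m * r.x for r in records) / total


def volume_to_mass(V: float, rho: float) -> float:
    """Convert volume to mass at mean density ``rho``."""
    if V < 0 or rho < 0:
        raise ValidationError("volume and density must be >= 0")
    return V * rho


def apply_density(body: BodyMeasurement, model: DensityModel) -> MassProperties:
    """Apply a density model to a measured body.

    Per-subslab masses are exact closed-form volumes times the slab
    density; void volume overlapping each subslab interval is removed
    analytically (ellipsoid-segment calculus, no sampling) at the local
    density, and the CM plane is the mass-weighted centroid of what
    remains.  Appendages contribute volume/area/mass at the default
    density but are excluded from the CM.
    """
    start = body.start_station
    end = start + body.total_length
    for void in model.voids:
        if void.center - void.p < start - 1e-12 or void.center + void.p > end + 1e-12:
            raise ValidationError(
                f"void [{void.center - void.p}, {void.center + void.p}] extends "
                f"outside the body axis [{start}, {end}]"
            )

    records: list[CentroidRecord] = []
    rows = []
    k_global = 0
    for i, slab in enumerate(body.slabs):
        rho = model.density_of(i)
        coeffs = slab.coefficients()
        slab_mass = 0.0
        slab_vol = 0.0
        for j, coeff in enumerate(coeffs):
            k_global += 1
            s0 = slab.anterior.station + j * slab.Ln
            s1 = s0 + slab.Ln
            v = subslab_volume(coeff)
            slab_vol += v
            moment = subslab_first_moment(coeff) + s0 * v  # about station 0
            m = rho * v
            mx = rho * moment
            for void in model.voids:
                v_void, moment_void = void.slice(s0, s1)
                m -= rho * v_void
                mx -= rho * moment_void
            slab_mass += m
            if m > 0:
                records.append(
                    CentroidRecord(
                        k=k_global,
                        l_bar=moment / v - s0 if v > 0 else 0.0,
                        x=mx / m,
                        m=m,
                    )
                )
        rows.append(
            {
                "slab": i,
                "start": slab.anterior.station,
                "end": slab.posterior.station,
                "mode": slab.mode,
                "volume": slab_vol,
                "area": slab_area(slab),
                "density": rho,
                "mass": slab_mass,
            }
        )

    main_mass = sum(r["mass"] for r in rows)
    appendage_mass = sum(
        body_volume(a) * model.default_density for a in body.appendages
    )
    cm = cm_plane(records)
    return MassProperties(
        volume=body_volume(body),
        area=body_area(body),
        mass=main_mass + appendage_mass,
        cm_station=cm,
        per_slab=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# error metrics


def error_rate(calculated: float, observed: float) -> float:
    """Signed relative error in percent: ``(calculated - observed)/observed``.

    Positive when the method overestimates, negative when it
    underestimates.
    """
    if observed <= 0:
        raise ValidationError("observed value must be > 0")
    return (calculated - observed) / observed * 100.0


def mean_error(rates: list[float] | np.ndarray) -> float:
    """Mean of absolute error rates (percent); invariant to sign flips."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValidationError("mean_error needs a non-empty list")
    return float(np.mean(np.abs(rates)))
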