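"""Cross-sectional integration engine.

The cross-sectional method (CSM) reconstructs the volume and lateral
surface area of an animal's body from a single-view silhouette and a
series of measured cross-sections.  The body is cut by parallel planes
into *slabs*; each slab is bounded by two measured sections and is
subdivided into ``n`` equal-length *subslabs*.  Within a subslab the
method assumes that both the identity segment ``d`` (maximum section
height in side view, or width in dorsal view) and the dimensionless
shape ratios

    phi = S / d**2        (area ratio;  pi/4 for a circle)
    psi = C / d           (perimeter ratio;  pi for a circle)

vary linearly along the axis.  The section area ``S(l) = phi(l) d(l)**2``
is then a cubic polynomial in the axial coordinate ``l`` and the section
circumference ``C(l) = psi(l) d(l)`` a quadratic, so subslab volume
(``integral of S dl``) and lateral area (``integral of C dl``) have exact
closed forms.  Terminal slabs that taper to a point are handled in *cone
mode*: the shape ratios are frozen at the measured base's values and only
``d`` tapers to zero, which avoids evaluating ``S/d**2`` at the apex.

All closed-form polynomial integrals are evaluated in Horner form to
limit cancellation.  Units are caller-defined but must be consistent;
nothing here converts units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegenerateSectionError, ValidationError

__all__ = [
    "CrossSection",
    "Slab",
    "SubslabCoefficients",
    "BodyMeasurement",
    "shape_ratio_phi",
    "shape_ratio_psi",
    "interpolate_ratio",
    "subslab_coefficients",
    "section_area_at",
    "section_circumference_at",
    "subslab_volume",
    "subslab_volume_constant_phi",
    "subslab_lateral_area",
    "subslab_lateral_area_constant_psi",
    "slab_volume",
    "slab_area",
    "slab_section_area",
    "slab_section_circumference",
    "body_volume",
    "body_area",
    "rescale_body",
]

#: relative tolerance for shared boundaries of adjacent slabs (measurement
#: noise allowance; when slabs are cut from one figure they coincide exactly)
BOUNDARY_TOL = 0.01


# ---------------------------------------------------------------------------
# shape ratios and interpolation


def shape_ratio_phi(S: float, d: float) -> float:
    """Area shape ratio ``phi = S / d**2`` of a cross-section.

    ``phi`` is a dimensionless proxy for how the section fills the square
    spanned by its identity segment: pi/4 for a circle, 1 for a square.

    Raises
    ------
    DegenerateSectionError
        If ``d == 0`` (cone apex); callers must use cone mode instead.
    """
    if d == 0:
        raise DegenerateSectionError("phi undefined at d = 0 (use cone mode)")
    if d < 0 or S <= 0:
        raise ValidationError(f"need d > 0 and S > 0, got d={d}, S={S}")
    return S / (d * d)


def shape_ratio_psi(C: float, d: float) -> float:
    """Perimeter shape ratio ``psi = C / d``: pi for a circle, 4 for a square.

    Any closed section satisfies ``C >= 2 d`` (the identity segment is a
    chord), so ``psi < 2`` indicates a measurement problem and triggers a
    warning.
    """
    if d == 0:
        raise DegenerateSectionError("psi undefined at d = 0 (use cone mode)")
    if d < 0 or C <= 0:
        raise ValidationError(f"need d > 0 and C > 0, got d={d}, C={C}")
    psi = C / d
    if psi < 2.0 * (1.0 - 1e-9):
        warnings.warn(
            f"psi = C/d = {psi:.4f} < 2: perimeter smaller than twice the "
            "identity segment, check the measurements",
            stacklevel=2,
        )
    return psi


def interpolate_ratio(k: int, n: int, r0: float, rn: float) -> float:
    """Linear interpolation of a shape ratio across a slab.

    Returns the ratio at the ``k``-th of ``n`` equally spaced subslab
    boundaries: ``k (rn - r0)/n + r0``.  Endpoints reproduce ``r0`` and
    ``rn`` exactly.
    """
    if not 0 <= k <= n:
        raise IndexError(f"subslab index k={k} outside [0, {n}]")
    if n < 1:
        raise ValidationError(f"need n >= 1, got {n}")
    return k * (rn - r0) / n + r0


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CrossSection:
    """A measured body cross-section.

    Parameters
    ----------
    station
        Axial distance from the anterior end, in length units.
    d
        Identity-segment length (maximum section height in side view or
        width in dorsal/ventral view); the shared measurement linking the
        silhouette and the section profile.
    S, C
        Enclosed area and perimeter of the section.  Required at slab
        boundaries (where shape ratios are formed); interior stations of
        a slab carry only ``d``.
    label
        Free-text annotation.
    """

    station: float
    d: float
    S: float | None = None
    C: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValidationError(f"identity segment d={self.d} < 0")
        if self.d > 0:
            if self.S is not None and self.S <= 0:
                raise ValidationError(f"section area S={self.S} <= 0")
            if self.C is not None and self.C <= 0:
                raise ValidationError(f"section perimeter C={self.C} <= 0")
        if self.C is not None and self.d > 0 and self.C < 2 * self.d * (1 - 1e-9):
            warnings.warn(
                f"section at station {self.station}: C={self.C} < 2 d={2 * self.d}; "
                "a closed curve's perimeter is at least twice any chord",
                stacklevel=2,
            )
        if (
            self.S is not None
            and self.C is not None
            # 1% slack for rasterized measurements
            and self.C**2 < 4 * math.pi * self.S * 0.99
        ):
            warnings.warn(
                f"section at station {self.station} violates the isoperimetric "
                f"inequality C^2 >= 4 pi S ({self.C**2:.6g} < "
                f"{4 * math.pi * self.S:.6g})",
                stacklevel=2,
            )

    @property
    def phi(self) -> float:
        """Area shape ratio ``S/d**2``."""
        if self.S is None:
            raise ValidationError(f"section at station {self.station} has no S")
        return shape_ratio_phi(self.S, self.d)

    @property
    def psi(self) -> float:
        """Perimeter shape ratio ``C/d``."""
        if self.C is None:
            raise ValidationError(f"section at station {self.station} has no C")
        return shape_ratio_psi(self.C, self.d)


@dataclass(frozen=True)
class SubslabCoefficients:
    """Linear-variation coefficients of one subslab.

    ``alpha``, ``beta`` and ``gamma`` are the axial slopes of phi, d and
    psi over the subslab; ``base_*`` are the values at its anterior face.
    Section area and circumference inside the subslab are

        S(l) = (alpha l + base_phi) (beta l + base_d)**2
        C(l) = (gamma l + base_psi) (beta l + base_d)

    for ``0 <= l <= Ln``.
    """

    alpha: float
    beta: float
    gamma: float
    base_d: float
    base_phi: float
    base_psi: float
    Ln: float

    def end_values(self) -> tuple[float, float, float]:
        """(d, phi, psi) at the posterior face, reconstructed from slopes."""
        return (
            self.base_d + self.beta * self.Ln,
            self.base_phi + self.alpha * self.Ln,
            self.base_psi + self.gamma * self.Ln,
        )


def subslab_coefficients(
    phi_prev: float,
    phi_k: float,
    psi_prev: float,
    psi_k: float,
    d_prev: float,
    d_k: float,
    Ln: float,
) -> SubslabCoefficients:
    """Slopes of phi, d and psi across one subslab of length ``Ln``."""
    if Ln <= 0:
        raise ValidationError(f"subslab length Ln={Ln} <= 0")
    return SubslabCoefficients(
        alpha=(phi_k - phi_prev) / Ln,
        beta=(d_k - d_prev) / Ln,
        gamma=(psi_k - psi_prev) / Ln,
        base_d=d_prev,
        base_phi=phi_prev,
        base_psi=psi_prev,
        Ln=Ln,
    )


# ---------------------------------------------------------------------------
# closed-form subslab integrals


def _check_l(l: float, Ln: float) -> None:
    if not 0 <= l <= Ln:
        raise ValidationError(f"axial position l={l} outside subslab [0, {Ln}]")


def section_area_at(l: float, coeff: SubslabCoefficients) -> float:
    """Section area ``S(l) = (alpha l + phi)(beta l + d)**2`` inside a subslab."""
    _check_l(l, coeff.Ln)
    dl = coeff.beta * l + coeff.base_d
    return (coeff.alpha * l + coeff.base_phi) * dl * dl


def section_circumference_at(l: float, coeff: SubslabCoefficients) -> float:
    """Section circumference ``C(l) = (gamma l + psi)(beta l + d)``."""
    _check_l(l, coeff.Ln)
    return (coeff.gamma * l + coeff.base_psi) * (coeff.beta * l + coeff.base_d)


def subslab_volume(coeff: SubslabCoefficients) -> float:
    """Exact integral of the cubic ``S(l)`` over the subslab.

    The antiderivative is the quartic

        (1/4) a b^2 Ln^4 + (1/3)(2 a b d + p b^2) Ln^3
        + (1/2)(a d^2 + 2 b d p) Ln^2 + p d^2 Ln

    with ``a = alpha``, ``b = beta``, ``p = base_phi``, ``d = base_d``,
    evaluated here in Horner form.
    """
    a, b = coeff.alpha, coeff.beta
    d, p, Ln = coeff.base_d, coeff.base_phi, coeff.Ln
    return Ln * (
        p * d * d
        + Ln * ((a * d * d + 2 * b * d * p) / 2.0
                + Ln * ((2 * a * b * d + p * b * b) / 3.0
                        + Ln * (a * b * b / 4.0)))
    )


def subslab_volume_constant_phi(Phi: float, coeff: SubslabCoefficients) -> float:
    """Cone-mode subslab volume: phi frozen at the base value ``Phi``.

    Equals :func:`subslab_volume` with ``alpha = 0`` exactly; kept as its
    own entry point because terminal (cone) slabs never form phi at the
    apex where ``d = 0``.
    """
    b, d, Ln = coeff.beta, coeff.base_d, coeff.Ln
    return Phi * Ln * (d * d + Ln * (b * d + Ln * (b * b / 3.0)))


def subslab_lateral_area(coeff: SubslabCoefficients) -> float:
    """Exact integral of the quadratic ``C(l)`` over the subslab.

    Note this is the method's definition of lateral area (circumference
    integrated along the axis); on tapering solids it understates the
    true slant area.
    """
    g, b = coeff.gamma, coeff.beta
    d, s, Ln = coeff.base_d, coeff.base_psi, coeff.Ln
    return Ln * (s * d + Ln * ((g * d + b * s) / 2.0 + Ln * (g * b / 3.0)))


def subslab_lateral_area_constant_psi(Psi: float, coeff: SubslabCoefficients) -> float:
    """Cone-mode subslab lateral area: psi frozen at the base value ``Psi``."""
    b, d, Ln = coeff.beta, coeff.base_d, coeff.Ln
    return Psi * Ln * (d + b * Ln / 2.0)


def subslab_first_moment(coeff: SubslabCoefficients) -> float:
    """Exact integral of ``l S(l)`` over the subslab (quintic antiderivative).

    Used for the subslab centroid; see :mod:`crossvol.mass`.
    """
    a, b = coeff.alpha, coeff.beta
    d, p, Ln = coeff.base_d, coeff.base_phi, coeff.Ln
    return Ln * Ln * (
        p * d * d / 2.0
        + Ln * ((a * d * d + 2 * b * d * p) / 3.0
                + Ln * ((2 * a * b * d + p * b * b) / 4.0
                        + Ln * (a * b * b / 5.0)))
    )


# ---------------------------------------------------------------------------
# slabs


@dataclass(frozen=True)
class Slab:
    """A body segment between two parallel measured sections.

    ``anterior`` and ``posterior`` are the bounding sections (both with
    ``S`` and ``C`` in frustum mode; in cone mode the apex end has
    ``d = 0`` and needs neither).  ``interior_d`` lists the identity
    segments read off the silhouette at the ``n - 1`` equally spaced
    interior subslab boundaries.
    """

    anterior: CrossSection
    posterior: CrossSection
    n: int
    interior_d: tuple[float, ...] = ()
    mode: str = "frustum"

    def __post_init__(self) -> None:
        object.__setattr__(self, "interior_d", tuple(self.interior_d))
        if self.mode not in ("frustum", "cone"):
            raise ValidationError(f"unknown slab mode {self.mode!r}")
        if self.n < 1:
            raise ValidationError(f"subslab count n={self.n} < 1")
        if self.L <= 0:
            raise ValidationError(
                f"slab length {self.L} <= 0 (stations "
                f"{self.anterior.station} -> {self.posterior.station})"
            )
        if len(self.interior_d) != self.n - 1:
            raise ValidationError(
                f"interior_d has {len(self.interior_d)} entries, expected "
                f"n - 1 = {self.n - 1}"
            )
        if any(d < 0 for d in self.interior_d):
            raise ValidationError("interior_d entries must be >= 0")
        if self.mode == "cone":
            apex = [s for s in (self.anterior, self.posterior) if s.d == 0]
            if len(apex) != 1:
                raise ValidationError(
                    "cone mode needs exactly one end with d = 0 (the apex)"
                )

    # -- geometry -----------------------------------------------------------

    @property
    def L(self) -> float:
        """Slab length along the axis."""
        return self.posterior.station - self.anterior.station

    @property
    def Ln(self) -> float:
        """Subslab length ``L / n``."""
        return self.L / self.n

    @property
    def base(self) -> CrossSection:
        """The measured base of a cone-mode slab (the non-apex end)."""
        if self.mode != "cone":
            raise ValidationError("base is defined for cone-mode slabs only")
        return self.posterior if self.anterior.d == 0 else self.anterior

    def d_profile(self) -> np.ndarray:
        """Identity segments at the ``n + 1`` subslab boundaries."""
        return np.array(
            [self.anterior.d, *self.interior_d, self.posterior.d], dtype=float
        )

    def _ratio_profiles(self) -> tuple[np.ndarray, np.ndarray]:
        """(phi, psi) at the subslab boundaries.

        Frustum mode interpolates linearly between the bounding sections'
        ratios; cone mode holds the base's values constant.
        """
        ks = np.arange(self.n + 1)
        if self.mode == "cone":
            phi = np.full(self.n + 1, self.base.phi)
            psi = np.full(self.n + 1, self.base.psi)
        else:
            phi0, phin = self.anterior.phi, self.posterior.phi
            psi0, psin = self.anterior.psi, self.posterior.psi
            phi = ks * (phin - phi0) / self.n + phi0
            psi = ks * (psin - psi0) / self.n + psi0
        return phi, psi

    def coefficients(self) -> list[SubslabCoefficients]:
        """Per-subslab linear-variation coefficients, anterior to posterior."""
        d = self.d_profile()
        phi, psi = self._ratio_profiles()
        return [
            subslab_coefficients(
                phi[k - 1], phi[k], psi[k - 1], psi[k], d[k - 1], d[k], self.Ln
            )
            for k in range(1, self.n + 1)
        ]


def slab_volume(slab: Slab) -> float:
    """Slab volume: sum of the exact subslab integrals.

    Cone-mode slabs go through the constant-phi path, which never forms a
    shape ratio at the apex.
    """
    coeffs = slab.coefficients()
    if slab.mode == "cone":
        Phi = slab.base.phi
        return sum(subslab_volume_constant_phi(Phi, c) for c in coeffs)
    return sum(subslab_volume(c) for c in coeffs)


def slab_area(slab: Slab) -> float:
    """Slab lateral area (integral of circumference along the axis)."""
    coeffs = slab.coefficients()
    if slab.mode == "cone":
        Psi = slab.base.psi
        return sum(subslab_lateral_area_constant_psi(Psi, c) for c in coeffs)
    return sum(subslab_lateral_area(c) for c in coeffs)


def _locate(slab: Slab, x: float) -> tuple[SubslabCoefficients, float]:
    """Map an axial position ``x`` in ``[0, L]`` to (subslab, local l)."""
    if not 0 <= x <= slab.L:
        raise ValidationError(f"x={x} outside slab [0, {slab.L}]")
    k = min(int(x / slab.Ln), slab.n - 1)
    return slab.coefficients()[k], x - k * slab.Ln


def slab_section_area(slab: Slab, x: float) -> float:
    """Modelled section area at axial position ``x`` from the slab's
    anterior face (piecewise cubic; used by the quadrature oracle)."""
    coeff, l = _locate(slab, x)
    return section_area_at(l, coeff)


def slab_section_circumference(slab: Slab, x: float) -> float:
    """Modelled section circumference at axial position ``x`` (piecewise
    quadratic)."""
    coeff, l = _locate(slab, x)
    return section_circumference_at(l, coeff)


# ---------------------------------------------------------------------------
# whole bodies


def _rel_diff(a: float, b: float) -> float:
    denom = max(abs(a), abs(b))
    return 0.0 if denom == 0 else abs(a - b) / denom


@dataclass
class BodyMeasurement:
    """An ordered series of slabs along the sagittal axis, plus appendages.

    Appendages (fins, limbs, flukes) are separated from the main body and
    carried as independent bodies measured the same way; their volumes and
    areas add to the totals.
    """

    slabs: list[Slab]
    appendages: list["BodyMeasurement"] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if not self.slabs:
            raise ValidationError("body needs at least one slab")
        for prev, nxt in zip(self.slabs, self.slabs[1:]):
            a, b = prev.posterior, nxt.anterior
            if abs(a.station - b.station) > 1e-9 * max(1.0, self.total_length):
                raise ValidationError(
                    f"slab boundary stations disagree: {a.station} vs {b.station}"
                )
            for attr in ("d", "S", "C"):
                va, vb = getattr(a, attr), getattr(b, attr)
                if va is None or vb is None:
                    continue
                if _rel_diff(va, vb) > BOUNDARY_TOL:
                    raise ValidationError(
                        f"adjacent slabs disagree on {attr} at station "
                        f"{a.station}: {va} vs {vb} (> {BOUNDARY_TOL:.0%})"
                    )

    @property
    def start_station(self) -> float:
        return self.slabs[0].anterior.station

    @property
    def total_length(self) -> float:
        return self.slabs[-1].posterior.station - self.slabs[0].anterior.station


def body_volume(body: BodyMeasurement) -> float:
    """Total volume: main-body slabs plus appendages (exact additivity)."""
    return sum(slab_volume(s) for s in body.slabs) + sum(
        body_volume(a) for a in body.appendages
    )


def body_area(body: BodyMeasurement) -> float:
    """Total lateral surface area: main-body slabs plus appendages."""
    return sum(slab_area(s) for s in body.slabs) + sum(
        body_area(a) for a in body.appendages
    )


def _scale_section(sec: CrossSection, f: float) -> CrossSection:
    return CrossSection(
        station=sec.station * f,
        d=sec.d * f,
        S=None if sec.S is None else sec.S * f * f,
        C=None if sec.C is None else sec.C * f,
        label=sec.label,
    )


def rescale_body(body: BodyMeasurement, total_length: float = 1.0) -> BodyMeasurement:
    """Geometrically rescale a body so the main axis has the given length.

    Stations, d and C scale by the factor, S by its square; shape ratios
    (and hence relative errors) are invariant.  Appendages scale by the
    same factor.
    """
    f = total_length / body.total_length

    def scale(b: BodyMeasurement) -> BodyMeasurement:
        return BodyMeasurement(
            slabs=[
                replace(
                    s,
                    anterior=_scale_section(s.anterior, f),
                    posterior=_scale_section(s.posterior, f),
                    interior_d=tuple(d * f for d in s.interior_d),
                )
                for s in b.slabs
            ],
            appendages=[scale(a) for a in b.appendages],
            name=b.name,
        )

    return scale(body)
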