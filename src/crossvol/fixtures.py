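"""Synthetic solids with exact reference values.

Every estimator in this package is validated against solids whose volume
and surface area are known in closed form (or to quadrature accuracy far
beyond measurement precision).  Each solid exposes analytic per-station
sections — identity segment ``d``, area ``S``, perimeter ``C`` — so the
whole pipeline, from measurement tables to mask rasterisation, can be
exercised without any external data.

Two area truths are stored and must not be conflated:

``exact_lateral_area``
    the true lateral surface area (slant area for cones/frusta,
    surface-of-revolution integral for smooth profiles);
``method_area``
    the integral of section circumference along the axis, which is the
    quantity the cross-sectional method and GDI actually estimate.  On
    tapering solids it is systematically below the slant area (for a
    cone of radius r and height h: ``pi r h`` versus
    ``pi r sqrt(r^2 + h^2)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .comparators import SuperellipseSpec, TwoViewProfile, superellipse_area, superellipse_perimeter
from .core import BodyMeasurement, CrossSection, Slab
from .exceptions import ValidationError
from .silhouette import MaskImage

__all__ = [
    "SyntheticSolid",
    "MaskSet",
    "make_solid",
    "sample_measurements",
    "render_masks",
    "fixture_suite",
]


@dataclass(frozen=True)
class SyntheticSolid:
    """A solid with analytic cross-sections along ``l`` in ``[0, length]``."""

    kind: str
    params: dict
    length: float
    exact_volume: float
    exact_lateral_area: float
    method_area: float
    half_height: Callable[[float], float]   # side-view semi-axis b(l)
    half_width: Callable[[float], float]    # dorsal-view semi-axis a(l)
    section_area: Callable[[float], float]
    section_perimeter: Callable[[float], float]
    #: (l, X, Y) -> bool array: does the section at l contain point (X, Y)?
    section_contains: Callable[[float, np.ndarray, np.ndarray], np.ndarray]

    def d(self, l: float) -> float:
        """Identity segment in side view: full section height ``2 b(l)``."""
        return 2.0 * self.half_height(l)

    def section(self, l: float, label: str = "") -> CrossSection:
        """Analytic :class:`CrossSection` at station ``l``."""
        d = self.d(l)
        if d == 0:
            return CrossSection(station=l, d=0.0, label=label)
        return CrossSection(
            station=l,
            d=d,
            S=self.section_area(l),
            C=self.section_perimeter(l),
            label=label,
        )

    def profile(self, n_stations: int = 121) -> TwoViewProfile:
        """Two-view profile sampled at equally spaced stations."""
        st = np.linspace(0.0, self.length, n_stations)
        return TwoViewProfile(
            stations=st,
            half_height=np.array([self.half_height(l) for l in st]),
            half_width=np.array([self.half_width(l) for l in st]),
        )


def _circular(kind: str, params: dict, length: float, radius_fn,
              exact_volume: float, exact_lateral_area: float,
              method_area: float) -> SyntheticSolid:
    """Build a solid of revolution from a radius profile."""

    def contains(l, X, Y):
        r = radius_fn(l)
        return X * X + Y * Y <= r * r

    return SyntheticSolid(
        kind=kind,
        params=params,
        length=length,
        exact_volume=exact_volume,
        exact_lateral_area=exact_lateral_area,
        method_area=method_area,
        half_height=radius_fn,
        half_width=radius_fn,
        section_area=lambda l: math.pi * radius_fn(l) ** 2,
        section_perimeter=lambda l: 2.0 * math.pi * radius_fn(l),
        section_contains=contains,
    )


def make_solid(kind: str, **params) -> SyntheticSolid:
    """Construct a synthetic solid.

    Kinds and parameters (all lengths in caller units):

    - ``cylinder(radius, length)``
    - ``cone(radius, length, apex="posterior"|"anterior")`` — circular
      cone tapering to a point at one end
    - ``frustum(r_anterior, r_posterior, length)`` — linear radius taper
    - ``superellipse_loft(a, b, k, length)`` — constant superellipse
      section extruded along the axis
    - ``revolution(length, r_mean, amplitude, cycles)`` — body of
      revolution with radius ``r_mean + amplitude sin(2 pi cycles l/length)``,
      emulating the irregular fluctuation of body height along a real
      animal's axis

    Construction is deterministic; randomness only enters through the
    noise wrapper of :func:`sample_measurements`.
    """
    if kind == "cylinder":
        r, L = params["radius"], params["length"]
        if r <= 0 or L <= 0:
            raise ValidationError("cylinder needs radius > 0 and length > 0")
        return _circular(
            kind, params, L, lambda l: r,
            exact_volume=math.pi * r * r * L,
            exact_lateral_area=2 * math.pi * r * L,
            method_area=2 * math.pi * r * L,
        )

    if kind == "cone":
        r, L = params["radius"], params["length"]
        apex = params.get("apex", "posterior")
        if r <= 0 or L <= 0 or apex not in ("anterior", "posterior"):
            raise ValidationError("cone needs radius > 0, length > 0, valid apex")
        if apex == "posterior":
            radius_fn = lambda l: r * (1.0 - l / L)
        else:
            radius_fn = lambda l: r * (l / L)
        return _circular(
            kind, params, L, radius_fn,
            exact_volume=math.pi * r * r * L / 3.0,
            exact_lateral_area=math.pi * r * math.hypot(r, L),
            method_area=math.pi * r * L,
        )

    if kind == "frustum":
        r0, r1, L = params["r_anterior"], params["r_posterior"], params["length"]
        if min(r0, r1) <= 0 or L <= 0:
            raise ValidationError("frustum needs positive radii and length")
        return _circular(
            kind, params, L, lambda l: r0 + (r1 - r0) * l / L,
            exact_volume=math.pi * L * (r0 * r0 + r0 * r1 + r1 * r1) / 3.0,
            exact_lateral_area=math.pi * (r0 + r1) * math.hypot(r1 - r0, L),
            method_area=math.pi * (r0 + r1) * L,
        )

    if kind == "superellipse_loft":
        a, b, k, L = params["a"], params["b"], params["k"], params["length"]
        spec = SuperellipseSpec(a=a, b=b, k=k)
        if L <= 0:
            raise ValidationError("loft needs length > 0")
        S = superellipse_area(spec)
        C = superellipse_perimeter(spec)

        def contains(l, X, Y):
            return (np.abs(X / a) ** k + np.abs(Y / b) ** k) <= 1.0

        return SyntheticSolid(
            kind=kind,
            params=params,
            length=L,
            exact_volume=S * L,
            exact_lateral_area=C * L,  # no taper: slant area == method area
            method_area=C * L,
            half_height=lambda l: b,
            half_width=lambda l: a,
            section_area=lambda l: S,
            section_perimeter=lambda l: C,
            section_contains=contains,
        )

    if kind == "revolution":
        L = params.get("length", 1.0)
        r_mean = params.get("r_mean", 0.5)
        amp = params.get("amplitude", 0.1)
        cycles = params.get("cycles", 1)
        if L <= 0 or r_mean <= abs(amp):
            raise ValidationError("revolution needs length > 0 and r_mean > |amplitude|")
        w = 2.0 * math.pi * cycles / L
        radius_fn = lambda l: r_mean + amp * math.sin(w * l)
        # closed forms: int r^2 over a whole number of cycles leaves the
        # mean-square term only; the lateral area needs quadrature
        exact_volume = math.pi * L * (r_mean**2 + amp**2 / 2.0)
        method_area = 2.0 * math.pi * r_mean * L
        lateral, _ = quad(
            lambda l: 2.0 * math.pi * radius_fn(l)
            * math.hypot(1.0, amp * w * math.cos(w * l)),
            0.0, L, limit=200,
        )
        return _circular(
            kind, params, L, radius_fn,
            exact_volume=exact_volume,
            exact_lateral_area=lateral,
            method_area=method_area,
        )

    raise ValidationError(f"unknown solid kind {kind!r}")


def fixture_suite() -> list[SyntheticSolid]:
    """The standard validation set: regular and irregular solids spanning
    the shapes the estimators are exercised on (all unit-scale)."""
    return [
        make_solid("cylinder", radius=0.5, length=1.0),
        make_solid("cone", radius=0.5, length=1.0),
        make_solid("frustum", r_anterior=0.5, r_posterior=0.25, length=1.0),
        make_solid("superellipse_loft", a=0.5, b=0.35, k=1.6, length=1.0),
        make_solid("superellipse_loft", a=0.4, b=0.4, k=2.3, length=1.0),
        make_solid("revolution", length=1.0, r_mean=0.5, amplitude=0.1, cycles=1),
    ]


# ---------------------------------------------------------------------------
# sampling measurements


def sample_measurements(
    solid: SyntheticSolid,
    slab_bounds=None,
    n_subslabs: int = 10,
    noise_sd: float = 0.0,
    seed: int = 0,
    name: str = "",
) -> BodyMeasurement:
    """Emulate the data-collection workflow on a known solid.

    Sections are evaluated analytically at the slab boundaries (d, S, C)
    and at the equally spaced interior subslab stations (d only).  With
    ``noise_sd > 0`` every measurement is perturbed multiplicatively by
    ``1 + N(0, noise_sd)`` (one draw per quantity per station, shared
    boundaries drawn once), reproducibly from ``seed``.

    Slabs whose one end has ``d = 0`` become cone-mode slabs; all others
    are frusta.  Default partition: 12 equal slabs.
    """
    if slab_bounds is None:
        slab_bounds = np.linspace(0.0, solid.length, 13)
    bounds = np.asarray(slab_bounds, dtype=float)
    if bounds.size < 2 or np.any(np.diff(bounds) <= 0):
        raise ValidationError("slab_bounds must be >= 2 strictly increasing values")
    if bounds[0] < -1e-12 or bounds[-1] > solid.length + 1e-12:
        raise ValidationError("slab_bounds outside the solid")
    rng = np.random.default_rng(seed)

    def jitter(value: float) -> float:
        if value == 0 or noise_sd == 0:
            return value
        return value * max(1e-9, 1.0 + rng.normal(0.0, noise_sd))

    boundary_sections = []
    for l in bounds:
        sec = solid.section(float(l))
        if sec.d == 0:
            boundary_sections.append(sec)
        else:
            boundary_sections.append(
                CrossSection(
                    station=sec.station,
                    d=jitter(sec.d),
                    S=jitter(sec.S),
                    C=jitter(sec.C),
                )
            )

    slabs = []
    for i in range(bounds.size - 1):
        ant, post = boundary_sections[i], boundary_sections[i + 1]
        interior = np.linspace(bounds[i], bounds[i + 1], n_subslabs + 1)[1:-1]
        interior_d = tuple(jitter(solid.d(float(l))) for l in interior)
        mode = "cone" if (ant.d == 0) != (post.d == 0) else "frustum"
        slabs.append(
            Slab(anterior=ant, posterior=post, n=n_subslabs,
                 interior_d=interior_d, mode=mode)
        )
    return BodyMeasurement(slabs=slabs, name=name or solid.kind)


# ---------------------------------------------------------------------------
# mask rendering


@dataclass(frozen=True)
class MaskSet:
    """Rendered masks for one solid: a side-view silhouette plus section
    masks at chosen stations.  ``origin`` is the axial station of image
    x-coordinate zero (i.e. station ``s`` sits at pixel column
    ``s/scale + origin_px``)."""

    side: MaskImage
    sections: dict[float, MaskImage]
    origin: float
    scale: float


def render_masks(
    solid: SyntheticSolid,
    resolution: tuple[int, int] = (6000, 4000),
    stations=None,
    margin_px: int = 40,
    scale: float | None = None,
) -> MaskSet:
    """Rasterise a solid's side view and cross-sections to binary masks.

    ``resolution`` is (width, height) of the side view in pixels; the
    default matches common practice for bitmap-based silhouette work.
    ``scale`` (units per pixel) is derived from the resolution and margin
    unless given.  Section masks are square, rendered at the same scale,
    at the given stations (default: the solid's quartiles).

    Round-tripping these masks through :mod:`crossvol.silhouette`
    recovers the analytic d, S, C within rasterisation error (<1% at the
    default resolution).
    """
    width, height = resolution
    if scale is None:
        scale = solid.length / (width - 2 * margin_px)
    if width <= 2 * margin_px or height <= 2 * margin_px:
        raise ValidationError(f"resolution {resolution} too small for margin {margin_px}")
    max_d = max(solid.d(l) for l in np.linspace(0, solid.length, 512))
    if max_d / scale > height - 2 * margin_px:
        raise ValidationError(
            f"resolution {resolution} too small: body height {max_d / scale:.0f} px "
            f"exceeds usable height {height - 2 * margin_px} px"
        )

    origin = -margin_px * scale  # station of image x = 0
    cols = (np.arange(width) + 0.5) * scale + origin
    row_y = ((np.arange(height) + 0.5) - height / 2.0) * scale
    half = np.zeros(width)
    inside = (cols >= 0) & (cols <= solid.length)
    half[inside] = [solid.d(float(l)) / 2.0 for l in cols[inside]]
    side = np.abs(row_y)[:, None] <= half[None, :]
    side_mask = MaskImage(pixels=side, scale=scale, axis="columns")

    if stations is None:
        stations = list(np.linspace(0, solid.length, 5)[1:-1])
    sections = {}
    max_w = max(solid.half_width(l) for l in np.linspace(0, solid.length, 512))
    n = int(math.ceil(2 * max(max_d / 2, max_w) / scale)) + 2 * margin_px
    centers = ((np.arange(n) + 0.5) - n / 2.0) * scale
    X, Y = np.meshgrid(centers, centers)
    for st in stations:
        mask = solid.section_contains(float(st), X, Y)
        sections[float(st)] = MaskImage(pixels=np.asarray(mask, bool), scale=scale)
    return MaskSet(side=side_mask, sections=sections, origin=origin, scale=scale)
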