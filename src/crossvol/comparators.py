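"""Benchmark estimators: Graphic Double Integration and superellipse brackets.

Both comparators replace the measured cross-sections with an assumed
family of shapes built from two orthogonal silhouettes (side and
dorsal/ventral views).  GDI treats each axial slice as a cylinder with
elliptical bases whose semi-axes are averaged between the two ends;
superellipse bracketing spans the true section between two exponents
``k_min <= k <= k_max`` of the curve ``|x/a|^k + |y/b|^k = 1`` (``k = 2``
is an ellipse) and reports a [low, high] interval plus its arithmetic
mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import gamma

from .exceptions import ValidationError

__all__ = [
    "TwoViewProfile",
    "SuperellipseSpec",
    "SuperellipseBracket",
    "ellipse_perimeter",
    "gdi_slab",
    "gdi_body",
    "superellipse_area",
    "superellipse_perimeter",
    "superellipse_body",
]

#: default number of equal GDI slices
GDI_SLABS = 120
#: default exponent ranges: cetacean-like bodies, and a general-purpose span
K_RANGE_MARINE = (2.0, 2.3)
K_RANGE_GENERAL = (1.6, 2.4)


@dataclass(frozen=True)
class TwoViewProfile:
    """Per-station semi-axes measured from two orthogonal views.

    ``half_height`` comes from the side view, ``half_width`` from the
    dorsal/ventral view; both are half of the respective identity
    segments.
    """

    stations: np.ndarray
    half_height: np.ndarray
    half_width: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.stations, dtype=float)
        hh = np.asarray(self.half_height, dtype=float)
        hw = np.asarray(self.half_width, dtype=float)
        if not (st.shape == hh.shape == hw.shape) or st.ndim != 1:
            raise ValidationError("profile sequences must be equal-length 1-D")
        if st.size < 2:
            raise ValidationError("profile needs at least 2 stations")
        if np.any(np.diff(st) <= 0):
            raise ValidationError("stations must be strictly increasing")
        if np.any(hh < 0) or np.any(hw < 0):
            raise ValidationError("semi-axes must be >= 0")
        object.__setattr__(self, "stations", st)
        object.__setattr__(self, "half_height", hh)
        object.__setattr__(self, "half_width", hw)

    def at(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (half_height, half_width) at stations x."""
        return (
            np.interp(x, self.stations, self.half_height),
            np.interp(x, self.stations, self.half_width),
        )


@dataclass(frozen=True)
class SuperellipseSpec:
    """Superellipse ``|x/a|^k + |y/b|^k = 1`` with semi-axes a, b > 0."""

    a: float
    b: float
    k: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.k <= 0:
            raise ValidationError("superellipse needs a, b, k > 0")


def ellipse_perimeter(a: float, b: float) -> float:
    """Ellipse perimeter by Ramanujan's second approximation.

    Relative error is below 1e-9 for aspect ratios up to ~1:5, far inside
    measurement noise for biological sections.
    """
    if a < 0 or b < 0:
        raise ValidationError("semi-axes must be >= 0")
    if a == 0 and b == 0:
        return 0.0
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def gdi_slab(
    a1: float, b1: float, a2: float, b2: float, L: float
) -> tuple[float, float]:
    """One GDI part: an elliptical cylinder with averaged semi-axes.

    Returns ``(volume, lateral area) = (pi a b L, P(a, b) L)`` where
    ``a = (a1 + a2)/2`` and ``b = (b1 + b2)/2``.
    """
    if L <= 0:
        raise ValidationError(f"slab length L={L} <= 0")
    if min(a1, b1, a2, b2) < 0:
        raise ValidationError("semi-axes must be >= 0")
    a = (a1 + a2) / 2.0
    b = (b1 + b2) / 2.0
    return math.pi * a * b * L, ellipse_perimeter(a, b) * L


def gdi_body(profile: TwoViewProfile, n_slabs: int = GDI_SLABS) -> tuple[float, float]:
    """Graphic Double Integration over a two-view profile.

    The body is sliced equally into ``n_slabs`` parts; each part is an
    elliptical cylinder with end semi-axes read from the profile and
    averaged.  Returns total (volume, lateral area).
    """
    if n_slabs < 1:
        raise ValidationError("n_slabs must be >= 1")
    bounds = np.linspace(profile.stations[0], profile.stations[-1], n_slabs + 1)
    hh, hw = profile.at(bounds)
    L = bounds[1] - bounds[0]
    vol = 0.0
    area = 0.0
    for i in range(n_slabs):
        v, s = gdi_slab(hw[i], hh[i], hw[i + 1], hh[i + 1], L)
        vol += v
        area += s
    return vol, area


def superellipse_area(spec: SuperellipseSpec) -> float:
    """Enclosed area ``4 a b Gamma(1 + 1/k)^2 / Gamma(1 + 2/k)``.

    Reduces to ``pi a b`` at k = 2, ``2 a b`` at k = 1, and tends to the
    bounding rectangle ``4 a b`` as k grows.
    """
    a, b, k = spec.a, spec.b, spec.k
    return 4.0 * a * b * gamma(1 + 1 / k) ** 2 / gamma(1 + 2 / k)


def superellipse_perimeter(spec: SuperellipseSpec) -> float:
    """Arc length of the superellipse by adaptive quadrature.

    Uses the parametrisation ``x = a cos(t)^(2/k)``, ``y = b sin(t)^(2/k)``
    on one quadrant; the integrand's endpoint singularities (k > 2) are
    integrable and handled by the adaptive rule.
    """
    a, b, k = spec.a, spec.b, spec.k
    e = 2.0 / k

    def integrand(t: float) -> float:
        c, s = math.cos(t), math.sin(t)
        term_x = a * c ** (e - 1) * s if c > 0 else 0.0
        term_y = b * s ** (e - 1) * c if s > 0 else 0.0
        return e * math.hypot(term_x, term_y)

    length, _ = quad(integrand, 0.0, math.pi / 2, limit=200)
    return 4.0 * length


def _section(a: float, b: float, k: float) -> tuple[float, float]:
    """(area, perimeter) of a per-station section, tolerating degenerate
    zero semi-axes at body ends."""
    if a == 0 or b == 0:
        return 0.0, 0.0
    spec = SuperellipseSpec(a=a, b=b, k=k)
    return superellipse_area(spec), superellipse_perimeter(spec)


@dataclass(frozen=True)
class SuperellipseBracket:
    """Volume/area interval from the two bounding exponents, with the
    arithmetic mean of the bounds as the point estimate."""

    volume_low: float
    volume_high: float
    volume_mean: float
    area_low: float
    area_high: float
    area_mean: float


def superellipse_body(
    profile: TwoViewProfile, k_min: float, k_max: float
) -> SuperellipseBracket:
    """Bracket a body's volume and lateral area with superellipse sections.

    At every profile station a superellipse with the measured semi-axes is
    built for each bounding exponent; section areas and perimeters are
    integrated along the axis by the trapezoidal rule.  Area is strictly
    increasing in k at fixed semi-axes, so the k_min/k_max solids bound any
    body whose true section exponents lie inside the range.
    """
    if k_min > k_max:
        raise ValidationError(f"k_min={k_min} > k_max={k_max}")
    st = profile.stations
    out = {}
    for tag, k in (("low", k_min), ("high", k_max)):
        areas = np.empty(st.size)
        perims = np.empty(st.size)
        for i in range(st.size):
            areas[i], perims[i] = _section(
                profile.half_width[i], profile.half_height[i], k
            )
        out[f"volume_{tag}"] = float(np.trapezoid(areas, st))
        out[f"area_{tag}"] = float(np.trapezoid(perims, st))
    return SuperellipseBracket(
        volume_low=out["volume_low"],
        volume_high=out["volume_high"],
        volume_mean=(out["volume_low"] + out["volume_high"]) / 2.0,
        area_low=out["area_low"],
        area_high=out["area_high"],
        area_mean=(out["area_low"] + out["area_high"]) / 2.0,
    )
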