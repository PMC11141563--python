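"""Unit and property tests for the slab/subslab integration engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import crossvol as cv
from crossvol.core import slab_section_area, slab_section_circumference, subslab_first_moment
from crossvol.exceptions import DegenerateSectionError, ValidationError

from conftest import random_frustum_slab

finite = st.floats(allow_nan=False, allow_infinity=False)


# ---------------------------------------------------------------------------
# shape ratios


@pytest.mark.parametrize(
    "S, d, expected",
    [
        (math.pi * 4.0, 4.0, math.pi / 4),      # circle r=2, d=2r
        (9.0, 3.0, 1.0),                        # square side 3
        (math.pi * 3 * 1, 2.0, 3 * math.pi / 4),  # ellipse a=3, b=1, d=2b
    ],
)
def test_phi_of_reference_shapes(S, d, expected):
    assert cv.shape_ratio_phi(S, d) == pytest.approx(expected, rel=1e-15)


@pytest.mark.parametrize(
    "C, d, expected",
    [
        (2 * math.pi * 2, 4.0, math.pi),  # circle r=2
        (12.0, 3.0, 4.0),                 # square side 3
    ],
)
def test_psi_of_reference_shapes(C, d, expected):
    assert cv.shape_ratio_psi(C, d) == pytest.approx(expected, rel=1e-15)


def test_ratios_reject_degenerate_section():
    with pytest.raises(DegenerateSectionError):
        cv.shape_ratio_phi(1.0, 0.0)
    with pytest.raises(DegenerateSectionError):
        cv.shape_ratio_psi(1.0, 0.0)


def test_psi_warns_when_perimeter_shorter_than_chord_bound():
    with pytest.warns(UserWarning, match="psi"):
        cv.shape_ratio_psi(1.5, 1.0)  # C < 2 d is geometrically impossible


def test_interpolate_ratio_endpoints_and_midpoint():
    assert cv.interpolate_ratio(0, 10, 0.8, 1.0) == 0.8
    assert cv.interpolate_ratio(10, 10, 0.8, 1.0) == 1.0
    assert cv.interpolate_ratio(5, 10, 0.8, 1.0) == pytest.approx(0.9)
    with pytest.raises(IndexError):
        cv.interpolate_ratio(11, 10, 0.8, 1.0)


# ---------------------------------------------------------------------------
# subslab coefficients and closed forms


@given(
    phi=st.tuples(st.floats(0.5, 1.0), st.floats(0.5, 1.0)),
    psi=st.tuples(st.floats(3.2, 4.0), st.floats(3.2, 4.0)),
    d=st.tuples(st.floats(0.1, 2.0), st.floats(0.1, 2.0)),
    Ln=st.floats(0.01, 5.0),
)
@settings(max_examples=100, derandomize=True)
def test_coefficients_reproduce_endpoints(phi, psi, d, Ln):
    c = cv.subslab_coefficients(phi[0], phi[1], psi[0], psi[1], d[0], d[1], Ln)
    d_end, phi_end, psi_end = c.end_values()
    assert d_end == pytest.approx(d[1], rel=1e-12, abs=1e-12)
    assert phi_end == pytest.approx(phi[1], rel=1e-12, abs=1e-12)
    assert psi_end == pytest.approx(psi[1], rel=1e-12, abs=1e-12)


def _coeff(phi0, phi1, psi0, psi1, d0, d1, Ln):
    return cv.subslab_coefficients(phi0, phi1, psi0, psi1, d0, d1, Ln)


def test_constant_section_has_zero_slopes():
    c = _coeff(1.0, 1.0, 4.0, 4.0, 1.0, 1.0, 2.0)
    assert c.alpha == c.beta == c.gamma == 0.0


def test_unit_slopes():
    c = _coeff(1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0)
    assert (c.alpha, c.beta, c.gamma) == (1.0, 1.0, 1.0)
    c2 = _coeff(1.0, 1.0, 3.0, 3.0, 2.0, 0.0, 3.0)
    assert c2.beta == pytest.approx(-2.0 / 3.0)


def test_section_area_evaluation():
    # phi: 1->2, d: 1->2 over Ln=1, so S(l) = (1+l)^3
    c = _coeff(1.0, 2.0, 3.0, 3.0, 1.0, 2.0, 1.0)
    assert cv.section_area_at(0.0, c) == pytest.approx(1.0)
    assert cv.section_area_at(0.5, c) == pytest.approx(1.5**3)
    with pytest.raises(ValidationError):
        cv.section_area_at(1.5, c)
    flat = _coeff(0.9, 0.9, 3.5, 3.5, 1.2, 1.2, 1.0)
    assert cv.section_area_at(0.7, flat) == pytest.approx(0.9 * 1.2**2)


def test_section_circumference_evaluation():
    c = _coeff(1.0, 1.0, 1.0, 2.0, 1.0, 2.0, 1.0)
    assert cv.section_circumference_at(0.0, c) == pytest.approx(1.0)
    assert cv.section_circumference_at(1.0, c) == pytest.approx(4.0)


def test_subslab_volume_closed_forms():
    # cylinder
    flat = _coeff(0.8, 0.8, 3.5, 3.5, 1.5, 1.5, 2.0)
    assert cv.subslab_volume(flat) == pytest.approx(0.8 * 1.5**2 * 2.0, rel=1e-15)
    # integral of (1+l)^3 over [0,1] = 15/4
    c = _coeff(1.0, 2.0, 3.0, 3.0, 1.0, 2.0, 1.0)
    assert cv.subslab_volume(c) == pytest.approx(3.75, rel=1e-14)
    # a circular cone r=1, h=3 as one subslab: V = pi
    cone = _coeff(math.pi / 4, math.pi / 4, math.pi, math.pi, 2.0, 0.0, 3.0)
    assert cv.subslab_volume(cone) == pytest.approx(math.pi, rel=1e-14)


def test_constant_phi_volume_matches_general_form():
    cone = _coeff(math.pi / 4, math.pi / 4, math.pi, math.pi, 2.0, 0.0, 3.0)
    assert cv.subslab_volume_constant_phi(math.pi / 4, cone) == pytest.approx(
        math.pi, rel=1e-14
    )
    flat = _coeff(0.8, 0.8, 3.5, 3.5, 1.5, 1.5, 2.0)
    assert cv.subslab_volume_constant_phi(0.8, flat) == pytest.approx(
        cv.subslab_volume(flat), rel=1e-15
    )


@pytest.mark.parametrize("n", [1, 2, 5, 17])
def test_cone_volume_independent_of_partition(n):
    # the constant-phi form integrates a quadratic exactly, so any equal
    # partition of the same cone sums to the same value
    Phi, d0, L = math.pi / 4, 2.0, 3.0
    Ln = L / n
    d = np.linspace(d0, 0.0, n + 1)
    total = sum(
        cv.subslab_volume_constant_phi(
            Phi, _coeff(Phi, Phi, math.pi, math.pi, d[k], d[k + 1], Ln)
        )
        for k in range(n)
    )
    assert total == pytest.approx(math.pi, rel=1e-13)


def test_subslab_lateral_area_closed_forms():
    flat = _coeff(0.8, 0.8, 3.5, 3.5, 1.5, 1.5, 2.0)
    assert cv.subslab_lateral_area(flat) == pytest.approx(3.5 * 1.5 * 2.0, rel=1e-15)
    # integral of (1+l)^2 over [0,1] = 7/3
    c = _coeff(1.0, 1.0, 1.0, 2.0, 1.0, 2.0, 1.0)
    assert cv.subslab_lateral_area(c) == pytest.approx(7.0 / 3.0, rel=1e-14)
    # cone r=1, h=3: method area = integral of C = 3 pi (not slant pi sqrt(10))
    cone = _coeff(math.pi / 4, math.pi / 4, math.pi, math.pi, 2.0, 0.0, 3.0)
    assert cv.subslab_lateral_area(cone) == pytest.approx(3 * math.pi, rel=1e-14)


@pytest.mark.parametrize("n", [1, 3, 8])
def test_constant_psi_area_matches_general_and_partition(n):
    Psi, d0, L = math.pi, 2.0, 3.0
    Ln = L / n
    d = np.linspace(d0, 0.0, n + 1)
    total = sum(
        cv.subslab_lateral_area_constant_psi(
            Psi, _coeff(1.0, 1.0, Psi, Psi, d[k], d[k + 1], Ln)
        )
        for k in range(n)
    )
    assert total == pytest.approx(3 * math.pi, rel=1e-13)
    assert cv.subslab_lateral_area_constant_psi(
        Psi, _coeff(1.0, 1.0, Psi, Psi, 0.0, 0.0, 1.0)
    ) == 0.0


# ---------------------------------------------------------------------------
# slabs


def cylinder_slab(r=0.7, L=2.0, n=5):
    sec0 = cv.CrossSection(station=0.0, d=2 * r, S=math.pi * r**2, C=2 * math.pi * r)
    sec1 = cv.CrossSection(station=L, d=2 * r, S=math.pi * r**2, C=2 * math.pi * r)
    return cv.Slab(anterior=sec0, posterior=sec1, n=n,
                   interior_d=(2 * r,) * (n - 1), mode="frustum")


@pytest.mark.parametrize("n", range(1, 51))
def test_cylinder_exactness_for_all_subslab_counts(n):
    r, L = 0.7, 2.0
    slab = cylinder_slab(r, L, n)
    assert cv.slab_volume(slab) == pytest.approx(math.pi * r**2 * L, rel=1e-12)
    assert cv.slab_area(slab) == pytest.approx(2 * math.pi * r * L, rel=1e-12)


@pytest.mark.parametrize("n", [1, 2, 7, 30])
def test_cone_mode_exactness_any_n(n):
    r, L = 0.5, 1.5
    base = cv.CrossSection(station=0.0, d=2 * r, S=math.pi * r**2, C=2 * math.pi * r)
    apex = cv.CrossSection(station=L, d=0.0)
    interior = tuple(2 * r * (1 - k / n) for k in range(1, n))
    slab = cv.Slab(anterior=base, posterior=apex, n=n, interior_d=interior,
                   mode="cone")
    assert cv.slab_volume(slab) == pytest.approx(math.pi * r**2 * L / 3, rel=1e-12)
    assert cv.slab_area(slab) == pytest.approx(math.pi * r * L, rel=1e-12)


def test_frustum_with_constant_phi_matches_analytic_integral():
    # phi constant, d linear d0 -> dn: V = Phi L (d0^2 + d0 dn + dn^2)/3
    Phi, Psi = 0.9, 3.7
    d0, dn, L, n = 1.0, 2.0, 3.0, 6
    d = np.linspace(d0, dn, n + 1)
    sec0 = cv.CrossSection(station=0.0, d=d0, S=Phi * d0**2, C=Psi * d0)
    sec1 = cv.CrossSection(station=L, d=dn, S=Phi * dn**2, C=Psi * dn)
    slab = cv.Slab(anterior=sec0, posterior=sec1, n=n, interior_d=tuple(d[1:-1]))
    assert cv.slab_volume(slab) == pytest.approx(
        Phi * L * (d0**2 + d0 * dn + dn**2) / 3, rel=1e-12
    )
    assert cv.slab_area(slab) == pytest.approx(Psi * L * (d0 + dn) / 2, rel=1e-12)


def test_slab_rejects_malformed_interior():
    sec0 = cv.CrossSection(station=0.0, d=1.0, S=0.8, C=3.5)
    sec1 = cv.CrossSection(station=1.0, d=1.0, S=0.8, C=3.5)
    with pytest.raises(ValidationError):
        cv.Slab(anterior=sec0, posterior=sec1, n=3, interior_d=(1.0,))


def test_cone_mode_requires_one_apex():
    sec0 = cv.CrossSection(station=0.0, d=1.0, S=0.8, C=3.5)
    sec1 = cv.CrossSection(station=1.0, d=1.0, S=0.8, C=3.5)
    with pytest.raises(ValidationError):
        cv.Slab(anterior=sec0, posterior=sec1, n=1, mode="cone")


def test_slab_integrals_match_quadrature_oracle(rng):
    """Closed forms equal adaptive quadrature of the piecewise S(l), C(l)."""
    for _ in range(20):
        slab = random_frustum_slab(rng)
        v_quad = quad(lambda x: slab_section_area(slab, x), 0, slab.L,
                      points=np.linspace(0, slab.L, slab.n + 1), limit=200)[0]
        a_quad = quad(lambda x: slab_section_circumference(slab, x), 0, slab.L,
                      points=np.linspace(0, slab.L, slab.n + 1), limit=200)[0]
        assert cv.slab_volume(slab) == pytest.approx(v_quad, rel=1e-10)
        assert cv.slab_area(slab) == pytest.approx(a_quad, rel=1e-10)


# ---------------------------------------------------------------------------
# bodies


def test_single_slab_body_equals_slab():
    slab = cylinder_slab()
    body = cv.BodyMeasurement(slabs=[slab])
    assert cv.body_volume(body) == cv.slab_volume(slab)
    assert cv.body_area(body) == cv.slab_area(slab)


def test_splitting_a_slab_at_interpolated_section_preserves_volume(rng):
    """Cutting a slab in two at one of its own subslab boundaries (with the
    interpolated phi/psi as the new section) leaves volume and area
    unchanged to quadrature accuracy."""
    slab = random_frustum_slab(rng, n=6)
    d = slab.d_profile()
    phi, psi = slab._ratio_profiles()
    cut = 3
    mid_station = slab.anterior.station + cut * slab.Ln
    mid = cv.CrossSection(station=mid_station, d=d[cut],
                          S=phi[cut] * d[cut] ** 2, C=psi[cut] * d[cut])
    left = cv.Slab(anterior=slab.anterior, posterior=mid, n=cut,
                   interior_d=tuple(d[1:cut]))
    right = cv.Slab(anterior=mid, posterior=slab.posterior, n=slab.n - cut,
                    interior_d=tuple(d[cut + 1:-1]))
    split = cv.BodyMeasurement(slabs=[left, right])
    whole = cv.BodyMeasurement(slabs=[slab])
    assert cv.body_volume(split) == pytest.approx(cv.body_volume(whole), rel=1e-10)
    assert cv.body_area(split) == pytest.approx(cv.body_area(whole), rel=1e-10)


def test_appendage_additivity():
    main = cylinder_slab(r=0.5, L=2.0)
    fin = cylinder_slab(r=0.1, L=0.5)
    body = cv.BodyMeasurement(slabs=[main],
                              appendages=[cv.BodyMeasurement(slabs=[fin])])
    assert cv.body_volume(body) == pytest.approx(
        cv.slab_volume(main) + cv.slab_volume(fin), rel=1e-15
    )


def test_boundary_mismatch_raises():
    s0 = cv.CrossSection(station=0.0, d=1.0, S=0.8, C=3.5)
    s1a = cv.CrossSection(station=1.0, d=1.0, S=0.8, C=3.5)
    s1b = cv.CrossSection(station=1.0, d=1.1, S=0.8, C=3.5)  # 10% off
    s2 = cv.CrossSection(station=2.0, d=1.0, S=0.8, C=3.5)
    a = cv.Slab(anterior=s0, posterior=s1a, n=1)
    b = cv.Slab(anterior=s1b, posterior=s2, n=1)
    with pytest.raises(ValidationError, match="adjacent slabs"):
        cv.BodyMeasurement(slabs=[a, b])


def test_rescaling_preserves_shape_ratios_and_scales_quantities():
    slab = cylinder_slab(r=0.7, L=2.0, n=4)
    body = cv.BodyMeasurement(slabs=[slab])
    scaled = cv.rescale_body(body, total_length=1.0)
    assert scaled.total_length == pytest.approx(1.0)
    f = 0.5  # 1.0 / 2.0
    assert cv.body_volume(scaled) == pytest.approx(cv.body_volume(body) * f**3,
                                                   rel=1e-12)
    assert cv.body_area(scaled) == pytest.approx(cv.body_area(body) * f**2,
                                                 rel=1e-12)


def test_first_moment_matches_quadrature(rng):
    for _ in range(10):
        slab = random_frustum_slab(rng, n=1)
        c = slab.coefficients()[0]
        oracle = quad(lambda l: l * cv.section_area_at(l, c), 0, c.Ln, limit=100)[0]
        assert subslab_first_moment(c) == pytest.approx(oracle, rel=1e-10)
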