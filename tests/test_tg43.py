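"""TG-43 formalism: geometry function, extraction, fitting, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from ybm42 import (
    anisotropy_function,
    air_kerma_strength,
    dose_rate_constant,
    extract_parameters,
    fit_radial_polynomial,
    geometry_function_line,
    isodose_contours,
    load_fixture,
    radial_dose_function,
    reconstruct_dose,
)
from ybm42.scoring import PolarDoseTable
from ybm42.tg43 import dose_plane

L = 0.6


def _gl_quadrature(r, theta_deg, length):
    """Independent oracle: (1/L) * integral of 1/|P - s zhat|^2 over the line."""
    t = np.radians(theta_deg)
    px, pz = r * np.sin(t), r * np.cos(t)

    def integrand(s):
        return 1.0 / (px**2 + (pz - s) ** 2)

    val, _ = quad(integrand, -length / 2, length / 2, epsabs=0, epsrel=1e-10)
    return val / length


def test_geometry_function_reference_values():
    # transverse: beta/(L r sin t) = 2 arctan(L/2r) / (L r)
    assert geometry_function_line(1.0, 90.0, L) == pytest.approx(
        2 * np.arctan(L / 2.0) / L, rel=1e-12
    )
    assert geometry_function_line(1.0, 90.0, L) == pytest.approx(0.97152, abs=5e-6)
    # on axis: 1/(r^2 - L^2/4)
    assert geometry_function_line(0.5, 0.0, L) == pytest.approx(6.25, rel=1e-12)
    assert geometry_function_line(0.5, 180.0, L) == pytest.approx(6.25, rel=1e-12)


def test_geometry_function_point_source_limit():
    for r, t in [(0.5, 30.0), (1.0, 90.0), (5.0, 120.0)]:
        assert geometry_function_line(r, t, 1e-5) == pytest.approx(1 / r**2, rel=1e-6)


def test_geometry_function_domain_errors():
    with pytest.raises(ValueError):
        geometry_function_line(0.2, 0.0, L)  # on the active segment
    with pytest.raises(ValueError):
        geometry_function_line(-1.0, 90.0, L)


def test_geometry_function_matches_line_integral_oracle():
    rs = np.linspace(0.35, 10.0, 50)
    ts = np.linspace(1.0, 179.0, 50)
    for r in rs:
        for t in ts:
            assert geometry_function_line(r, t, L) == pytest.approx(
                _gl_quadrature(r, t, L), rel=1e-6
            )


def test_geometry_function_continuous_near_axis():
    # the off-axis formula approaches the on-axis limit
    assert geometry_function_line(1.0, 1e-4, L) == pytest.approx(
        geometry_function_line(1.0, 0.0, L), rel=1e-6
    )


def test_normalisation_exactness():
    table = load_fixture("table1")
    g = radial_dose_function(table, L)
    assert g[1.0] == 1.0
    f = anisotropy_function(table, L)
    for r in table.r_cm:
        assert f[(float(r), 90.0)] == 1.0


def test_missing_reference_cell_raises():
    table = load_fixture("table1")
    no_ref = PolarDoseTable(
        table.r_cm[2:], table.theta_deg, table.dose[:, 2:], None
    )  # drops r = 1 cm
    with pytest.raises(KeyError):
        radial_dose_function(no_ref, L)


@settings(max_examples=50, derandomize=True)
@given(scale=st.floats(1e-3, 1e3))
def test_extraction_invariant_under_rescaling(scale):
    table = load_fixture("table1")
    scaled = PolarDoseTable(table.r_cm, table.theta_deg, table.dose * scale, None)
    g0 = radial_dose_function(table, L)
    g1 = radial_dose_function(scaled, L)
    assert np.allclose(list(g0.values()), list(g1.values()), rtol=1e-12)
    lam0 = dose_rate_constant(table.cell(1, 90), 1.082)
    lam1 = dose_rate_constant(scaled.cell(1, 90), 1.082 * scale)
    assert lam1 == pytest.approx(lam0, rel=1e-12)


def test_air_kerma_strength_unit_conversion():
    # 1e-4 cGy/h at 100 cm is exactly 1 U (uGy m^2/h)
    assert air_kerma_strength(1e-4, 100.0) == pytest.approx(1.0, rel=1e-12)
    assert air_kerma_strength(0.0, 100.0) == 0.0
    assert air_kerma_strength(5e-5, 100.0) == pytest.approx(0.5, rel=1e-12)


def test_dose_rate_constant_ratio_properties():
    assert dose_rate_constant(2.5, 2.5) == pytest.approx(1.0)
    assert dose_rate_constant(3 * 1.229, 3 * 1.082) == pytest.approx(
        dose_rate_constant(1.229, 1.082), rel=1e-12
    )
    with pytest.raises(ValueError):
        dose_rate_constant(1.0, 0.0)


def test_polynomial_fit_recovers_exact_coefficients():
    truth = np.array([0.92, 0.09, -0.013, 0.0028, -4e-4, 2e-5])
    r = np.linspace(0.5, 10, 11)
    g = {float(x): float(np.polynomial.polynomial.polyval(x, truth)) for x in r}
    coeffs, r2 = fit_radial_polynomial(g)
    assert np.allclose(coeffs, truth, atol=1e-9)
    assert r2 == pytest.approx(1.0, abs=1e-12)


def test_polynomial_fit_requires_enough_points():
    with pytest.raises(ValueError):
        fit_radial_polynomial({float(r): 1.0 for r in range(6)})


def test_reconstruction_at_reference_returns_sk_lambda():
    table = load_fixture("table1")
    params = extract_parameters(table, L, s_k_per_mci=1.082)
    val = reconstruct_dose(params, 1.0, 90.0, s_k=1.082)
    assert val == pytest.approx(params.dose_rate_constant * 1.082, rel=1e-12)


def test_reconstruction_round_trip_on_grid_nodes():
    table = load_fixture("table1")
    s_k = 1.082
    params = extract_parameters(table, L, s_k_per_mci=s_k)
    for i, t in enumerate(table.theta_deg):
        for j, r in enumerate(table.r_cm):
            rec = reconstruct_dose(params, float(r), float(t), s_k=s_k)
            assert rec == pytest.approx(table.dose[i, j], rel=5e-3)


def test_reconstruction_linear_in_sk_and_range_checked():
    table = load_fixture("table1")
    params = extract_parameters(table, L, s_k_per_mci=1.0)
    one = reconstruct_dose(params, 2.0, 45.0, s_k=1.0)
    assert reconstruct_dose(params, 2.0, 45.0, s_k=2.0) == pytest.approx(2 * one)
    with pytest.raises(ValueError):
        reconstruct_dose(params, 12.0, 90.0, s_k=1.0)


@settings(max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_extraction_reconstruction_identity_on_random_tables(seed):
    """extract -> reconstruct is the identity at grid nodes for any positive table."""
    rng = np.random.default_rng(seed)
    r = np.array([0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0])
    t = np.arange(0.0, 181.0, 30.0)
    dose = rng.uniform(0.05, 5.0, size=(t.size, r.size))
    table = PolarDoseTable(r, t, dose)
    params = extract_parameters(table, L, s_k_per_mci=1.0)
    for i, tt in enumerate(t):
        for j, rr in enumerate(r):
            rec = reconstruct_dose(params, float(rr), float(tt), s_k=1.0)
            assert rec == pytest.approx(dose[i, j], rel=1e-9)


def test_isodose_circular_map_gives_circular_contours():
    x = np.linspace(-2, 2, 801)
    xx, yy = np.meshgrid(x, x)
    rr = np.hypot(xx, yy)
    dose = 1.0 / (0.05 + rr**2)
    level = 1.0 / (0.05 + 1.0)
    contours = isodose_contours(dose, [level], x=x, y=x)
    (poly,) = contours[level]
    radii = np.hypot(poly[:, 0], poly[:, 1])
    ecc = (radii.max() - radii.min()) / radii.mean()
    assert ecc < 1e-3


def test_isodose_of_extracted_parameters_squeezed_along_axis():
    table = load_fixture("table1")
    params = extract_parameters(table, L, s_k_per_mci=1.082)
    level = reconstruct_dose(params, 1.0, 90.0, s_k=1.082)
    y, z, dose = dose_plane(params, s_k=1.082, half_extent=3.0, n=401)
    contours = isodose_contours(dose, [level], x=y, y=z)
    pts = np.vstack(contours[level])
    on_axis = pts[np.abs(pts[:, 0]) < 0.02]      # near the source axis (y ~ 0)
    transverse = pts[np.abs(pts[:, 1]) < 0.02]   # near the transverse plane
    assert on_axis.size and transverse.size
    # polar dose suppression (F < 1): contour hugs the source along the axis
    assert np.abs(on_axis[:, 1]).max() < np.abs(transverse[:, 0]).max()


def test_isodose_empty_levels():
    assert isodose_contours(np.ones((5, 5)), []) == {}
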