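"""Detector grid geometry, bin lookup, unit conversion, bin averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ybm42 import average_symmetric_bins, bin_index, per_history_to_clinical
from ybm42.scoring import UNITS, PolarDoseTable, RingDetectorGrid


def test_analytic_volumes_match_numerical_integration(grid):
    """V = int r^2 sin(theta) dr dtheta dphi over every bin, Gauss quadrature."""
    x, w = np.polynomial.legendre.leggauss(24)
    vols = grid.volumes()
    for i in range(grid.n_polar):
        t1, t2 = np.radians(grid.theta_lo[i]), np.radians(grid.theta_hi[i])
        tt = 0.5 * (t2 - t1) * x + 0.5 * (t1 + t2)
        wt = 0.5 * (t2 - t1) * w
        for j in range(grid.n_radial):
            r1, r2 = grid.r_lo[j], grid.r_hi[j]
            rr = 0.5 * (r2 - r1) * x + 0.5 * (r1 + r2)
            wr = 0.5 * (r2 - r1) * w
            num = 2 * np.pi * np.sum(wr * rr**2) * np.sum(wt * np.sin(tt))
            assert num == pytest.approx(vols[i, j], rel=1e-6)


def test_total_bin_volume_below_phantom_volume(grid):
    assert grid.volumes().sum() < 4 / 3 * np.pi * 50.0**3


def test_bin_index_examples(grid):
    assert bin_index(np.array([0.0, 0.0, 1.0]), grid) == (1, 0)      # on tip axis, r=1
    assert bin_index(np.array([1.0, 0.0, 0.0]), grid) == (1, 9)      # transverse, r=1
    assert bin_index(np.array([0.0, 0.0, -0.5]), grid) == (0, 18)    # cable side cap
    assert bin_index(np.array([1.5, 0.0, 0.0]), grid) == (-1, -1)    # radial gap
    r = 1.0
    p = np.array([r * np.sin(np.radians(5.0)), 0.0, r * np.cos(np.radians(5.0))])
    assert bin_index(p, grid) == (-1, -1)                            # polar gap


def test_monte_carlo_volume_fractions_match_analytic(grid, rng):
    n = 1_000_000
    R = 10.5
    pts = rng.uniform(-R, R, size=(3 * n, 3))
    pts = pts[np.sum(pts**2, axis=1) <= R * R][:n]
    ir, it = bin_index(pts, grid)
    vols = grid.volumes()
    v_sphere = 4 / 3 * np.pi * R**3
    counts = np.zeros_like(vols)
    ok = ir >= 0
    np.add.at(counts, (it[ok], ir[ok]), 1)
    expected = vols / v_sphere * len(pts)
    sigma = np.sqrt(np.maximum(expected, 1.0))
    assert np.all(np.abs(counts - expected) < 4 * sigma + 4)


@settings(max_examples=200, derandomize=True)
@given(
    r=st.floats(0.01, 12.0),
    theta=st.floats(0.0, 180.0),
    phi=st.floats(0.0, 2 * np.pi),
)
def test_grid_totality_and_membership(r, theta, phi):
    """Every point maps to at most one bin, and a mapped bin contains it."""
    grid = RingDetectorGrid.default()
    t = np.radians(theta)
    p = np.array([r * np.sin(t) * np.cos(phi), r * np.sin(t) * np.sin(phi), r * np.cos(t)])
    ir, it = bin_index(p, grid)
    if ir >= 0:
        assert grid.r_lo[ir] <= r <= grid.r_hi[ir] + 1e-9
        assert grid.theta_lo[it] - 1e-9 <= theta <= grid.theta_hi[it] + 1e-9
    else:
        in_r = np.any((grid.r_lo <= r) & (r < grid.r_hi))
        in_t = np.any((grid.theta_lo <= theta) & (theta <= grid.theta_hi))
        assert not (in_r and in_t)


def test_unit_conversion_closed_form():
    # hand arithmetic: 1e6 keV in 1 g, yield 1 ->
    # 1e6 * 1.602176634e-16 J / 1e-3 kg * 100 cGy/Gy * 3.7e7 /s * 3600 s/h
    expected = 1e6 * 1.602176634e-16 / 1e-3 * 100 * 3.7e7 * 3600
    assert per_history_to_clinical(1e6, 1.0, 1.0) == pytest.approx(expected, rel=1e-12)
    assert per_history_to_clinical(0.0, 1.0, 3.0) == 0.0
    assert per_history_to_clinical(1.0, 1.0, 2.0) == pytest.approx(
        2 * per_history_to_clinical(1.0, 1.0, 1.0)
    )
    with pytest.raises(ValueError):
        per_history_to_clinical(1.0, 0.0, 1.0)


def test_unit_constants_round_trip():
    assert UNITS.mci_to_bq == 3.7e7
    assert 1.0 / (1.0 / UNITS.kev_to_joule) == pytest.approx(UNITS.kev_to_joule, rel=1e-12)


def _frame(rows):
    return pd.DataFrame(rows, columns=["r_cm", "theta_deg", "dose_rate_cGy_per_h_per_mCi", "rel_err"])


def test_average_unique_rows_unchanged():
    frame = _frame([(1.0, 90.0, 2.0, 0.01), (2.0, 90.0, 1.0, 0.02)])
    out = average_symmetric_bins(frame)
    assert out.cell(1.0, 90.0) == pytest.approx(2.0)
    assert out.cell(2.0, 90.0) == pytest.approx(1.0)


def test_average_equal_errors_is_arithmetic_mean():
    frame = _frame([(1.0, 90.0, 2.0, 0.01), (1.0, 90.0, 4.0, 0.005)])
    # equal absolute errors: 2.0*0.01 == 4.0*0.005
    out = average_symmetric_bins(frame)
    assert out.cell(1.0, 90.0) == pytest.approx(3.0)


def test_average_weighted_by_inverse_variance():
    frame = _frame([(1.0, 90.0, 1.0, 1.0), (1.0, 90.0, 2.0, 1.0)])
    # absolute errors 1 and 2 -> weights 4:1 -> (4*1 + 1*2)/5
    out = average_symmetric_bins(frame)
    assert out.cell(1.0, 90.0) == pytest.approx((4 * 1.0 + 1 * 2.0) / 5)


def test_polar_table_csv_round_trip(tmp_path):
    grid = RingDetectorGrid.default()
    rng = np.random.default_rng(0)
    dose = rng.uniform(0.5, 2.0, size=(grid.n_polar, grid.n_radial))
    err = np.full_like(dose, 0.01)
    table = PolarDoseTable(grid.radial_nodes, grid.polar_nodes, dose, err, meta={"seed": "7"})
    path = tmp_path / "t.csv"
    table.write_csv(path)
    back = PolarDoseTable.read_csv(path)
    assert np.allclose(back.dose, dose)
    assert np.allclose(back.rel_err, err)
    assert back.meta["seed"] == "7"
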