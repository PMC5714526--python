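"""Monte Carlo transport: determinism, closed-form oracles, error scaling."""

import math

import numpy as np
import pytest

from ybm42 import (
    AirKermaSpec,
    PhotonState,
    RingDetectorGrid,
    SimulationConfig,
    air_kerma_strength,
    build_default_m42,
    run_air_kerma,
    run_water_phantom,
    transport_photon,
)
from ybm42.physics import material_table
from ybm42.scoring import UNITS
from ybm42.source import AIR, WATER, ConfigError
from ybm42.transport import TransportContext


@pytest.fixture(scope="module")
def bare_source():
    """Point-like, effectively transparent source: capsules and cable removed,
    core shrunk to 1 um scale with negligible density."""
    return build_default_m42(
        {
            "drop_regions": ["inner_capsule", "outer_capsule", "cable"],
            "regions": {
                "core": {"radius": 1e-4, "zmin": -1e-4, "zmax": 1e-4, "density": 1e-6}
            },
        }
    )


def test_fixed_seed_bit_identical(m42, grid):
    cfg = SimulationConfig(n_histories=30_000, rng_seed=77, batch_count=5)
    a = run_water_phantom(m42, grid, cfg)
    b = run_water_phantom(m42, grid, cfg)
    assert np.array_equal(a.dose, b.dose)
    assert np.array_equal(a.rel_err, b.rel_err, equal_nan=True)
    c = run_water_phantom(m42, grid, SimulationConfig(30_000, 78, batch_count=5))
    assert not np.array_equal(a.dose, c.dose)


def test_config_invariants():
    with pytest.raises(ConfigError):
        SimulationConfig(n_histories=10, batch_count=20)
    with pytest.raises(ConfigError):
        SimulationConfig(batch_count=1)
    with pytest.raises(ConfigError):
        AirKermaSpec(inner_radius=101.0)
    with pytest.raises(ConfigError):
        AirKermaSpec(cone_min_deg=87.0, cone_max_deg=92.0)


def test_zero_score_bins_flagged_not_silent(m42, grid):
    cfg = SimulationConfig(n_histories=2_000, rng_seed=5, batch_count=2)
    table = run_water_phantom(m42, grid, cfg)
    empty = table.dose == 0.0
    assert empty.any()  # a 2k-history run cannot populate the far bins
    assert np.all(np.isnan(table.rel_err[empty]))


def test_bookkeeping_counters(small_water_table, grid, m42):
    meta = small_water_table.meta
    assert meta["lost_particles"] == 0
    assert 0 < meta["scored_kev_total"] <= meta["emitted_kev"]
    assert 0 < meta["scored_kev_in_bins"] <= meta["scored_kev_total"]
    # the per-bin dose grid re-aggregates exactly to the in-bin counter
    conv = (
        UNITS.kev_per_gram_to_cgy
        * UNITS.mci_to_bq
        * m42.spectrum.total_yield
        * UNITS.s_per_h
    )
    kev_in_bins = (small_water_table.dose / conv * grid.masses()).sum() * meta["histories"]
    assert kev_in_bins == pytest.approx(meta["scored_kev_in_bins"], rel=1e-9)


def test_emitted_energy_matches_spectrum_mean(small_water_table, m42):
    per_hist = small_water_table.meta["emitted_kev"] / small_water_table.meta["histories"]
    assert per_hist == pytest.approx(m42.spectrum.mean_energy, rel=5e-3)


def test_inverse_square_law_without_attenuation(bare_source):
    """Bare source in vacuum: kerma x d^2 is distance-independent."""
    results = []
    for d in (20.0, 50.0, 90.0):
        spec = AirKermaSpec(inner_radius=d - 2.5, outer_radius=d + 2.5,
                            reference_distance=d)
        cfg = SimulationConfig(n_histories=100_000, rng_seed=31, phantom="vacuum",
                               phantom_radius=120.0, batch_count=10)
        res = run_air_kerma(bare_source, spec, cfg)
        results.append((air_kerma_strength(res.rate, d), res.rel_err))
    (s0, e0), (s1, e1), (s2, e2) = results
    assert abs(s1 - s0) < 3 * math.hypot(e0 * s0, e1 * s1)
    assert abs(s2 - s0) < 3 * math.hypot(e0 * s0, e2 * s2)


def test_bare_source_air_kerma_matches_analytic(bare_source):
    """No encapsulation: S_k equals sum_i I_i E_i (mu_en/rho)_air / (4 pi d^2)."""
    cfg = SimulationConfig(n_histories=200_000, rng_seed=32, phantom="vacuum",
                           batch_count=10)
    res = run_air_kerma(bare_source, AirKermaSpec(), cfg)
    s_k = air_kerma_strength(res.rate, 100.0)
    air = material_table(AIR)
    spec = bare_source.spectrum
    kev_cm2_per_g = float(
        np.sum(spec.intensities * spec.energies * air.energy_absorption(spec.energies))
    )
    kerma_kev_per_g = kev_cm2_per_g / (4 * math.pi * 100.0**2) / spec.total_yield
    expected = (
        kerma_kev_per_g
        * UNITS.kev_per_gram_to_cgy
        * UNITS.mci_to_bq
        * spec.total_yield
        * UNITS.s_per_h
        * 100.0**2
    )
    assert s_k == pytest.approx(expected, rel=max(3 * res.rel_err, 0.01))


def test_primary_kerma_matches_closed_form(bare_source, grid):
    """Unscattered-only scoring against the analytic primary-kerma shell average."""
    cfg = SimulationConfig(n_histories=300_000, rng_seed=33, batch_count=10,
                           primary_only=True)
    table = run_water_phantom(bare_source, grid, cfg)
    water = material_table(WATER)
    spec = bare_source.spectrum
    p = spec.intensities / spec.total_yield
    conv = (
        UNITS.kev_per_gram_to_cgy * UNITS.mci_to_bq * spec.total_yield * UNITS.s_per_h
    )
    s_grid = np.linspace(0, 1, 501)
    for j, r in enumerate([1.0, 2.0, 3.0]):
        jj = int(np.where(grid.radial_nodes == r)[0][0])
        r1, r2 = grid.r_lo[jj], grid.r_hi[jj]
        s = r1 + (r2 - r1) * s_grid
        kev_per_g = 0.0
        for pi, ei in zip(p, spec.energies):
            mu = water.total(ei) * WATER.density
            muen = water.energy_absorption(ei)
            shell_integral = np.trapezoid(np.exp(-mu * s), s)
            kev_per_g += pi * ei * muen * shell_integral
        # dose rate = conv * (solid-angle fraction) * sum_i p E muen int e^{-mu s} ds / V
        v_bin = grid.volumes()[9, jj]
        omega_frac = (v_bin * 3 / (r2**3 - r1**3)) / (4 * np.pi)
        expected = conv * kev_per_g * omega_frac / v_bin
        sim = table.cell(r, 90.0)
        err = table.rel_err[9, jj]
        assert sim == pytest.approx(expected, rel=max(3 * err, 0.02))


def test_batch_error_scales_as_inverse_sqrt_n(m42, grid):
    """log-log slope of the batch-means relative error vs history count."""
    ns = [200_000, 800_000, 3_200_000]
    mean_log_err = []
    sel_t = [7, 8, 9, 10, 11]          # 70-110 degrees
    sel_r = [1, 2, 3]                  # 1-3 cm
    for i, n in enumerate(ns):
        cfg = SimulationConfig(n_histories=n, rng_seed=40 + i, batch_count=20)
        table = run_water_phantom(m42, grid, cfg)
        errs = table.rel_err[np.ix_(sel_t, sel_r)]
        assert np.all(np.isfinite(errs))
        mean_log_err.append(np.mean(np.log(errs)))
    slope = np.polyfit(np.log(ns), mean_log_err, 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.05)


def test_cylindrical_scoring_rebins_to_polar(m42, grid):
    polar = run_water_phantom(
        m42, grid, SimulationConfig(n_histories=400_000, rng_seed=55, batch_count=10)
    )
    cyl = run_water_phantom(
        m42, grid,
        SimulationConfig(n_histories=400_000, rng_seed=56, batch_count=10,
                         scoring_mode="cylindrical"),
    )
    for r in (1.0, 2.0):
        assert cyl.cell(r, 90.0) == pytest.approx(polar.cell(r, 90.0), rel=0.15)


def test_transport_photon_vacuum_traversal(bare_source, rng):
    ctx = TransportContext(bare_source, None)
    state = PhotonState(np.array([0.5, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]), 100.0)
    events = transport_photon(state, ctx, rng, phantom_radius=10.0)
    assert events == []
    assert not state.alive


def test_transport_photon_attenuation_oracle(bare_source, rng):
    """Fraction reaching 1 cm unscattered = exp(-mu * 1 cm) in water."""
    ctx = TransportContext(bare_source, WATER)
    n = 4000
    survived = 0
    for _ in range(n):
        state = PhotonState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 100.0)
        events = transport_photon(state, ctx, rng, phantom_radius=50.0)
        first = events[0]["position"][2] if events else np.inf
        survived += first > 1.0
    expected = math.exp(-material_table(WATER).total(100.0) * WATER.density * 1.0)
    sigma = math.sqrt(expected * (1 - expected) / n)
    assert abs(survived / n - expected) < 4 * sigma
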