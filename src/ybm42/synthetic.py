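"""Synthetic polar dose tables with known TG-43 structure.

The generator builds D(r, theta) = C * G_L(r, theta) * g*(r) * F*(r, theta)
* (1 + eps) with eps ~ Normal(0, sigma) per cell, so every stage of the
extraction pipeline can be tested without running photon transport and its
output compared against the exact truth (Lambda*, g*, F*).

Defaults mirror the published characterisation conditions: Lambda* = 1.14
cGy/h/U, g* = the published fifth-order radial polynomial renormalised to
g*(1) = 1, and a polar anisotropy dip F* = 1 - A(r) cos^2(theta) with A
decreasing in r, qualitatively matching the published anisotropy surface
without copying its values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixtures import load_fixture
from .scoring import PolarDoseTable, RingDetectorGrid
from .tg43 import geometry_function_line, R0_CM, THETA0_DEG

__all__ = ["SyntheticSpec", "generate_polar_dose_table"]


def _default_g_coeffs() -> np.ndarray:
    c = np.array(load_fixture("constants")["poly_coeffs_a0_a5"], dtype=float)
    return c / np.polynomial.polynomial.polyval(1.0, c)  # enforce g*(1) = 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and noise level for one synthetic table."""

    lambda_star: float = 1.14            # cGy/h/U
    s_k: float = 1.0                     # U per activity unit (unit-strength convention)
    g_coeffs: np.ndarray = field(default_factory=_default_g_coeffs)
    dip_amplitude: float = 0.40          # A(0.5); F* = 1 - A(r) cos^2 theta
    dip_decay: float = 0.10              # A(r) = A0 / (1 + decay * (r - 0.5))
    noise_sigma: float = 0.0             # relative Gaussian sigma per cell
    rng_seed: int = 0
    active_length: float = 0.6           # cm

    def __post_init__(self):
        g = np.asarray(self.g_coeffs, dtype=float)
        object.__setattr__(self, "g_coeffs", g)
        if abs(np.polynomial.polynomial.polyval(1.0, g) - 1.0) > 1e-9:
            raise ValueError("g* must satisfy g*(1) = 1")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not 0 <= self.dip_amplitude < 1:
            raise ValueError("dip amplitude must be in [0, 1)")

    def g_star(self, r) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(r, dtype=float), self.g_coeffs)

    def f_star(self, r, theta_deg) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        t = np.radians(np.asarray(theta_deg, dtype=float))
        amp = self.dip_amplitude / (1.0 + self.dip_decay * (r - 0.5))
        return 1.0 - amp * np.cos(t) ** 2


def generate_polar_dose_table(
    spec: SyntheticSpec, grid: RingDetectorGrid | None = None
) -> PolarDoseTable:
    """Build a noisy polar dose table whose exact TG-43 decomposition is known.

    The overall constant is chosen so that D(r0, theta0) = Lambda* x S_k
    exactly before noise; by construction the same seed gives an identical
    table.
    """
    grid = grid or RingDetectorGrid.default()
    r = grid.radial_nodes
    theta = grid.polar_nodes
    rr = np.broadcast_to(r[None, :], (theta.size, r.size))
    tt = np.broadcast_to(theta[:, None], (theta.size, r.size))
    gl = geometry_function_line(rr, tt, spec.active_length)
    gl0 = geometry_function_line(R0_CM, THETA0_DEG, spec.active_length)
    clean = (
        spec.lambda_star * spec.s_k * (gl / gl0) * spec.g_star(rr) * spec.f_star(rr, tt)
    )
    rng = np.random.default_rng(spec.rng_seed)
    noisy = clean * (1.0 + spec.noise_sigma * rng.standard_normal(clean.shape))
    rel = np.full_like(noisy, spec.noise_sigma)
    meta = {
        "generator": "synthetic-tg43",
        "lambda_star": spec.lambda_star,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.rng_seed,
    }
    return PolarDoseTable(r, theta, noisy, rel, meta=meta)
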