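"""TG-43U1/HEBD dose formalism for a cylindrically symmetric line source.

The two-dimensional dose-rate model is

    D(r, theta) = S_k * Lambda * [G_L(r, theta) / G_L(r0, theta0)]
                  * g_L(r) * F(r, theta)

with reference point (r0, theta0) = (1 cm, 90 deg), line-source geometry
function G_L = beta / (L r sin theta) (beta the angle the active line subtends
at the field point), radial dose function g_L, 2D anisotropy function F,
air-kerma strength S_k (U = uGy m^2/h) and dose-rate constant Lambda
(cGy/h/U).  Extraction from a polar dose-rate grid is pure algebra; the
extraction and Eq.-style reconstruction are exact inverses at grid nodes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .scoring import PolarDoseTable

__all__ = [
    "TG43ParameterSet",
    "geometry_function_line",
    "radial_dose_function",
    "anisotropy_function",
    "air_kerma_strength",
    "dose_rate_constant",
    "fit_radial_polynomial",
    "extract_parameters",
    "reconstruct_dose",
    "isodose_contours",
    "dose_plane",
]

R0_CM = 1.0
THETA0_DEG = 90.0


def geometry_function_line(r, theta_deg, length: float):
    """Line-source geometry function G_L(r, theta) in cm^-2.

    ``beta / (L r sin theta)`` off axis; the on-axis limit is
    ``1 / (r^2 - L^2/4)``.  Points on or inside the active line segment are a
    domain error.
    """
    r = np.asarray(r, dtype=float)
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    if length <= 0:
        raise ValueError("active length must be positive")
    sin_t = np.sin(theta)
    cos_t = np.cos(theta)
    x = r * sin_t
    z = r * cos_t
    on_axis = np.abs(sin_t) < 1e-12
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if np.any(on_axis & (r <= length / 2 + 1e-12)):
        raise ValueError("field point on the active line segment (r <= L/2 on axis)")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.arctan2(x, z - length / 2) - np.arctan2(x, z + length / 2)
        g_off = beta / (length * np.where(on_axis, np.nan, x))
    g_axis = 1.0 / (r * r - length * length / 4.0)
    out = np.where(on_axis, g_axis, g_off)
    return float(out) if out.ndim == 0 else out


def radial_dose_function(table: PolarDoseTable, length: float) -> dict[float, float]:
    """g_L(r) from the transverse (theta0) profile of a polar dose table.

    ``g_L(r) = [D(r,90)/G_L(r,90)] / [D(1,90)/G_L(1,90)]``; exactly 1 at r0.
    """
    _require_node(table.theta_deg, THETA0_DEG, "theta")
    _require_node(table.r_cm, R0_CM, "r")
    profile = table.transverse_profile()
    gl = geometry_function_line(table.r_cm, THETA0_DEG, length)
    corrected = profile / gl
    ref = corrected[np.argmin(np.abs(table.r_cm - R0_CM))]
    values = corrected / ref
    return dict(zip(table.r_cm.tolist(), values.tolist()))


def anisotropy_function(table: PolarDoseTable, length: float) -> dict[tuple[float, float], float]:
    """F(r, theta) relative to the transverse axis, geometry-function corrected.

    ``F(r,theta) = [D(r,theta)/G_L(r,theta)] / [D(r,90)/G_L(r,90)]``; exactly
    1 along theta = 90 for every r.
    """
    _require_node(table.theta_deg, THETA0_DEG, "theta")
    gl = geometry_function_line(
        table.r_cm[None, :], np.broadcast_to(table.theta_deg[:, None], (table.theta_deg.size, table.r_cm.size)), length
    )
    corrected = table.dose / gl
    it0 = int(np.argmin(np.abs(table.theta_deg - THETA0_DEG)))
    values = corrected / corrected[it0][None, :]
    return {
        (float(r), float(t)): float(values[i, j])
        for i, t in enumerate(table.theta_deg)
        for j, r in enumerate(table.r_cm)
    }


def air_kerma_strength(kerma_rate: float, distance_cm: float) -> float:
    """S_k = K_delta(d) * d^2 in U (uGy m^2/h) per the activity unit of the rate.

    With the rate in cGy/h and d in cm the product is numerically in U
    (1 cGy cm^2 = 1e4 uGy * 1e-4 m^2).
    """
    if not distance_cm > 0:
        raise ValueError("distance must be positive")
    return kerma_rate * distance_cm**2


def dose_rate_constant(dose_at_ref: float, s_k: float) -> float:
    """Lambda = D(1 cm, 90 deg) / S_k; any common activity normalisation cancels."""
    if not s_k > 0:
        raise ValueError("S_k must be positive")
    return dose_at_ref / s_k


def fit_radial_polynomial(g_table: dict[float, float], order: int = 5):
    """Ordinary least-squares polynomial fit g(r) = a0 + a1 r + ... + a5 r^5.

    Returns (coefficients a0..a5 ascending, R^2 vs the mean model)."""
    r = np.array(sorted(g_table))
    g = np.array([g_table[k] for k in r])
    if r.size < order + 2:
        raise ValueError(f"need at least {order + 2} points for an order-{order} fit")
    design = np.vander(r, order + 1, increasing=True)
    coeffs, residuals, rank, _ = np.linalg.lstsq(design, g, rcond=None)
    if rank < order + 1:
        raise ValueError("rank-deficient design matrix: degenerate radial grid")
    pred = design @ coeffs
    ss_res = float(np.sum((g - pred) ** 2))
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return coeffs, r2


@dataclass
class TG43ParameterSet:
    """Extracted TG-43 parameters of one source characterisation."""

    dose_rate_constant: float                  # cGy/h/U
    air_kerma_strength_per_activity: float     # U/mCi
    active_length: float                       # cm
    g_table: dict[float, float]
    f_table: dict[tuple[float, float], float]
    poly_coeffs: np.ndarray
    fit_r2: float
    reference_r: float = R0_CM
    reference_theta: float = THETA0_DEG
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.dose_rate_constant > 0:
            raise ValueError("Lambda must be positive")
        if not self.air_kerma_strength_per_activity > 0:
            raise ValueError("S_k must be positive")
        if abs(self.g_table[self.reference_r] - 1.0) > 1e-12:
            raise ValueError("g_L(r0) must equal 1 exactly")

    @property
    def r_values(self) -> np.ndarray:
        return np.array(sorted(self.g_table))

    @property
    def theta_values(self) -> np.ndarray:
        return np.unique([t for (_, t) in self.f_table])

    def to_json(self, path) -> None:
        doc = {
            "dose_rate_constant_cGy_per_h_per_U": self.dose_rate_constant,
            "air_kerma_strength_U_per_mCi": self.air_kerma_strength_per_activity,
            "active_length_cm": self.active_length,
            "reference_point": {"r_cm": self.reference_r, "theta_deg": self.reference_theta},
            "radial_dose_function": {str(k): v for k, v in self.g_table.items()},
            "anisotropy_function": [
                {"r_cm": r, "theta_deg": t, "F": v} for (r, t), v in self.f_table.items()
            ],
            "poly_coeffs_a0_a5": list(map(float, self.poly_coeffs)),
            "fit_R2": self.fit_r2,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TG43ParameterSet":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            dose_rate_constant=doc["dose_rate_constant_cGy_per_h_per_U"],
            air_kerma_strength_per_activity=doc["air_kerma_strength_U_per_mCi"],
            active_length=doc["active_length_cm"],
            g_table={float(k): v for k, v in doc["radial_dose_function"].items()},
            f_table={
                (row["r_cm"], row["theta_deg"]): row["F"]
                for row in doc["anisotropy_function"]
            },
            poly_coeffs=np.array(doc["poly_coeffs_a0_a5"]),
            fit_r2=doc["fit_R2"],
            reference_r=doc["reference_point"]["r_cm"],
            reference_theta=doc["reference_point"]["theta_deg"],
            provenance=doc.get("provenance", {}),
        )


def extract_parameters(
    table: PolarDoseTable,
    length: float,
    s_k_per_mci: float,
    provenance: dict | None = None,
) -> TG43ParameterSet:
    """Full TG-43 extraction from a polar dose-rate table plus the air-kerma
    strength per contained activity (same normalisation as the table)."""
    g = radial_dose_function(table, length)
    f = anisotropy_function(table, length)
    coeffs, r2 = fit_radial_polynomial(g)
    lam = dose_rate_constant(table.cell(R0_CM, THETA0_DEG), s_k_per_mci)
    return TG43ParameterSet(
        dose_rate_constant=lam,
        air_kerma_strength_per_activity=s_k_per_mci,
        active_length=length,
        g_table=g,
        f_table=f,
        poly_coeffs=coeffs,
        fit_r2=r2,
        provenance=provenance or {},
    )


def _require_node(nodes: np.ndarray, value: float, name: str) -> None:
    if not np.any(np.abs(nodes - value) < 1e-9):
        raise KeyError(f"dose table lacks the reference {name} = {value} node")


def _interp_g(params: TG43ParameterSet, r) -> np.ndarray:
    """Log-linear interpolation of g_L in r (the treatment-planning convention)."""
    rv = params.r_values
    gv = np.array([params.g_table[k] for k in rv])
    r = np.asarray(r, dtype=float)
    if np.any(r < rv[0] - 1e-9) or np.any(r > rv[-1] + 1e-9):
        raise ValueError(f"r outside tabulated range [{rv[0]}, {rv[-1]}] cm")
    return np.exp(np.interp(r, rv, np.log(gv)))


def _interp_f(params: TG43ParameterSet, r, theta_deg) -> np.ndarray:
    """Bilinear interpolation of F in (r, theta)."""
    rv = params.r_values
    tv = params.theta_values
    fgrid = np.array([[params.f_table[(rr, tt)] for rr in rv] for tt in tv])
    r = np.atleast_1d(np.asarray(r, dtype=float))
    t = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    if np.any(t < tv[0] - 1e-9) or np.any(t > tv[-1] + 1e-9):
        raise ValueError(f"theta outside tabulated range [{tv[0]}, {tv[-1]}] deg")
    ir = np.clip(np.searchsorted(rv, r) - 1, 0, rv.size - 2)
    it = np.clip(np.searchsorted(tv, t) - 1, 0, tv.size - 2)
    fr = np.clip((r - rv[ir]) / (rv[ir + 1] - rv[ir]), 0, 1)
    ft = np.clip((t - tv[it]) / (tv[it + 1] - tv[it]), 0, 1)
    val = (
        fgrid[it, ir] * (1 - fr) * (1 - ft)
        + fgrid[it, ir + 1] * fr * (1 - ft)
        + fgrid[it + 1, ir] * (1 - fr) * ft
        + fgrid[it + 1, ir + 1] * fr * ft
    )
    return val


def reconstruct_dose(params: TG43ParameterSet, r, theta_deg, s_k: float):
    """Evaluate the TG-43 dose-rate model at (r, theta) for a source of
    strength ``s_k`` (U); returns cGy/h.

    g_L is interpolated log-linearly in r and F bilinearly in (r, theta);
    evaluation outside the tabulated range raises ``ValueError``.
    """
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    t_arr = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    r_b, t_b = np.broadcast_arrays(r_arr, t_arr)
    gl = geometry_function_line(r_b, t_b, params.active_length)
    gl0 = geometry_function_line(params.reference_r, params.reference_theta, params.active_length)
    out = (
        s_k
        * params.dose_rate_constant
        * (gl / gl0)
        * _interp_g(params, r_b)
        * _interp_f(params, r_b, t_b)
    )
    return float(out.ravel()[0]) if np.ndim(r) == 0 and np.ndim(theta_deg) == 0 else out


def dose_plane(
    params: TG43ParameterSet,
    s_k: float,
    half_extent: float = 10.0,
    n: int = 201,
):
    """TG-43 dose-rate map over the y-z plane through the source axis.

    Radii outside the tabulated range are clamped to the nearest tabulated
    boundary (a plotting convenience; point evaluation still range-checks).
    Returns (y, z, dose) with dose shaped (n, n) indexed [z, y].
    """
    y = np.linspace(-half_extent, half_extent, n)
    z = np.linspace(-half_extent, half_extent, n)
    yy, zz = np.meshgrid(y, z)
    r = np.hypot(yy, zz)
    rv = params.r_values
    r_cl = np.clip(r, rv[0], rv[-1])
    theta = np.degrees(np.arctan2(np.abs(yy), zz))
    dose = reconstruct_dose(params, r_cl, theta, s_k)
    return y, z, dose


def isodose_contours(dose_map: np.ndarray, levels, x=None, y=None):
    """Extract isodose polylines from a 2D dose map.

    ``dose_map`` is indexed [row, col] over coordinates ``(y[row], x[col])``
    (defaults to pixel indices).  Returns ``{level: [poly, ...]}`` where each
    poly is an (n, 2) array of (x, y) points.
    """
    from skimage import measure

    dose_map = np.asarray(dose_map, dtype=float)
    if not np.all(np.isfinite(dose_map)):
        raise ValueError("dose map must be finite")
    x = np.arange(dose_map.shape[1]) if x is None else np.asarray(x)
    y = np.arange(dose_map.shape[0]) if y is None else np.asarray(y)
    out = {}
    for level in levels:
        polys = []
        for contour in measure.find_contours(dose_map, level):
            cx = np.interp(contour[:, 1], np.arange(x.size), x)
            cy = np.interp(contour[:, 0], np.arange(y.size), y)
            polys.append(np.column_stack([cx, cy]))
        out[float(level)] = polys
    return out
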