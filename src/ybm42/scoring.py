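"""Ring-detector geometry, polar dose tables, and clinical unit conversion.

The detector is a set of disjoint bins formed by intersecting concentric
spherical shells with coaxial polar cones centred on the source: the
canonical grid has 0.5 cm-thick shells centred on r = 0.5, 1, 2, ..., 10 cm
and 4 deg-wide cones centred on theta = 0, 10, ..., 180 deg (the axial rows
are full cones spanning 0-3 deg and 177-180 deg).  theta is measured from
the seed tip; the delivery cable sits at theta = 180 deg.

The analytic volume of a shell-cone intersection is
``V = (2 pi / 3) (r2^3 - r1^3) (cos t1 - cos t2)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RingDetectorGrid",
    "PolarDoseTable",
    "UnitConstants",
    "UNITS",
    "bin_index",
    "per_history_to_clinical",
    "average_symmetric_bins",
]


@dataclass(frozen=True)
class UnitConstants:
    """Conversion chain from per-history energy scores to cGy/h per mCi."""

    mci_to_bq: float = 3.7e7            # decays per second per mCi (exact)
    kev_to_joule: float = 1.602176634e-16
    gram_to_kg: float = 1e-3
    gy_to_cgy: float = 100.0
    s_per_h: float = 3600.0

    @property
    def kev_per_gram_to_cgy(self) -> float:
        # keV/g -> Gy (J/kg) -> cGy
        return self.kev_to_joule / self.gram_to_kg * self.gy_to_cgy


UNITS = UnitConstants()


def per_history_to_clinical(
    energy_per_history_kev: float,
    bin_mass_g: float,
    photon_yield: float,
    constants: UnitConstants = UNITS,
) -> float:
    """Convert a per-history energy score (keV) in a bin of mass ``bin_mass_g``
    to cGy/h per contained mCi, given ``photon_yield`` photons per decay
    (one history = one primary photon)."""
    if not bin_mass_g > 0:
        raise ValueError("bin mass must be positive")
    dose_cgy_per_history = energy_per_history_kev / bin_mass_g * constants.kev_per_gram_to_cgy
    histories_per_h_per_mci = constants.mci_to_bq * photon_yield * constants.s_per_h
    return dose_cgy_per_history * histories_per_h_per_mci


@dataclass(frozen=True)
class RingDetectorGrid:
    """Spherical-shell x polar-cone scoring bins.

    ``r_lo/r_hi`` (cm) and ``theta_lo/theta_hi`` (deg) are the bin boundaries;
    bins are disjoint (shells and cones may leave unscored gaps between them,
    as in the published detector layout).
    """

    radial_nodes: np.ndarray
    r_lo: np.ndarray
    r_hi: np.ndarray
    polar_nodes: np.ndarray
    theta_lo: np.ndarray
    theta_hi: np.ndarray
    medium_density: float = 0.998  # g/cm3 of the scoring medium (water)

    def __post_init__(self):
        for name in ("radial_nodes", "r_lo", "r_hi", "polar_nodes", "theta_lo", "theta_hi"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.r_lo >= self.r_hi) or np.any(self.theta_lo >= self.theta_hi):
            raise ValueError("bin boundaries must satisfy lo < hi")
        if np.any(np.diff(self.r_lo) <= 0) or np.any(self.r_hi[:-1] > self.r_lo[1:] + 1e-12):
            raise ValueError("radial shells must be ascending and disjoint")
        if np.any(self.theta_hi[:-1] > self.theta_lo[1:] + 1e-12):
            raise ValueError("polar cones must be ascending and disjoint")

    @classmethod
    def default(cls, medium_density: float = 0.998) -> "RingDetectorGrid":
        r_nodes = np.array([0.5] + list(range(1, 11)), dtype=float)
        polar = np.arange(0.0, 181.0, 10.0)
        th_lo = np.clip(polar - 2.0, 0.0, 180.0)
        th_hi = np.clip(polar + 2.0, 0.0, 180.0)
        th_hi[0] = 3.0       # axial caps are full cones
        th_lo[-1] = 177.0
        return cls(
            radial_nodes=r_nodes,
            r_lo=r_nodes - 0.25,
            r_hi=r_nodes + 0.25,
            polar_nodes=polar,
            theta_lo=th_lo,
            theta_hi=th_hi,
            medium_density=medium_density,
        )

    @property
    def n_radial(self) -> int:
        return self.radial_nodes.size

    @property
    def n_polar(self) -> int:
        return self.polar_nodes.size

    def volumes(self) -> np.ndarray:
        """Analytic bin volumes, shape (n_polar, n_radial), cm^3."""
        shell = self.r_hi**3 - self.r_lo**3
        cone = np.cos(np.radians(self.theta_lo)) - np.cos(np.radians(self.theta_hi))
        return (2.0 * np.pi / 3.0) * cone[:, None] * shell[None, :]

    def masses(self) -> np.ndarray:
        return self.volumes() * self.medium_density

    def radial_edges(self) -> np.ndarray:
        return np.column_stack([self.r_lo, self.r_hi]).ravel()

    def polar_edges(self) -> np.ndarray:
        return np.column_stack([self.theta_lo, self.theta_hi]).ravel()


def bin_index(position, grid: RingDetectorGrid):
    """Map point(s) to (radial index, polar index); -1 where the point falls
    in an unscored gap or outside the grid.

    ``position`` is a length-3 vector or an (n, 3) array of cm coordinates;
    theta is measured from the +z axis (source tip), cable side = 180 deg.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    r = np.sqrt((pos**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        theta = np.degrees(np.arccos(np.clip(pos[:, 2] / np.where(r > 0, r, np.inf), -1, 1)))
    ir = _edge_lookup(r, grid.radial_edges())
    it = _edge_lookup(theta, grid.polar_edges(), closed_top=True)
    ir = np.where(it < 0, -1, ir)
    it = np.where(ir < 0, -1, it)
    if np.ndim(position) == 1:
        return int(ir[0]), int(it[0])
    return ir, it


def _edge_lookup(x, edges, closed_top: bool = False):
    """Index of the [lo, hi) interval containing x among paired edges, else -1."""
    k = np.searchsorted(edges, x, side="right")
    idx = np.where(k % 2 == 1, (k - 1) // 2, -1)
    if closed_top:  # include the very top boundary (theta = 180)
        idx = np.where(x == edges[-1], edges.size // 2 - 1, idx)
    return idx


@dataclass
class PolarDoseTable:
    """Polar dose-rate grid D(r, theta) in cGy/h/mCi with per-cell relative
    statistical uncertainty (NaN where undefined)."""

    r_cm: np.ndarray                      # radial nodes, ascending
    theta_deg: np.ndarray                 # polar nodes, ascending
    dose: np.ndarray                      # (n_theta, n_radial)
    rel_err: np.ndarray | None = None     # same shape, relative (1 sigma)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r_cm = np.asarray(self.r_cm, dtype=float)
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != (self.theta_deg.size, self.r_cm.size):
            raise ValueError("dose grid shape must be (n_theta, n_radial)")
        if self.rel_err is not None:
            self.rel_err = np.asarray(self.rel_err, dtype=float)
            if self.rel_err.shape != self.dose.shape:
                raise ValueError("rel_err shape must match dose")

    def cell(self, r: float, theta: float) -> float:
        ir = int(np.argmin(np.abs(self.r_cm - r)))
        it = int(np.argmin(np.abs(self.theta_deg - theta)))
        if abs(self.r_cm[ir] - r) > 1e-9 or abs(self.theta_deg[it] - theta) > 1e-9:
            raise KeyError(f"no grid node at (r={r}, theta={theta})")
        return float(self.dose[it, ir])

    def transverse_profile(self) -> np.ndarray:
        """Dose along theta = 90 deg, one value per radial node."""
        it = int(np.argmin(np.abs(self.theta_deg - 90.0)))
        return self.dose[it, :].copy()

    def to_frame(self) -> pd.DataFrame:
        rr, tt = np.meshgrid(self.r_cm, self.theta_deg)
        err = self.rel_err if self.rel_err is not None else np.full_like(self.dose, np.nan)
        return pd.DataFrame(
            {
                "r_cm": rr.ravel(),
                "theta_deg": tt.ravel(),
                "dose_rate_cGy_per_h_per_mCi": self.dose.ravel(),
                "rel_err": err.ravel(),
            }
        )

    def write_csv(self, path) -> None:
        buf = io.StringIO()
        for key, val in self.meta.items():
            buf.write(f"# {key}: {val}\n")
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def read_csv(cls, path) -> "PolarDoseTable":
        meta = {}
        with open(path) as fh:
            text = fh.readlines()
        body = []
        for line in text:
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
            else:
                body.append(line)
        frame = pd.read_csv(io.StringIO("".join(body)))
        return cls.from_frame(frame, meta=meta)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: dict | None = None) -> "PolarDoseTable":
        r = np.unique(frame["r_cm"].to_numpy())
        t = np.unique(frame["theta_deg"].to_numpy())
        dose = np.full((t.size, r.size), np.nan)
        err = np.full((t.size, r.size), np.nan)
        ir = np.searchsorted(r, frame["r_cm"].to_numpy())
        it = np.searchsorted(t, frame["theta_deg"].to_numpy())
        dose[it, ir] = frame["dose_rate_cGy_per_h_per_mCi"].to_numpy()
        if "rel_err" in frame:
            err[it, ir] = frame["rel_err"].to_numpy()
        return cls(r, t, dose, err, meta=meta or {})


def average_symmetric_bins(frame: pd.DataFrame) -> PolarDoseTable:
    """Merge duplicate (r, theta) rows by uncertainty-weighted mean.

    Rows mapping to the same polar cell (e.g. produced by re-binning a
    cylindrical mesh whose cells straddle common virtual surfaces) are
    combined with inverse-variance weights computed from absolute errors;
    cells with missing or zero uncertainties fall back to the plain mean.
    No theta-mirror averaging is performed: the cable makes the source
    asymmetric about the transverse plane.
    """
    if isinstance(frame, PolarDoseTable):
        frame = frame.to_frame()
    out = []
    for (r, t), grp in frame.groupby(["r_cm", "theta_deg"], sort=True):
        d = grp["dose_rate_cGy_per_h_per_mCi"].to_numpy()
        rel = grp["rel_err"].to_numpy() if "rel_err" in grp else np.full(d.shape, np.nan)
        sig = np.abs(d) * rel
        if np.all(np.isfinite(sig)) and np.all(sig > 0):
            w = 1.0 / sig**2
            mean = float((w * d).sum() / w.sum())
            err = float(np.sqrt(1.0 / w.sum()) / abs(mean)) if mean != 0 else np.nan
        else:
            mean = float(d.mean())
            err = float(np.nanmean(rel) / np.sqrt(d.size))
        out.append((r, t, mean, err))
    merged = pd.DataFrame(
        out, columns=["r_cm", "theta_deg", "dose_rate_cGy_per_h_per_mCi", "rel_err"]
    )
    return PolarDoseTable.from_frame(merged)
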