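"""Seed geometry, materials and emission spectrum of the 169Yb Model M42 HDR source.

The M42 source is a thin Yb2O3 ceramic cylinder (the *active core*, length
``L`` = 0.6 cm) encapsulated by two coaxial cylinders — an inner titanium
capsule and an outer 304 stainless-steel capsule — with a short stainless
delivery-cable stub attached on one end.  The cable end defines the polar
angle theta = 180 deg; the seed tip is theta = 0 deg.  The assembly is
rotationally symmetric about the long (z) axis but *not* mirror-symmetric
about the transverse plane, which is why the polar dose grid spans the full
0–180 deg range.

Only the active length is a published dimension; the remaining dimensions are
nominal engineering defaults at the scale typical of HDR seeds and every one
of them can be overridden through the configuration mapping accepted by
:func:`build_default_m42`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "MaterialSpec",
    "EmissionSpectrum",
    "CylinderRegion",
    "SourceModel",
    "ConfigError",
    "WATER",
    "AIR",
    "TITANIUM",
    "SS304",
    "YB2O3",
    "build_default_m42",
    "load_default_spectrum",
    "sample_decay",
    "spectrum_mean_energy",
]


class ConfigError(ValueError):
    """A source/simulation configuration entry is invalid; the message names the key."""


@dataclass(frozen=True)
class MaterialSpec:
    """A homogeneous material: density (g/cm3) and elemental mass fractions."""

    name: str
    density: float
    composition: dict[str, float]

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ConfigError(f"material {self.name!r}: density must be > 0, got {self.density}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(
                f"material {self.name!r}: mass fractions sum to {total!r}, expected 1 within 1e-6"
            )
        if any(f <= 0 for f in self.composition.values()):
            raise ConfigError(f"material {self.name!r}: mass fractions must be positive")


WATER = MaterialSpec("water", 0.998, {"H": 0.111898, "O": 0.888102})
#: Dry air near sea level (mass fractions per the standard dosimetry composition).
AIR = MaterialSpec(
    "air", 1.196e-3, {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012828}
)
TITANIUM = MaterialSpec("titanium", 4.51, {"Ti": 1.0})
#: 304 stainless steel with the published M42 composition.
SS304 = MaterialSpec(
    "ss304",
    7.80,
    {
        "Cr": 0.16,
        "Ni": 0.10,
        "S": 0.0003,
        "Si": 0.0075,
        "C": 0.0008,
        "Mn": 0.02,
        "P": 0.00045,
        "Fe": 0.69095,
        "Mo": 0.02,
    },
)
YB2O3 = MaterialSpec("yb2o3", 7.1, {"Yb": 0.878208, "O": 0.121792})

_BUILTIN_MATERIALS = {
    m.name: m for m in (WATER, AIR, TITANIUM, SS304, YB2O3)
}


@dataclass(frozen=True)
class EmissionSpectrum:
    """Discrete photon line spectrum: (energy keV, photons per decay) pairs.

    ``total_yield`` is the number of photons emitted per disintegration and is
    the normalisation used when converting per-history Monte Carlo scores to
    per-mCi dose rates.
    """

    energies: np.ndarray       # keV, strictly ascending
    intensities: np.ndarray    # photons per decay

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "intensities", i)
        if e.size == 0:
            raise ConfigError("spectrum: no emission lines")
        if e.size != i.size:
            raise ConfigError("spectrum: energies and intensities differ in length")
        if not np.all(e > 0):
            raise ConfigError("spectrum: energies must be strictly positive")
        if not np.all(np.diff(e) > 0):
            raise ConfigError("spectrum: energies must be strictly ascending")
        if not np.all(i > 0):
            raise ConfigError("spectrum: intensities must be positive")

    @property
    def total_yield(self) -> float:
        return float(self.intensities.sum())

    @property
    def mean_energy(self) -> float:
        return float(np.average(self.energies, weights=self.intensities))

    def cdf(self) -> np.ndarray:
        c = np.cumsum(self.intensities)
        return c / c[-1]

    @classmethod
    def from_file(cls, path) -> "EmissionSpectrum":
        """Read a two-column text spectrum (energy_keV, photons_per_decay, '#' comments)."""
        data = np.loadtxt(path, comments="#", ndmin=2)
        order = np.argsort(data[:, 0])
        return cls(data[order, 0], data[order, 1])


def load_default_spectrum() -> EmissionSpectrum:
    """The packaged 169Yb line spectrum (gamma lines plus Tm K X-rays)."""
    ref = resources.files("ybm42").joinpath("data/yb169_spectrum.txt")
    with resources.as_file(ref) as path:
        return EmissionSpectrum.from_file(path)


@dataclass(frozen=True)
class CylinderRegion:
    """A finite solid cylinder coaxial with the z axis.

    Regions are listed innermost-first; a point belongs to the first region
    that geometrically contains it, so an outer cylinder region represents the
    shell left after subtracting every earlier region.
    """

    name: str
    radius: float
    zmin: float
    zmax: float
    material: MaterialSpec

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ConfigError(f"region {self.name!r}: radius must be > 0")
        if not self.zmax > self.zmin:
            raise ConfigError(f"region {self.name!r}: zmax must exceed zmin")

    def contains(self, point) -> bool:
        x, y, z = point
        return (self.zmin <= z <= self.zmax) and (x * x + y * y) <= self.radius**2

    def inside(self, other: "CylinderRegion") -> bool:
        return (
            self.radius <= other.radius
            and self.zmin >= other.zmin
            and self.zmax <= other.zmax
        )

    def disjoint(self, other: "CylinderRegion") -> bool:
        return self.zmax <= other.zmin or self.zmin >= other.zmax


@dataclass(frozen=True)
class SourceModel:
    """The encapsulated seed: ordered coaxial regions plus the emission spectrum."""

    regions: tuple[CylinderRegion, ...]
    active_length: float
    spectrum: EmissionSpectrum
    core_name: str = "core"

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if self.core_name not in names:
            raise ConfigError(f"source model: no region named {self.core_name!r}")
        core = self.core
        if abs((core.zmax - core.zmin) - self.active_length) > 1e-9:
            raise ConfigError("source model: active_length must equal the core z extent")
        # every pair of regions must be either nested (later contains earlier) or disjoint
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1 :]:
                if not (a.inside(b) or a.disjoint(b)):
                    raise ConfigError(
                        f"source model: regions {a.name!r} and {b.name!r} overlap without nesting"
                    )
        capsules = [r for r in self.regions if r.name in ("inner_capsule", "outer_capsule")]
        for cap in capsules:
            if not core.inside(cap):
                raise ConfigError(f"source model: active core not inside {cap.name!r}")

    @property
    def core(self) -> CylinderRegion:
        return next(r for r in self.regions if r.name == self.core_name)

    def region_at(self, point) -> CylinderRegion | None:
        """The unique region containing ``point`` (innermost-first priority), or None."""
        for region in self.regions:
            if region.contains(point):
                return region
        return None

    @property
    def bounding_radius(self) -> float:
        return max(
            math.hypot(r.radius, max(abs(r.zmin), abs(r.zmax))) for r in self.regions
        )


_DEFAULT_DIMENSIONS = {
    "core": {"radius": 0.020, "zmin": -0.30, "zmax": 0.30, "material": "yb2o3"},
    "inner_capsule": {"radius": 0.028, "zmin": -0.34, "zmax": 0.34, "material": "titanium"},
    "outer_capsule": {"radius": 0.040, "zmin": -0.40, "zmax": 0.40, "material": "ss304"},
    # cable stub on the theta=180 (negative z) side
    "cable": {"radius": 0.035, "zmin": -0.60, "zmax": -0.40, "material": "ss304"},
}


def build_default_m42(config: dict | None = None) -> SourceModel:
    """Construct the default Model M42 seed, optionally overriding any dimension.

    ``config`` may contain a ``regions`` mapping (region name -> dict with any
    of radius/zmin/zmax/material/density), a ``spectrum_file`` path, and
    ``drop_regions`` (list of region names to omit, e.g. the cable).  Unknown
    keys raise :class:`ConfigError` naming the offending key.
    """
    config = dict(config or {})
    region_over = config.pop("regions", {})
    spectrum_file = config.pop("spectrum_file", None)
    drop = set(config.pop("drop_regions", ()))
    if config:
        raise ConfigError(f"unknown source config key(s): {sorted(config)}")

    unknown = set(region_over) - set(_DEFAULT_DIMENSIONS)
    if unknown:
        raise ConfigError(f"unknown region name(s) in config: {sorted(unknown)}")

    regions = []
    for name, defaults in _DEFAULT_DIMENSIONS.items():
        if name in drop:
            continue
        spec = {**defaults, **region_over.get(name, {})}
        extra = set(spec) - {"radius", "zmin", "zmax", "material", "density"}
        if extra:
            raise ConfigError(f"region {name!r}: unknown key(s) {sorted(extra)}")
        material = spec["material"]
        if isinstance(material, str):
            try:
                material = _BUILTIN_MATERIALS[material]
            except KeyError:
                raise ConfigError(f"region {name!r}: unknown material {material!r}") from None
        if "density" in spec:
            material = MaterialSpec(material.name, spec["density"], material.composition)
        regions.append(
            CylinderRegion(name, spec["radius"], spec["zmin"], spec["zmax"], material)
        )

    spectrum = (
        EmissionSpectrum.from_file(spectrum_file)
        if spectrum_file is not None
        else load_default_spectrum()
    )
    core = next(r for r in regions if r.name == "core")
    return SourceModel(tuple(regions), core.zmax - core.zmin, spectrum)


def spectrum_mean_energy(spectrum: EmissionSpectrum) -> float:
    """Intensity-weighted mean line energy in keV."""
    return spectrum.mean_energy


def sample_decay(model: SourceModel, rng: np.random.Generator, size: int | None = None):
    """Sample primary photons: position uniform over the active core, isotropic
    direction, line energy with probability proportional to intensity.

    Returns ``(position, direction, energy)``; with ``size=None`` a single
    (3,), (3,), float triple, otherwise arrays of shape (size, 3) and (size,).
    """
    n = 1 if size is None else int(size)
    core = model.core
    # uniform over the cylinder volume
    rho = core.radius * np.sqrt(rng.random(n))
    phi = 2 * np.pi * rng.random(n)
    z = core.zmin + (core.zmax - core.zmin) * rng.random(n)
    pos = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    # isotropic direction
    mu = 2 * rng.random(n) - 1
    psi = 2 * np.pi * rng.random(n)
    s = np.sqrt(1 - mu * mu)
    direction = np.column_stack([s * np.cos(psi), s * np.sin(psi), mu])
    # line energies
    idx = np.searchsorted(model.spectrum.cdf(), rng.random(n), side="right")
    energy = model.spectrum.energies[np.minimum(idx, model.spectrum.energies.size - 1)]
    if size is None:
        return pos[0], direction[0], float(energy[0])
    return pos, direction, energy
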