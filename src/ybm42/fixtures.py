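"""Packaged benchmark fixtures: the published polar dose-rate table, radial
dose function, anisotropy function and scalar constants of the 169Yb Model
M42 characterisation.

Files store values exactly as printed (so tests can distinguish printed
rounding from code changes); loaders verify a SHA-256 checksum and parse
onto the canonical polar grid.
"""

from __future__ import annotations

import hashlib
import io
import json
from importlib import resources

import numpy as np
import pandas as pd

from .scoring import PolarDoseTable

__all__ = ["load_fixture", "FixtureError"]

_CHECKSUMS = {
    "table1.csv": "be1212f198a339fdffe0515c8f67878efc43254ff2a47797bf97ff9b9def5086",
    "table2.csv": "2f3c319b60fa49b35ab8cdb4618eca7c477f839a618da1e7a9fb5c948f7a7f4a",
    "table3.csv": "490fc97cbd4e0debf92318fd9d022b36016ba7f8a0bb4fe208f9aad936c1121f",
    "constants.json": "5e5245721f6cf17de2cd2ee0059e3cde47d548143ff33fb6b1773799cfe2dcf3",
    "yb169_spectrum.txt": "36a7ed24df95189b738a128091e7faa8df284d87345068e7b686d82967d240fa",
}


class FixtureError(RuntimeError):
    """Unknown fixture name or corrupted packaged data."""


def _read(filename: str) -> bytes:
    ref = resources.files("ybm42").joinpath(f"data/{filename}")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise FixtureError(f"checksum mismatch for packaged fixture {filename!r}")
    return raw


def _read_matrix(filename: str) -> PolarDoseTable:
    raw = _read(filename).decode()
    frame = pd.read_csv(io.StringIO(raw), comment="#")
    theta = frame["theta_deg"].to_numpy(dtype=float)
    r = np.array([float(c) for c in frame.columns[1:]])
    dose = frame.iloc[:, 1:].to_numpy(dtype=float)
    return PolarDoseTable(r, theta, dose, None, meta={"fixture": filename})


def load_fixture(name: str):
    """Load a packaged fixture by name.

    Names: ``table1`` (polar dose-rate grid, cGy/h/mCi), ``table2``
    (DataFrame: r, g_fluka, g_mcnp5, difference_pct), ``table3`` (anisotropy
    grid as a :class:`PolarDoseTable`-shaped container), ``constants``
    (dict of published scalars).
    """
    if name == "table1":
        return _read_matrix("table1.csv")
    if name == "table3":
        return _read_matrix("table3.csv")
    if name == "table2":
        raw = _read("table2.csv").decode()
        return pd.read_csv(io.StringIO(raw), comment="#")
    if name == "constants":
        return json.loads(_read("constants.json").decode())
    raise FixtureError(f"unknown fixture {name!r}")
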