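"""Tabulated linear attenuation coefficients.

Each material ships with a linear attenuation table mu(E) on a 1-150 keV,
1-keV grid (derived from NIST-XCOM mass attenuation anchors at standard
density).  Evaluation at arbitrary energies uses linear interpolation of
log(mu) versus log(E), which is near-exact between absorption edges where
attenuation follows an approximate power law.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialTable",
    "BasisPair",
    "get_material",
    "list_materials",
    "linear_attenuation",
]

# canonical names plus common aliases
_ALIASES = {
    "al": "aluminum",
    "ti": "titanium",
    "cu": "copper",
    "soft tissue": "soft_tissue",
    "tissue": "soft_tissue",
    "bone_cortical": "bone",
}


@dataclass(frozen=True)
class MaterialTable:
    """Linear attenuation mu(E) of one material.

    Attributes
    ----------
    name : str
        Material label, e.g. ``"pmma"``.
    energies : ndarray
        Strictly increasing energy grid in keV.
    mu : ndarray
        Linear attenuation coefficient at each grid energy, 1/cm.
    density : float
        Mass density in g/cm^3.
    """

    name: str
    energies: np.ndarray = field(repr=False)
    mu: np.ndarray = field(repr=False)
    density: float

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        m = np.asarray(self.mu, dtype=float)
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energies must be a strictly increasing 1-D grid")
        if m.shape != e.shape:
            raise ValueError("mu and energies must have matching shapes")
        if np.any(m <= 0):
            raise ValueError("mu must be positive at every tabulated energy")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu", m)

    def __call__(self, energy) -> np.ndarray | float:
        """Evaluate mu (1/cm) at ``energy`` keV (scalar or array)."""
        return linear_attenuation(self, energy)


@dataclass(frozen=True)
class BasisPair:
    """An ordered pair of basis materials for two-material decomposition."""

    m1: MaterialTable
    m2: MaterialTable

    def __post_init__(self) -> None:
        if self.m1.name == self.m2.name:
            raise ValueError("basis materials must differ")
        # Proportional mu curves make the decomposition singular.
        ratio = self.m1.mu / np.interp(
            self.m1.energies, self.m2.energies, self.m2.mu
        )
        if np.ptp(ratio) / np.mean(ratio) < 1e-6:
            raise ValueError("basis attenuation curves are proportional")


_DATA_DIR = pathlib.Path(__file__).parent / "data"


def _load_table(name: str) -> MaterialTable:
    ref = _DATA_DIR / f"{name}.csv"
    density = None
    energies, mu = [], []
    with ref.open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "density_g_cm3" in line:
                    density = float(line.split(":")[1])
                continue
            if not line or line.startswith("energy"):
                continue
            e, m = line.split(",")
            energies.append(float(e))
            mu.append(float(m))
    return MaterialTable(name, np.array(energies), np.array(mu), density)


_CACHE: dict[str, MaterialTable] = {}


def list_materials() -> list[str]:
    """Names of all packaged materials."""
    return sorted(p.stem for p in _DATA_DIR.glob("*.csv"))


def get_material(name: str) -> MaterialTable:
    """Look up a packaged material table by name (aliases accepted)."""
    key = _ALIASES.get(name.lower(), name.lower())
    if key not in _CACHE:
        if key not in list_materials():
            raise KeyError(
                f"unknown material {name!r}; available: {list_materials()}"
            )
        _CACHE[key] = _load_table(key)
    return _CACHE[key]


def linear_attenuation(material: MaterialTable, energy) -> np.ndarray | float:
    """Linear attenuation (1/cm) at ``energy`` keV by log-log interpolation.

    Raises ``ValueError`` when any requested energy lies outside the table.
    """
    e = np.asarray(energy, dtype=float)
    lo, hi = material.energies[0], material.energies[-1]
    if np.any(e < lo) or np.any(e > hi):
        raise ValueError(
            f"energy outside table range [{lo}, {hi}] keV for "
            f"{material.name}"
        )
    out = np.exp(
        np.interp(np.log(e), np.log(material.energies), np.log(material.mu))
    )
    return float(out) if np.isscalar(energy) else out
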