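"""Polychromatic tube spectra and the ideal two-bin photon-counting detector.

The tube model is a Kramers bremsstrahlung continuum plus tungsten K
characteristic lines, hardened by 1.6 mm of inherent aluminum filtration.
It is a parameterized stand-in with the qualitative shape of a TASMIP
140-kV tungsten spectrum; an externally computed spectrum can be imported
from CSV when exact fidelity is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import MaterialTable, get_material

__all__ = [
    "Spectrum",
    "DetectorModel",
    "generate_spectrum",
    "apply_filtration",
    "bin_weights",
    "monoenergetic",
    "load_spectrum_csv",
    "save_spectrum_csv",
]

# Tungsten K lines present above the K edge (69.5 keV): energy keV and
# relative strength (K-alpha1 dominant; alpha2 folded into 59.3).
_W_LINES = ((59.3, 1.0), (67.2, 0.35), (69.1, 0.15))
_LINE_FRACTION = 0.10  # fraction of unfiltered continuum fluence in lines
_INHERENT_AL_MM = 1.6


@dataclass(frozen=True)
class Spectrum:
    """Relative photon fluence per energy bin.

    ``fluence[i]`` is the relative number of photons at ``energies[i]``
    (dimensionless weights; absolute intensity enters through the blank
    count N0).
    """

    energies: np.ndarray = field(repr=False)
    fluence: np.ndarray = field(repr=False)
    kvp: float

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        if np.any(f < 0):
            raise ValueError("fluence must be non-negative")
        if np.any(f[e > self.kvp] > 0):
            raise ValueError("fluence must vanish above the tube potential")
        if f.sum() <= 0:
            raise ValueError("spectrum carries no photons")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", f)

    @property
    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy, keV."""
        return float(np.average(self.energies, weights=self.fluence))

    def normalized(self) -> "Spectrum":
        return Spectrum(self.energies, self.fluence / self.fluence.sum(),
                        self.kvp)


@dataclass(frozen=True)
class DetectorModel:
    """Ideal photon-counting detector with two comparator thresholds.

    Bin 1 collects energies in [low, high), bin 2 in [high, kvp]; the
    response inside a bin is a perfect indicator (unit efficiency, perfect
    energy resolution).
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("thresholds must satisfy low < high")

    @property
    def n_bins(self) -> int:
        return 2

    def bin_labels(self, kvp: float) -> list[str]:
        """Whole-keV quoting convention: thresholds (30, 80) at 140 kVp are
        quoted as [31 80] and [81 140]."""
        return [
            f"[{int(self.low) + 1} {int(self.high)}]",
            f"[{int(self.high) + 1} {int(kvp)}]",
        ]


def generate_spectrum(kvp: float, grid_step: float = 1.0) -> Spectrum:
    """Bremsstrahlung + tungsten K-line tube spectrum at ``kvp`` kV.

    The continuum follows Kramers' law (fluence proportional to
    (kvp - E)/E), characteristic lines at 59.3/67.2/69.1 keV appear when
    the potential exceeds the tungsten K edge, and 1.6 mm of inherent Al
    filtration is applied.  The result is normalized to unit total fluence
    on a 1-150 keV grid with the requested step.
    """
    if not 40.0 <= kvp <= 150.0:
        raise ValueError("kvp must lie in [40, 150] kV")
    energies = np.arange(1.0, 150.0 + 1e-9, grid_step)
    fluence = np.where(energies < kvp, (kvp - energies) / energies, 0.0)
    fluence[energies < 5.0] = 0.0  # photons below 5 keV never leave the tube
    if kvp > 69.5:
        total = fluence.sum()
        weights = np.array([w for _, w in _W_LINES])
        weights = weights / weights.sum() * _LINE_FRACTION * total
        for (line_e, _), w in zip(_W_LINES, weights):
            idx = int(np.argmin(np.abs(energies - line_e)))
            fluence[idx] += w
    spec = Spectrum(energies, fluence, kvp)
    spec = apply_filtration(spec, get_material("aluminum"),
                            _INHERENT_AL_MM / 10.0)
    return spec.normalized()


def monoenergetic(energy: float, grid_step: float = 1.0) -> Spectrum:
    """Delta spectrum: all fluence in the single grid bin nearest ``energy``."""
    energies = np.arange(1.0, 150.0 + 1e-9, grid_step)
    fluence = np.zeros_like(energies)
    idx = int(np.argmin(np.abs(energies - energy)))
    fluence[idx] = 1.0
    return Spectrum(energies, fluence, kvp=float(energies[idx]))


def apply_filtration(spectrum: Spectrum, material: MaterialTable,
                     thickness_cm: float) -> Spectrum:
    """Attenuate the spectrum through ``thickness_cm`` of ``material``
    (Beer-Lambert per energy)."""
    if thickness_cm < 0:
        raise ValueError("filtration thickness must be non-negative")
    mu = material(spectrum.energies)
    return Spectrum(spectrum.energies,
                    spectrum.fluence * np.exp(-mu * thickness_cm),
                    spectrum.kvp)


def bin_weights(spectrum: Spectrum, detector: DetectorModel | None) -> np.ndarray:
    """Per-bin fluence weights, shape (n_bins, n_energies).

    ``weights[k, i]`` = fluence at energy i if energy i falls in bin k,
    else 0.  Bins are [low, high) and [high, kvp] and never overlap.  With
    ``detector=None`` a single bin spanning the whole spectrum is used.
    """
    e, f = spectrum.energies, spectrum.fluence
    if detector is None:
        return f[None, :].copy()
    in1 = (e >= detector.low) & (e < detector.high)
    in2 = (e >= detector.high) & (e <= spectrum.kvp)
    return np.stack([np.where(in1, f, 0.0), np.where(in2, f, 0.0)])


def save_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a two-column (energy_keV, relative_fluence) CSV."""
    with open(path, "w") as fh:
        fh.write(f"# kvp: {spectrum.kvp}\n")
        fh.write("energy_keV,relative_fluence\n")
        for e, f in zip(spectrum.energies, spectrum.fluence):
            fh.write(f"{e:.6g},{f:.8e}\n")


def load_spectrum_csv(path, kvp: float | None = None) -> Spectrum:
    """Read a two-column CSV written externally (e.g. a TASMIP spectrum)."""
    energies, fluence = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "kvp" in line and kvp is None:
                    kvp = float(line.split(":")[1])
                continue
            if not line or line.startswith("energy"):
                continue
            e, f = line.split(",")
            energies.append(float(e))
            fluence.append(float(f))
    energies = np.array(energies)
    if kvp is None:
        kvp = float(energies[np.array(fluence) > 0].max())
    return Spectrum(energies, np.array(fluence), kvp)
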