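"""Synthetic phantom generators.

Provides the step-wedge material-decomposition calibration design, the
metal-artifact-evaluation (MAE) phantom (three 5-mm copper rods in a 30-mm
PMMA cylinder), simplified anatomical slices (head / abdomen / hip) with
titanium implants, and plain disk fixtures for analytic oracles.

Coordinate convention: the image center is the rotation isocenter, pixel
centers sit at half-integer offsets, row index increases downward (i.e.
physical y decreases with row index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import BasisPair

__all__ = [
    "PhantomImage",
    "CalibrationDesign",
    "Disk",
    "Rect",
    "MetalSpec",
    "make_calibration_design",
    "make_mae_phantom",
    "make_anatomy_surrogate",
    "make_disk_phantom",
]


@dataclass(frozen=True)
class PhantomImage:
    """A square raster of material labels.

    ``label_map[i, j]`` indexes into ``materials``; ``pixel_size`` is in mm
    and the image center coincides with the scanner isocenter.
    """

    label_map: np.ndarray = field(repr=False)
    materials: tuple[str, ...]
    pixel_size: float

    def __post_init__(self) -> None:
        lm = np.asarray(self.label_map)
        if lm.ndim != 2 or lm.shape[0] != lm.shape[1]:
            raise ValueError("label map must be square")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if lm.max(initial=0) >= len(self.materials) or lm.min(initial=0) < 0:
            raise ValueError("label map indexes a material that is not listed")
        object.__setattr__(self, "label_map", lm.astype(np.int16))
        object.__setattr__(self, "materials", tuple(self.materials))

    @property
    def n(self) -> int:
        return self.label_map.shape[0]

    @property
    def extent_mm(self) -> float:
        return self.n * self.pixel_size

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) pixel-center coordinates in mm (y up)."""
        n = self.n
        c = (np.arange(n) - n / 2 + 0.5) * self.pixel_size
        x = c[None, :].repeat(n, axis=0)
        y = (-c)[:, None].repeat(n, axis=1)
        return x, y

    def mu_map(self, energy: float) -> np.ndarray:
        """Linear attenuation image (1/cm) at ``energy`` keV."""
        from .materials import get_material

        mu = np.array([get_material(m)(energy) for m in self.materials])
        return mu[self.label_map]


@dataclass(frozen=True)
class CalibrationDesign:
    """Known slab-thickness pairs (cm) of the two basis materials."""

    pairs: np.ndarray = field(repr=False)  # (n, 2), cm
    basis: BasisPair

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.pairs, dtype=float))
        if p.shape[1] != 2:
            raise ValueError("pairs must be (n, 2)")
        if np.any(p < 0):
            raise ValueError("thicknesses must be non-negative")
        if len(np.unique(p, axis=0)) != len(p):
            raise ValueError("design points must be distinct")
        if len(p) < 6:
            raise ValueError("need at least 6 design points")
        object.__setattr__(self, "pairs", p)


@dataclass(frozen=True)
class Disk:
    """Disk primitive: center (x, y) mm, radius mm."""

    center: tuple[float, float]
    radius: float


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle primitive: center (x, y) mm, width/height mm."""

    center: tuple[float, float]
    width: float
    height: float


@dataclass(frozen=True)
class MetalSpec:
    """Metal implant description: geometric primitives plus a material name."""

    shapes: tuple
    material: str = "titanium"

    def rasterize(self, phantom_like: PhantomImage) -> np.ndarray:
        """Binary mask of the implant on the grid of ``phantom_like``."""
        x, y = phantom_like.coords()
        mask = np.zeros(x.shape, dtype=bool)
        for s in self.shapes:
            if isinstance(s, Disk):
                mask |= (x - s.center[0]) ** 2 + (y - s.center[1]) ** 2 \
                    <= s.radius ** 2
            elif isinstance(s, Rect):
                mask |= (np.abs(x - s.center[0]) <= s.width / 2) & \
                    (np.abs(y - s.center[1]) <= s.height / 2)
            else:
                raise TypeError(f"unsupported shape {type(s).__name__}")
        return mask


def make_calibration_design(n1: int, n2: int, max1: float, max2: float,
                            basis: BasisPair) -> CalibrationDesign:
    """Full-factorial step-wedge design: ``n1`` x ``n2`` equally spaced
    thickness pairs including zero, spanning [0, max1] x [0, max2] cm."""
    if n1 < 3 or n2 < 3:
        raise ValueError("need at least 3 steps per material")
    if max1 <= 0 or max2 <= 0:
        raise ValueError("maximum thicknesses must be positive")
    t1 = np.linspace(0.0, max1, n1)
    t2 = np.linspace(0.0, max2, n2)
    g1, g2 = np.meshgrid(t1, t2, indexing="ij")
    return CalibrationDesign(np.column_stack([g1.ravel(), g2.ravel()]), basis)


def _disk_mask(x, y, cx, cy, r):
    return (x - cx) ** 2 + (y - cy) ** 2 <= r ** 2


def make_disk_phantom(material: str, radius: float, pixel_size: float,
                      n: int | None = None,
                      background: str = "air") -> PhantomImage:
    """Single centered disk of ``material`` in ``background``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n is None:
        n = int(np.ceil(2.4 * radius / pixel_size / 2)) * 2
    lm = np.zeros((n, n), dtype=np.int16)
    p = PhantomImage(lm, (background, material), pixel_size)
    x, y = p.coords()
    lm[_disk_mask(x, y, 0.0, 0.0, radius)] = 1
    return PhantomImage(lm, (background, material), pixel_size)


def make_mae_phantom(pixel_size: float = 0.1, n: int | None = None) -> PhantomImage:
    """Metal-artifact evaluation phantom.

    A 30-mm diameter PMMA cylinder containing three 5-mm diameter copper
    rods whose centers sit on a 9-mm circle at 90, 210 and 330 degrees.
    """
    if pixel_size > 0.2:
        raise ValueError("pixel_size must be <= 0.2 mm to resolve 5-mm rods")
    if n is None:
        n = int(np.ceil(40.0 / pixel_size / 2)) * 2
    if n * pixel_size < 30.0:
        raise ValueError("grid too small for the 30-mm PMMA cylinder")
    materials = ("air", "pmma", "copper")
    lm = np.zeros((n, n), dtype=np.int16)
    x, y = PhantomImage(lm, materials, pixel_size).coords()
    lm[_disk_mask(x, y, 0.0, 0.0, 15.0)] = 1
    for ang in (90.0, 210.0, 330.0):
        cx = 9.0 * np.cos(np.deg2rad(ang))
        cy = 9.0 * np.sin(np.deg2rad(ang))
        lm[_disk_mask(x, y, cx, cy, 2.5)] = 2
    return PhantomImage(lm, materials, pixel_size)


# (body semi-axes, bone features) per region; extents follow the published
# per-region fields of view (head 256 mm, abdomen 409.6 mm, hip 512 mm).
_REGIONS = {"head": 256.0, "abdomen": 409.6, "hip": 512.0}


def make_anatomy_surrogate(region: str, metal: MetalSpec | None,
                           pixel_size: float,
                           n: int | None = None) -> PhantomImage:
    """Simplified anatomical slice with an optional burned-in metal implant.

    Geometric stand-ins replace the licensed XCAT anatomy: an elliptical
    soft-tissue body with a skull annulus (head), a vertebral body
    (abdomen) or femoral heads (hip).  Materials are always
    (air, soft_tissue, bone[, metal]).
    """
    if region not in _REGIONS:
        raise ValueError(f"unknown region {region!r}; choose from "
                         f"{sorted(_REGIONS)}")
    extent = _REGIONS[region]
    if n is None:
        n = int(round(extent / pixel_size))
    materials = ["air", "soft_tissue", "bone"]
    lm = np.zeros((n, n), dtype=np.int16)
    x, y = PhantomImage(lm, tuple(materials), pixel_size).coords()

    def ellipse(cx, cy, a, b):
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0

    if region == "head":
        a, b = 0.34 * extent, 0.42 * extent
        lm[ellipse(0, 0, a, b)] = 2          # skull
        lm[ellipse(0, 0, a - 8.0, b - 8.0)] = 1  # brain cavity
    elif region == "abdomen":
        a, b = 0.42 * extent, 0.28 * extent
        lm[ellipse(0, 0, a, b)] = 1
        lm[_disk_mask(x, y, 0.0, -0.17 * extent, 0.055 * extent)] = 2  # vertebra
        lm[_disk_mask(x, y, 0.0, -0.17 * extent, 0.025 * extent)] = 1  # marrow
    else:  # hip
        a, b = 0.42 * extent, 0.27 * extent
        lm[ellipse(0, 0, a, b)] = 1
        for sx in (-1.0, 1.0):
            cx = sx * 0.21 * extent
            lm[_disk_mask(x, y, cx, 0.0, 0.055 * extent)] = 2  # femoral head

    if metal is not None:
        materials.append(metal.material)
        base = PhantomImage(lm, tuple(materials), pixel_size)
        lm[metal.rasterize(base)] = len(materials) - 1
    return PhantomImage(lm, tuple(materials), pixel_size)
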