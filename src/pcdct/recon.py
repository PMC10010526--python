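"""2D flat-detector fan-beam filtered backprojection and HU conversion.

The implementation follows the classical equispaced-detector fan-beam FBP:
projections are rescaled to a virtual flat detector through the isocenter,
cosine pre-weighted, ramp filtered (optionally Hann apodized), and
backprojected with the fan-beam distance weight SAD^2/U^2.  Full 360-degree
scans only; each line is measured twice, hence the global factor 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .projector import FanBeamGeometry

__all__ = ["ReconImage", "fbp_fan", "to_hu", "ramp_kernel"]


@dataclass(frozen=True)
class ReconImage:
    """Reconstructed image with pixel size (mm) and provenance metadata."""

    values: np.ndarray = field(repr=False)
    pixel_size: float
    meta: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, **meta) -> "ReconImage":
        return ReconImage(values, self.pixel_size, {**self.meta, **meta})


def ramp_kernel(n: int, spacing: float) -> np.ndarray:
    """Spatial-domain Ram-Lak kernel h[k] for k in [-n/2, n/2)."""
    k = np.arange(-n // 2, n // 2)
    h = np.zeros(n)
    h[k == 0] = 1.0 / (4.0 * spacing ** 2)
    odd = k % 2 == 1
    h[odd] = -1.0 / (np.pi * k[odd] * spacing) ** 2
    return h


def _filter_projections(p: np.ndarray, spacing: float,
                        apodization: str) -> np.ndarray:
    """Ramp-filter each row of p (n_views, n_det); returns same shape."""
    n_det = p.shape[1]
    size = int(2 ** np.ceil(np.log2(2 * n_det)))
    h = ramp_kernel(size, spacing)
    H = np.abs(np.fft.fft(np.fft.ifftshift(h)))
    if apodization == "hann":
        f = np.fft.fftfreq(size)
        H *= 0.5 * (1 + np.cos(2 * np.pi * f / (2 * 0.5)))
    elif apodization != "ramp":
        raise ValueError("apodization must be 'ramp' or 'hann'")
    P = np.fft.fft(p, n=size, axis=1)
    out = np.real(np.fft.ifft(P * H[None, :], axis=1))[:, :n_det]
    return out * spacing


def fbp_fan(logp: np.ndarray, geometry: FanBeamGeometry,
            out_pixel_size: float, out_n: int,
            apodization: str = "ramp") -> ReconImage:
    """Reconstruct linear attenuation (1/cm) from log projections.

    ``logp`` has shape (n_views, n_det) and holds line integrals of mu in
    units of cm (i.e. mu [1/cm] times path [cm]); the view angles must
    cover a full 360-degree rotation.
    """
    logp = np.asarray(logp, dtype=float)
    if logp.shape != (geometry.n_views, geometry.n_det):
        raise ValueError("projection array does not match geometry")
    span = np.ptp(geometry.view_angles)
    if span < 360.0 * (1 - 2.0 / geometry.n_views):
        raise ValueError("fbp_fan supports full 360-degree scans only")

    sad = geometry.sad
    # virtual detector through the isocenter
    s = geometry.det_coords() / geometry.magnification
    ds = geometry.det_pitch / geometry.magnification
    weighted = logp * (sad / np.sqrt(sad ** 2 + s ** 2))[None, :]
    filtered = _filter_projections(weighted, ds, apodization)

    n = out_n
    c = (np.arange(n) - n / 2 + 0.5) * out_pixel_size
    x = c[None, :].repeat(n, axis=0)
    y = (-c)[:, None].repeat(n, axis=1)
    image = np.zeros((n, n))
    dbeta = np.deg2rad(360.0 / geometry.n_views)
    for v, ang in enumerate(geometry.view_angles):
        b = np.deg2rad(ang)
        cb, sb = np.cos(b), np.sin(b)
        u = sad - (x * cb + y * sb)          # distance along central ray
        sprime = sad * (-x * sb + y * cb) / u
        q = np.interp(sprime.ravel(), s, filtered[v], left=0.0, right=0.0)
        image += (sad ** 2 / u ** 2) * q.reshape(n, n)
    image *= dbeta / 2.0
    # logp carries mu*cm while distances are mm: the ramp filter contributes
    # 1/mm, so the image is (mu/cm)*(cm/mm)... convert to 1/cm.
    image *= 10.0
    return ReconImage(image, out_pixel_size,
                      {"method": "fbp_fan", "apodization": apodization,
                       "geometry": geometry})


def to_hu(image: ReconImage, mu_water: float) -> ReconImage:
    """Convert a mu image (1/cm) to Hounsfield units."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    hu = 1000.0 * (image.values - mu_water) / mu_water
    return image.with_values(hu, units="HU", mu_water=mu_water)
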