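"""Sinogram-inpainting metal artifact reduction baselines.

LMAR replaces the metal-trace samples of each view by 1-D linear
interpolation between the nearest untouched neighbors.  NMAR performs the
same interpolation on a sinogram normalized by the forward projection of a
three-class prior image (air / soft tissue / bone) built from the LMAR
reconstruction, then denormalizes; values outside the trace are restored
bit-exactly in both methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .projector import FanBeamGeometry, project_image
from .recon import ReconImage

__all__ = [
    "MetalMask",
    "MetalTrace",
    "segment_metal",
    "metal_trace",
    "lmar",
    "build_prior",
    "nmar",
    "reinsert_metal",
]

DEFAULT_METAL_HU = 3000.0
PRIOR_OFFSET_HU = 1000.0  # makes air ~0 so the prior sinogram stays positive


@dataclass(frozen=True)
class MetalMask:
    """Binary metal segmentation aligned with a reconstruction grid."""

    mask: np.ndarray = field(repr=False)
    threshold_hu: float

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass(frozen=True)
class MetalTrace:
    """Binary (view, detector) map of rays that intersect metal."""

    trace: np.ndarray = field(repr=False)

    @property
    def empty(self) -> bool:
        return not bool(self.trace.any())


def segment_metal(image: ReconImage,
                  threshold_hu: float = DEFAULT_METAL_HU) -> MetalMask:
    """Threshold an HU image at ``threshold_hu``."""
    return MetalMask(image.values >= threshold_hu, threshold_hu)


def metal_trace(mask: MetalMask, geometry: FanBeamGeometry,
                pixel_size: float, eps: float = 1e-9) -> MetalTrace:
    """Forward-project the metal mask; a ray is in the trace when its
    metal path length exceeds ``eps``."""
    if mask.empty:
        return MetalTrace(np.zeros((geometry.n_views, geometry.n_det),
                                   dtype=bool))
    proj = project_image(mask.mask.astype(float), pixel_size, geometry)
    return MetalTrace(proj > eps)


def _inpaint_view(values: np.ndarray, trace_row: np.ndarray) -> np.ndarray:
    """Linear interpolation across trace samples of one detector row."""
    out = values.copy()
    good = ~trace_row
    if good.sum() < 2:  # trace spans the whole row: fall back to view mean
        out[trace_row] = values[good].mean() if good.any() else values.mean()
        return out
    idx = np.arange(values.size)
    out[trace_row] = np.interp(idx[trace_row], idx[good], values[good])
    return out


def lmar(logp: np.ndarray, trace: MetalTrace) -> np.ndarray:
    """Linear-interpolation MAR on a (n_views, n_det) log projection array.

    Samples outside the trace are returned bit-identical.
    """
    logp = np.asarray(logp, dtype=float)
    if trace.empty:
        return logp.copy()
    out = logp.copy()
    rows = np.flatnonzero(trace.trace.any(axis=1))
    for v in rows:
        out[v] = _inpaint_view(logp[v], trace.trace[v])
    return out


def build_prior(lmar_image: ReconImage,
                tissue_thresholds: tuple[float, float] = (-500.0, 500.0),
                soft_tissue_hu: float = 0.0) -> ReconImage:
    """Three-class prior image from an initial LMAR reconstruction (HU):
    air below ``low`` -> -1000 HU, soft tissue in between -> a flat value,
    bone above ``high`` -> original values retained."""
    low, high = tissue_thresholds
    v = lmar_image.values
    prior = np.where(v < low, -1000.0,
                     np.where(v <= high, soft_tissue_hu, v))
    return lmar_image.with_values(prior, prior=True)


def nmar(logp: np.ndarray, trace: MetalTrace, prior: ReconImage,
         geometry: FanBeamGeometry) -> np.ndarray:
    """Normalized MAR: interpolate the prior-normalized sinogram in the
    trace, then denormalize; exact identity outside the trace."""
    logp = np.asarray(logp, dtype=float)
    if trace.empty:
        return logp.copy()
    shifted = prior.values + PRIOR_OFFSET_HU
    prior_sino = project_image(shifted, prior.pixel_size, geometry)
    eps = 1e-6 * prior_sino.max() if prior_sino.max() > 0 else 1e-12
    out = logp.copy()
    for v in np.flatnonzero(trace.trace.any(axis=1)):
        t = trace.trace[v]
        ps = prior_sino[v]
        if np.all(ps[t] <= eps):  # degenerate prior: fall back to LMAR
            out[v] = _inpaint_view(logp[v], t)
            continue
        norm = np.where(ps > eps, logp[v] / np.where(ps > eps, ps, 1.0),
                        logp[v])
        filled = _inpaint_view(norm, t)
        denorm = np.where(ps > eps, filled * ps, filled)
        out[v, t] = denorm[t]
    return out


def reinsert_metal(corrected: ReconImage, mask: MetalMask,
                   original: ReconImage) -> ReconImage:
    """Copy the original image values back into the metal mask."""
    if corrected.values.shape != original.values.shape:
        raise ValueError("image grids are not aligned")
    values = corrected.values.copy()
    values[mask.mask] = original.values[mask.mask]
    return corrected.with_values(values, metal_reinserted=True)
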