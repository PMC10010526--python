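"""Projection-based two-material decomposition and virtual monochromatic
sinogram synthesis.

Two estimators map the two energy-bin log projections (P1, P2) of a ray to
effective basis-material thicknesses (A_m1, A_m2):

* the *polynomial* (reverse) model fits each thickness on the quadratic
  basis {1, P1, P2, P1^2, P1 P2, P2^2} against a step-wedge calibration;
* the *A-table* model fits an effective 2x2 attenuation matrix M with
  P = M A + w, solves the weighted linear MLE, and corrects the residual
  beam-hardening bias with a look-up table of corrections dA tabulated at
  the calibration points in estimate space.

A virtual monochromatic projection at energy E is then
P(E) = mu_m1(E) A_m1 + mu_m2(E) A_m2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .materials import BasisPair
from .phantoms import CalibrationDesign
from .projector import BinnedSinogram, COUNT_FLOOR, log_projections
from .spectra import DetectorModel, Spectrum, bin_weights

__all__ = [
    "CalibrationSet",
    "PolyModel",
    "AtableModel",
    "ThicknessSinogram",
    "VMIRequest",
    "simulate_calibration",
    "fit_poly",
    "apply_poly",
    "fit_atable",
    "mle_estimate",
    "apply_atable",
    "decompose_sinogram",
    "synthesize_vmi",
]


@dataclass(frozen=True)
class CalibrationSet:
    """Step-wedge calibration measurements.

    ``projections`` holds (P1, P2) per design point, ``counts`` the
    corresponding per-bin photon counts (used for MLE weighting).
    """

    design: CalibrationDesign
    projections: np.ndarray = field(repr=False)  # (n, 2)
    counts: np.ndarray = field(repr=False)       # (n, 2)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.projections)):
            raise ValueError("calibration projections must be finite")

    @property
    def basis(self) -> BasisPair:
        return self.design.basis


def _quad_basis(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    return np.stack([np.ones_like(p1), p1, p2, p1 ** 2, p1 * p2, p2 ** 2],
                    axis=-1)


@dataclass(frozen=True)
class PolyModel:
    """Reverse quadratic decomposition model A_m = d . basis(P1, P2)."""

    d1: np.ndarray  # six coefficients for A_m1
    d2: np.ndarray  # six coefficients for A_m2
    basis: BasisPair
    fit_residual: float  # RMS thickness residual on the calibration set, cm


@dataclass(frozen=True)
class AtableModel:
    """Linear MLE decomposition with error-correction look-up table."""

    M: np.ndarray                      # (2, 2) effective mu matrix, 1/cm
    lut_nodes: np.ndarray = field(repr=False)   # A_MLE at calibration points
    lut_values: np.ndarray = field(repr=False)  # dA = A_calib - A_MLE there
    basis: BasisPair = None

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.M)) < 1e-12:
            raise ValueError("effective attenuation matrix is singular")
        object.__setattr__(
            self, "_lin",
            LinearNDInterpolator(self.lut_nodes, self.lut_values))
        object.__setattr__(
            self, "_near",
            NearestNDInterpolator(self.lut_nodes, self.lut_values))

    def correction(self, a_mle: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated dA at ``a_mle`` (n, 2); returns (dA, outside_hull)."""
        da = self._lin(a_mle)
        outside = np.isnan(da[:, 0])
        if np.any(outside):
            da[outside] = self._near(a_mle[outside])
        return da, outside


@dataclass(frozen=True)
class ThicknessSinogram:
    """Effective basis thicknesses per ray, cm, shape (n_views, n_det, 2)."""

    thickness: np.ndarray = field(repr=False)
    basis: BasisPair
    outside_hull_fraction: float = 0.0


@dataclass(frozen=True)
class VMIRequest:
    """A virtual monochromatic synthesis request."""

    energy: float
    basis: BasisPair

    def __post_init__(self) -> None:
        if not 1.0 <= self.energy <= 150.0:
            raise ValueError("energy must lie in [1, 150] keV")


def simulate_calibration(design: CalibrationDesign, spectrum: Spectrum,
                         detector: DetectorModel, n0: float,
                         seed: int | None = None) -> CalibrationSet:
    """Slab-geometry calibration measurements for every design point.

    Counts follow the spectral Beer-Lambert model through A_m1 cm of the
    first and A_m2 cm of the second basis material; with ``seed`` given,
    Poisson noise is applied.
    """
    w = bin_weights(spectrum, detector)
    w = w / w.sum()
    mu1 = design.basis.m1(spectrum.energies)
    mu2 = design.basis.m2(spectrum.energies)
    att = np.outer(design.pairs[:, 0], mu1) + np.outer(design.pairs[:, 1], mu2)
    counts = n0 * (np.exp(-att) @ w.T)       # (n, 2)
    blank = n0 * w.sum(axis=1)
    if seed is not None:
        counts = np.random.default_rng(seed).poisson(counts).astype(float)
        # integer measurements can be zero; floor before the log
        proj = -np.log(np.maximum(counts, COUNT_FLOOR) / blank[None, :])
    else:
        # noise-free expected counts are strictly positive: exact log
        proj = -np.log(counts / blank[None, :])
    return CalibrationSet(design, proj, counts)


def fit_poly(calib: CalibrationSet) -> PolyModel:
    """Least-squares fit of the reverse quadratic model on a calibration set."""
    if len(calib.design.pairs) < 6:
        raise ValueError("at least 6 calibration points are required")
    X = _quad_basis(calib.projections[:, 0], calib.projections[:, 1])
    if np.linalg.matrix_rank(X) < 6:
        raise np.linalg.LinAlgError("calibration design is rank deficient "
                                    "in (P1, P2)")
    sol, *_ = np.linalg.lstsq(X, calib.design.pairs, rcond=None)
    resid = calib.design.pairs - X @ sol
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return PolyModel(sol[:, 0].copy(), sol[:, 1].copy(), calib.basis, rms)


def apply_poly(model: PolyModel, p1, p2) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the reverse polynomial; no clipping is applied."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    X = _quad_basis(p1, p2)
    return X @ model.d1, X @ model.d2


def fit_atable(calib: CalibrationSet) -> AtableModel:
    """Fit the linear model P = M A (no intercept) and build the dA table.

    M comes from ordinary least squares over the full calibration design;
    each calibration point contributes one LUT node at its MLE estimate
    with value dA = A_calib - A_MLE.
    """
    A = calib.design.pairs
    if np.linalg.matrix_rank(A) < 2:
        raise np.linalg.LinAlgError("calibration thicknesses are collinear")
    Mt, *_ = np.linalg.lstsq(A, calib.projections, rcond=None)
    M = Mt.T  # P = M A
    a_mle = mle_estimate_matrix(M, calib.projections, calib.counts)
    da = A - a_mle
    return AtableModel(M, a_mle, da, calib.basis)


def mle_estimate_matrix(M: np.ndarray, p: np.ndarray,
                        counts: np.ndarray) -> np.ndarray:
    """Weighted linear MLE A = (M' R^-1 M)^-1 M' R^-1 P for many rays.

    R is the first-order Poisson covariance of the log projections,
    diag(1/N1, 1/N2) with the measured (floored) counts.  For the square
    two-bin system this equals M^-1 P for any positive weights; the full
    weighted form is kept for generality.
    """
    p = np.atleast_2d(p)
    w = np.maximum(np.atleast_2d(counts), COUNT_FLOOR)  # R^-1 = diag(N)
    # normal equations per ray, vectorized: 2x2 solve
    m11 = (w * M[:, 0] * M[:, 0]).sum(axis=1)
    m12 = (w * M[:, 0] * M[:, 1]).sum(axis=1)
    m22 = (w * M[:, 1] * M[:, 1]).sum(axis=1)
    b1 = (w * M[:, 0] * p).sum(axis=1)
    b2 = (w * M[:, 1] * p).sum(axis=1)
    det = m11 * m22 - m12 ** 2
    if np.any(np.abs(det) < 1e-300):
        raise np.linalg.LinAlgError("singular weighted normal matrix")
    a1 = (m22 * b1 - m12 * b2) / det
    a2 = (m11 * b2 - m12 * b1) / det
    return np.stack([a1, a2], axis=-1)


def mle_estimate(model: AtableModel, p, counts) -> np.ndarray:
    """Initial linear MLE thickness estimate for one or more rays."""
    return np.squeeze(mle_estimate_matrix(model.M, p, counts))


def apply_atable(model: AtableModel, p, counts,
                 return_outside: bool = False):
    """A = A_MLE + dA(A_MLE), with dA linearly interpolated over the LUT
    node cloud (nearest node outside the convex hull)."""
    a_mle = np.atleast_2d(mle_estimate_matrix(model.M, np.atleast_2d(p),
                                              np.atleast_2d(counts)))
    da, outside = model.correction(a_mle)
    a = np.squeeze(a_mle + da)
    if return_outside:
        return a, outside
    return a


def decompose_sinogram(model: PolyModel | AtableModel,
                       sino: BinnedSinogram) -> ThicknessSinogram:
    """Apply a fitted decomposition model ray-by-ray to a two-bin sinogram."""
    if sino.n_bins != 2:
        raise ValueError("decomposition requires exactly two energy bins")
    logp = log_projections(sino)
    p1 = logp[0].ravel()
    p2 = logp[1].ravel()
    nv, nd = logp.shape[1:]
    if isinstance(model, PolyModel):
        a1, a2 = apply_poly(model, p1, p2)
        thick = np.stack([a1, a2], axis=-1)
        frac = 0.0
        basis = model.basis
    else:
        counts = sino.counts.reshape(2, -1).T
        p = np.stack([p1, p2], axis=-1)
        thick, outside = apply_atable(model, p, counts, return_outside=True)
        thick = np.atleast_2d(thick)
        frac = float(np.mean(outside))
        basis = model.basis
    return ThicknessSinogram(thick.reshape(nv, nd, 2), basis, frac)


def synthesize_vmi(thick: ThicknessSinogram,
                   request: VMIRequest) -> np.ndarray:
    """Virtual monochromatic log projections at the requested energy:
    P(E) = mu_m1(E) A_m1 + mu_m2(E) A_m2, shape (n_views, n_det)."""
    mu1 = request.basis.m1(request.energy)
    mu2 = request.basis.m2(request.energy)
    return (mu1 * thick.thickness[..., 0] + mu2 * thick.thickness[..., 1])
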