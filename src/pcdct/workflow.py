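"""End-to-end pipeline: simulate -> calibrate -> decompose -> VMI/MAR ->
reconstruct -> evaluate.

All correction methods consume the *same* simulated raw two-bin sinogram,
so comparisons are paired; the reference image is a noise-free
monochromatic reconstruction of the same phantom (no beam hardening, hence
no metal artifacts).
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from . import decomp, mar
from .materials import BasisPair, get_material
from .metrics import MetricsReport, SSIMParams
from .phantoms import PhantomImage, make_calibration_design
from .projector import (BinnedSinogram, FanBeamGeometry, add_poisson_noise,
                        expected_counts, log_projections, trace_paths)
from .recon import ReconImage, fbp_fan, to_hu
from .spectra import (DetectorModel, apply_filtration, bin_weights,
                      generate_spectrum, monoenergetic)

__all__ = [
    "GEOMETRY_PRESETS",
    "RunConfig",
    "RunManifest",
    "PipelineResult",
    "run_pipeline",
    "extract_line_profile",
]

GEOMETRY_PRESETS = {
    # full-scale dental and conventional scanner geometries
    "dental": FanBeamGeometry(sad=400.0, aid=200.0, n_views=1080,
                              n_det=1024, det_pitch=0.5),
    "conventional": FanBeamGeometry(sad=600.0, aid=400.0, n_views=1080,
                                    n_det=1024, det_pitch=1.0),
    # reduced-size preset for fast runs: same dental fan angle, coarser
    # sampling (360 views, 256 detectors)
    "test": FanBeamGeometry(sad=400.0, aid=200.0, n_views=360,
                            n_det=256, det_pitch=2.0),
}

ALL_METHODS = ("uncorrected", "lmar", "nmar", "vmi_poly", "vmi_atable")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on."""

    phantom: PhantomImage
    geometry: str | FanBeamGeometry = "test"
    kvp: float = 140.0
    added_filtration_mm_al: float = 2.0
    thresholds: tuple[float, float] = (20.0, 90.0)
    energy_step: float = 1.0
    n0: float = 1.0e7
    noise: bool = True
    seed: int = 0
    methods: tuple[str, ...] = ALL_METHODS
    e_vmi: float = 100.0
    e_ref: float = 100.0
    recon_n: int = 256
    recon_pixel_size: float | None = None  # default: phantom FOV / recon_n
    basis: tuple[str, str] = ("pmma", "aluminum")
    calibration_steps: tuple[int, int] = (10, 10)
    calibration_max_cm: tuple[float, float] = (50.0, 10.0)
    calibration_noise: bool = False
    metal_threshold_hu: float = mar.DEFAULT_METAL_HU
    rois: dict = field(default_factory=dict)  # name -> (r0, r1, c0, c1)
    profiles: tuple = ()  # ((x0, y0), (x1, y1), n_samples) in mm

    def resolved_geometry(self) -> FanBeamGeometry:
        if isinstance(self.geometry, str):
            return GEOMETRY_PRESETS[self.geometry]
        return self.geometry

    def resolved_pixel_size(self) -> float:
        if self.recon_pixel_size is not None:
            return self.recon_pixel_size
        return self.phantom.extent_mm / self.recon_n

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(repr(self).encode())
        h.update(self.phantom.label_map.tobytes())
        return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    software_version: str
    stage_seconds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)  # path -> sha256


@dataclass
class PipelineResult:
    images: dict            # method -> ReconImage (HU)
    reference: ReconImage   # HU
    sinograms: dict         # method -> (n_views, n_det) log projections
    report: MetricsReport
    profiles: dict          # method -> list of sampled profiles
    manifest: RunManifest


def _mono_reference(config: RunConfig, geometry, paths) -> ReconImage:
    # delta spectrum: always exact on the fine grid, whatever the
    # polychromatic simulation step
    spec = monoenergetic(config.e_ref, 1.0)
    sino = expected_counts(paths, spec, None, config.n0)
    logp = log_projections(sino)[0]
    img = fbp_fan(logp, geometry, config.resolved_pixel_size(),
                  config.recon_n)
    return to_hu(img, get_material("water")(config.e_ref))


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Execute the requested methods on one shared simulated acquisition."""
    from . import __version__

    manifest = RunManifest(config.digest(), __version__)
    geometry = config.resolved_geometry()
    px = config.resolved_pixel_size()
    t0 = time.perf_counter()

    spectrum = generate_spectrum(config.kvp, config.energy_step)
    if config.added_filtration_mm_al > 0:
        spectrum = apply_filtration(
            spectrum, get_material("aluminum"),
            config.added_filtration_mm_al / 10.0).normalized()
    detector = DetectorModel(*config.thresholds)
    manifest.stage_seconds["spectrum"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    paths = trace_paths(config.phantom, geometry)
    raw = expected_counts(paths, spectrum, detector, config.n0)
    if config.noise:
        raw = add_poisson_noise(raw, config.seed)
    manifest.stage_seconds["forward"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    reference = _mono_reference(config, geometry, paths)
    manifest.stage_seconds["reference"] = time.perf_counter() - t0

    # detected mean energy defines the water reference for polychromatic HU
    w = bin_weights(spectrum, detector)
    e_mean = float(np.average(
        np.tile(spectrum.energies, (w.shape[0], 1)).ravel(),
        weights=w.ravel()))
    mu_water_poly = get_material("water")(e_mean)

    summed = raw.summed()
    logp_total = log_projections(summed)[0]
    images: dict[str, ReconImage] = {}
    sinos: dict[str, np.ndarray] = {}

    def recon_poly(logp):
        return to_hu(fbp_fan(logp, geometry, px, config.recon_n),
                     mu_water_poly)

    t0 = time.perf_counter()
    uncorrected = recon_poly(logp_total)
    if "uncorrected" in config.methods:
        images["uncorrected"] = uncorrected
        sinos["uncorrected"] = logp_total
    manifest.stage_seconds["uncorrected"] = time.perf_counter() - t0

    mask = mar.segment_metal(uncorrected, config.metal_threshold_hu)
    if mask.empty:
        manifest.warnings.append("empty metal mask: MAR methods are identity")
    trace = mar.metal_trace(mask, geometry, px)

    if "lmar" in config.methods or "nmar" in config.methods:
        t0 = time.perf_counter()
        lmar_sino = mar.lmar(logp_total, trace)
        lmar_img = recon_poly(lmar_sino)
        if "lmar" in config.methods:
            images["lmar"] = mar.reinsert_metal(lmar_img, mask, uncorrected)
            sinos["lmar"] = lmar_sino
        manifest.stage_seconds["lmar"] = time.perf_counter() - t0
        if "nmar" in config.methods:
            t0 = time.perf_counter()
            prior = mar.build_prior(lmar_img)
            nmar_sino = mar.nmar(logp_total, trace, prior, geometry)
            nmar_img = recon_poly(nmar_sino)
            images["nmar"] = mar.reinsert_metal(nmar_img, mask, uncorrected)
            sinos["nmar"] = nmar_sino
            manifest.stage_seconds["nmar"] = time.perf_counter() - t0

    if "vmi_poly" in config.methods or "vmi_atable" in config.methods:
        t0 = time.perf_counter()
        basis = BasisPair(get_material(config.basis[0]),
                          get_material(config.basis[1]))
        design = make_calibration_design(*config.calibration_steps,
                                         *config.calibration_max_cm, basis)
        calib = decomp.simulate_calibration(
            design, spectrum, detector, config.n0,
            seed=config.seed + 1 if config.calibration_noise else None)
        manifest.stage_seconds["calibration"] = time.perf_counter() - t0
        mu_water_vmi = get_material("water")(config.e_vmi)
        for name, fitter in (("vmi_poly", decomp.fit_poly),
                             ("vmi_atable", decomp.fit_atable)):
            if name not in config.methods:
                continue
            t0 = time.perf_counter()
            model = fitter(calib)
            thick = decomp.decompose_sinogram(model, raw)
            vmi = decomp.synthesize_vmi(
                thick, decomp.VMIRequest(config.e_vmi, basis))
            images[name] = to_hu(fbp_fan(vmi, geometry, px, config.recon_n),
                                 mu_water_vmi)
            sinos[name] = vmi
            if getattr(thick, "outside_hull_fraction", 0.0) > 0:
                manifest.warnings.append(
                    f"{name}: {thick.outside_hull_fraction:.1%} of rays "
                    "outside the calibration hull")
            manifest.stage_seconds[name] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = MetricsReport()
    ssim_params = SSIMParams()
    for name, img in images.items():
        report.add(name, "whole", reference, img, ssim_params)
        for roi_name, (r0, r1, c0, c1) in config.rois.items():
            report.add(name, roi_name, reference.values[r0:r1, c0:c1],
                       img.values[r0:r1, c0:c1], ssim_params)
    profiles = {}
    for name, img in images.items():
        profiles[name] = [
            extract_line_profile(img, p0, p1, nsamp)
            for (p0, p1, nsamp) in config.profiles
        ]
    manifest.stage_seconds["evaluate"] = time.perf_counter() - t0

    result = PipelineResult(images, reference, sinos, report, profiles,
                            manifest)
    if outdir is not None:
        _write_outputs(result, outdir, manifest)
    return result


def _write_outputs(result: PipelineResult, outdir, manifest: RunManifest):
    import json
    import pathlib

    from .io import save_image_tiff

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, img in {**result.images, "reference": result.reference}.items():
        path = outdir / f"{name}.tif"
        save_image_tiff(img, path)
        manifest.artifacts[str(path)] = hashlib.sha256(
            path.read_bytes()).hexdigest()
    result.report.to_json(outdir / "metrics.json")
    result.report.to_csv(outdir / "metrics.csv")
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump({
            "config_hash": manifest.config_hash,
            "software_version": manifest.software_version,
            "stage_seconds": manifest.stage_seconds,
            "warnings": manifest.warnings,
            "artifacts": manifest.artifacts,
        }, fh, indent=2)


def extract_line_profile(image: ReconImage, p0: tuple[float, float],
                         p1: tuple[float, float], n: int) -> np.ndarray:
    """Bilinear samples at ``n`` uniform points from ``p0`` to ``p1`` (mm,
    isocenter origin, y up)."""
    npix = image.n
    half = npix / 2 - 0.5

    def to_rc(p):
        x, y = p
        col = x / image.pixel_size + half
        row = half - y / image.pixel_size
        if not (0 <= row <= npix - 1 and 0 <= col <= npix - 1):
            raise ValueError(f"point {p} lies outside the image")
        return row, col

    r0, c0 = to_rc(p0)
    r1, c1 = to_rc(p1)
    t = np.linspace(0.0, 1.0, n)
    rows = r0 + t * (r1 - r0)
    cols = c0 + t * (c1 - c0)
    return map_coordinates(image.values, [rows, cols], order=1)
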