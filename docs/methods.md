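# Methods

## Physical model and scope

The simulator models 2-D fan-beam CT with an ideal point source, primary
photons only, and an ideal photon-counting detector (perfect energy
resolution and detection efficiency, two comparator thresholds).  These
are deliberate simplifications: scatter, focal-spot blur, detector
cross-talk, charge sharing and pile-up are out of scope.  Photon
transport is Beer–Lambert attenuation on a 1-keV energy grid; each
detector pixel's expected count in bin *k* is

    N_k = n0 * sum_E w_k(E) * exp(-sum_m mu_m(E) L_m),

where `w_k` is the tube fluence restricted to bin *k* and normalized so
that the blank counts over both bins sum to `n0`, and `L_m` is the exact
per-material intersection length of the ray with the labeled pixel grid
(Siddon traversal, vectorized per view).  Measurements are independent
Poisson draws around those expectations.

## Attenuation tables

Linear attenuation curves for water, soft tissue, cortical bone, PMMA,
aluminum, titanium, copper and air ship as CSV tables on a 1–150 keV,
1-keV grid, generated from NIST-XCOM standard-grid mass-attenuation
anchors (with K-edge discontinuities for Al, Ti, Cu) by log-log
interpolation (`tools/build_attenuation_tables.py`).  Run-time evaluation
at arbitrary energies uses the same log-log rule, exact at grid nodes.
Densities: water 1.0, soft tissue 1.06, bone 1.92, PMMA 1.19, Al 2.699,
Ti 4.506, Cu 8.96 g/cm³.  Soft tissue uses the water mass-attenuation
curve at tissue density (a standard water-equivalent surrogate); the
bone curve below 15 keV is a smooth edge-free interpolation and only
qualitative — immaterial here because the detector's low threshold is
20 keV.  Anchor fidelity in the 20–150 keV band is the printed NIST
precision for water/PMMA/Al/Ti/Cu (the quantitatively exercised
materials) and ~1–2% for bone and air.

## Tube spectrum

The polychromatic source is a Kramers continuum (fluence ∝ (kVp−E)/E)
plus tungsten K lines at 59.3/67.2/69.1 keV (10% of continuum fluence,
present only above the K edge), hardened by 1.6 mm inherent Al and, for
the standard protocol, 2 mm added Al.  This is a parameterized stand-in
with the qualitative shape of a measured 140-kV tungsten spectrum; the
decomposition algorithms are calibration-based and therefore robust to
the exact spectral shape.  An externally computed spectrum can be
imported from two-column CSV when numeric fidelity to a specific tube
matters.  Energy bins follow the half-open convention [low, high) and
[high, kVp]; in whole-keV quoting, thresholds (30, 80) at 140 kVp read
[31 80] and [81 140].

## Geometry and reconstruction

Flat-detector fan beam; presets: *dental* (SAD 400 mm, AID 200 mm,
1080 views, 1024 pixels at 0.5 mm), *conventional* (SAD 600, AID 400,
1080 views, 1024 at 1.0 mm), and a reduced *test* preset (SAD 400,
AID 200, 360 views, 256 pixels at 2.0 mm) used by the test suite, the
examples and the acceptance script so that every end-to-end check runs in
seconds on one CPU.  Reconstruction is classical equispaced fan-beam FBP:
rescale to a virtual detector through the isocenter, cosine weight, ramp
filter (FFT, zero-padded; optional Hann apodization, default pure ramp),
distance-weighted backprojection over 360°, global factor 1/2 for the
double coverage.  The monochromatic water-disk oracle reconstructs the
tabulated mu to 0.05%.  HU conversion uses mu_water at the VMI energy for
VMI images and at the detected mean energy for polychromatic images (the
reference is configurable and recorded in image metadata).

## Material decomposition

Calibration is a 10x10 full-factorial step wedge, PMMA 0–50 cm x Al
0–10 cm, measured in closed slab geometry (no ray tracing).  Noise-free
calibration uses exact expected counts (no count floor — expectations are
strictly positive); noisy measurements floor integer counts at 0.5 before
the log.

*Polynomial (VMI-Poly).*  Each thickness is least-squares fitted on the
six-term quadratic basis {1, P1, P2, P1², P1P2, P2²}; the RMS thickness
residual on the calibration set (0.046 cm ≈ 0.09% of the 50-cm maximum)
is stored on the model.  No clipping is applied at evaluation.

*A-table (VMI-Atable).*  `M` is the ordinary-least-squares solution of
`P_calib = M A_calib` (no intercept) over the full design.  The MLE uses
first-order Poisson weights `R = diag(1/N1, 1/N2)` from measured counts;
for the square two-bin system the weighted estimate equals `M⁻¹P`
identically, so the weighting matters only if more bins are added.  The
correction table stores `dA = A_calib − A_MLE,calib` at the nodes
`A_MLE,calib`, interpolated at query points by scattered linear
(Delaunay) interpolation; outside the node hull the nearest node's
correction is used and the ray is flagged (the fraction is recorded on
the thickness sinogram).  By construction the decomposition is exact at
calibration nodes to machine precision.

Between nodes the correction field is strongly curved near the design
origin: the low bin spans 20–90 keV, so the first centimeters of Al
remove the soft end of the spectrum and shift the effective attenuation
rapidly, while OLS fits `M` to the whole (heavily hardened) design.
Linear interpolation of `dA` on the coarse 10-step grid then leaves
errors up to ~0.5 cm in the first design cells (~1% of the design
diagonal but up to ~25% of the local thickness there); over ~90% of the
design the error is below 2% of the spacing-floored local truth.  This
is an intrinsic resolution limit of a 10-node LUT across an 18-decade
transmission range, not of the implementation: a C1 (Clough–Tocher)
interpolant halves the error but does not reach 2% everywhere, and
re-anchoring `M` to the small-signal slope fixes the origin while
breaking the far field.  Errors lie almost entirely along the direction
to which a 100-keV monochromatic synthesis is insensitive, so VMI
fidelity is far better than raw thickness fidelity (sinogram NRMSE
1e-4 for A-table, 7e-3 for the polynomial on a 50-mm PMMA disk).

Non-basis materials (tissues, Ti, Cu) are decomposed onto the PMMA/Al
basis by design; no metal-ray special-casing.  Negative thickness
estimates are kept (clipping would bias the ramp-filtered
reconstruction).  VMI synthesis defaults to 100 keV.

## MAR baselines

LMAR and NMAR operate on the summed-bin (total-count) log projection, as
they would on a conventional CT sinogram.  The metal mask is a 3000-HU
threshold of the uncorrected reconstruction (configurable); the trace is
its forward projection (> 1e-9 cm).  LMAR linearly interpolates each
view's trace intervals from the nearest untouched samples; a trace
covering an entire view falls back to the view mean.  NMAR builds a
three-class prior (air −1000 HU / flat soft tissue 0 HU between −500 and
500 HU / bone kept) from the LMAR image, offsets it by +1000 HU so its
forward projection is positive, normalizes, interpolates, denormalizes;
where the prior sinogram vanishes across an interval it falls back to
LMAR.  Both methods restore samples outside the trace bit-exactly, and
the corrected image gets the original metal pixels reinserted.  Because
of that reinsertion, rod-shape metrics on the metal itself differ between
methods only through the surrounding artifacts — a deliberate choice
that isolates MAR performance from segmentation quality.

## Metrics

PSNR uses the reference maximum (`10 log10(max(f)²/MSE)`, +inf for
identical images).  NRMSE divides by the *test* image norm by default
(`normalization="reference"` gives the conventional form).  SSIM is
computed globally from whole-image moments with `c1=(0.01L)²,
c2=(0.03L)²`, `L` the reference dynamic range (small positive floor for
degenerate constant references).  Circularity uses a sub-pixel perimeter:
the binary region is lightly Gaussian-smoothed (sigma 1 px) before
marching-squares contour extraction, which removes the ~5% staircase
overestimate on rasterized disks while leaving straight edges essentially
unchanged (a 200-px square scores 0.792 vs the ideal pi/4 = 0.785, a
50-px-diameter disk 0.99); values are clipped at 1.

## Synthetic phantoms: what they do and do not show

The generators cover: the step-wedge calibration design; a
metal-artifact-evaluation phantom (three 5-mm Cu rods on a 9-mm circle at
90°/210°/330° in a 30-mm PMMA cylinder); geometric anatomical surrogates
(elliptical soft-tissue body with skull annulus / vertebral body /
femoral heads, regions sized 256/409.6/512 mm) with titanium implants
burned in as the last label; and plain disks for analytic oracles.  All
generators are deterministic.  The surrogates reproduce the *mechanisms*
(beam hardening, photon starvation, tissue/bone/metal contrast) but not
anatomical texture, heterogeneous tissue composition, or 3-D partial
volume; passing tests therefore demonstrate the correctness and relative
behavior of the algorithms under controlled spectral physics, not
clinical image quality.

One consequence observed consistently: at the surrogate/test scale the
polynomial VMI slightly outperforms the A-table VMI (by ~0.1 dB PSNR on
the head case, noise-free and noisy alike), because within a generously
covered calibration range a global quadratic interpolates the smooth
inverse map better than a coarse LUT.  Published full-scale comparisons
on real anatomy report the opposite ordering; the package reports both
methods' numbers and makes no attempt to force either ranking.

## Determinism and problem sizes

Every stochastic step derives from a single integer seed
(`numpy.random.default_rng`); a pipeline run with the same configuration
and seed is bit-identical, and all correction methods share one raw
sinogram so comparisons are paired.  Default study sizes: test geometry
360x256 rays, 256² reconstructions, 5-keV spectral step for pipeline
runs (1 keV for calibration-only studies), n0 = 1e7 photons per ray
(1e5 for the noisy head comparison), 500 repetitions for the noise-bias
check.  These sizes were chosen so each end-to-end property runs in
seconds to tens of seconds; the full-scale presets (1080 views, 1024
detectors, 1-keV step) are available via configuration.

## Known limitations

- No scatter/detector physics; absolute HU of polychromatic images
  depends on the chosen water reference energy.
- The Kramers-based spectrum is qualitative; quantitative spectral work
  should import a measured/TASMIP spectrum via CSV.
- Between-node LUT accuracy near zero thickness is limited by the 10-step
  calibration design (see above).
- Sub-percent ring-like residuals from the pure ramp filter are visible
  at high dose; Hann apodization is available but off by default.
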