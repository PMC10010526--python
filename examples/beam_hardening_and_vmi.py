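"""Beam-hardening cupping and its removal by virtual monochromatic imaging.

A polychromatic 140-kV scan of a uniform water disk reconstructs with a
depressed center (cupping) because low-energy photons are filtered out
along long paths.  Decomposing the two-bin data into PMMA/Al thicknesses
and synthesizing a 100-keV monochromatic sinogram removes the effect.
"""

import numpy as np

import pcdct
from pcdct import decomp

geom = pcdct.GEOMETRY_PRESETS["test"]
spectrum = pcdct.apply_filtration(pcdct.generate_spectrum(140.0),
                                  pcdct.get_material("aluminum"),
                                  0.2).normalized()
detector = pcdct.DetectorModel(20.0, 90.0)
basis = pcdct.BasisPair(pcdct.get_material("pmma"),
                        pcdct.get_material("aluminum"))

# calibrate the A-table decomposition on the 10x10 step wedge
design = pcdct.make_calibration_design(10, 10, 50.0, 10.0, basis)
atable = decomp.fit_atable(
    decomp.simulate_calibration(design, spectrum, detector, 1e7))

phantom = pcdct.make_disk_phantom("water", 50.0, 0.5, n=256)
paths = pcdct.trace_paths(phantom, geom)
raw = pcdct.expected_counts(paths, spectrum, detector, 1e7)

img_poly = pcdct.fbp_fan(pcdct.log_projections(raw.summed())[0],
                         geom, 0.5, 256).values
thick = decomp.decompose_sinogram(atable, raw)
vmi = decomp.synthesize_vmi(thick, decomp.VMIRequest(100.0, basis))
img_vmi = pcdct.fbp_fan(vmi, geom, 0.5, 256).values

x, y = phantom.coords()
r = np.hypot(x, y)
center, edge = r < 10.0, (r > 35.0) & (r < 45.0)
cup = (img_poly[edge].mean() - img_poly[center].mean()) / img_poly[edge].mean()
flat = abs(img_vmi[edge].mean() - img_vmi[center].mean()) / img_vmi[edge].mean()

print(f"polychromatic cupping (edge-center)/edge:  {cup:.2%}")
print(f"VMI @ 100 keV residual non-uniformity:     {flat:.2%}")
print("The uncorrected disk dips several percent at the center; the "
      "decomposed monochromatic synthesis is flat to a fraction of a "
      "percent, i.e. beam hardening is gone.")
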