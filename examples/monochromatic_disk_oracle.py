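"""Full-chain sanity check: forward-project and reconstruct a water disk
with a monochromatic beam and compare against the tabulated attenuation.

With a single photon energy there is no beam hardening, so filtered
backprojection should return the disk's true linear attenuation
coefficient; the relative error of the interior mean quantifies the
accuracy of the ray tracer + reconstructor pair.
"""

import numpy as np

import pcdct

geom = pcdct.GEOMETRY_PRESETS["test"]          # 360 views, 256 detectors
phantom = pcdct.make_disk_phantom("water", 50.0, 0.5, n=256)

paths = pcdct.trace_paths(phantom, geom)
sino = pcdct.expected_counts(paths, pcdct.monoenergetic(100.0), None, 1e7)
image = pcdct.fbp_fan(pcdct.log_projections(sino)[0], geom,
                      out_pixel_size=0.5, out_n=256)

mu_true = pcdct.get_material("water")(100.0)
x, y = phantom.coords()
interior = np.hypot(x, y) <= 25.0
mu_recon = image.values[interior].mean()

print(f"mu water @ 100 keV (table):        {mu_true:.5f} 1/cm")
print(f"reconstructed interior mean:       {mu_recon:.5f} 1/cm")
print(f"relative error:                    {abs(mu_recon-mu_true)/mu_true:.2%}")
print("A sub-0.1% error means the fan-beam projector and FBP are "
      "quantitatively consistent.")
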