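"""Rod-shape fidelity on the metal-artifact-evaluation phantom.

Three 5-mm copper rods in a 30-mm PMMA cylinder are scanned at fine
detector pitch; the circularity (4 pi Area / Perimeter^2) of each
reconstructed rod measures how much the correction method distorts the
metal geometry (1 = perfect circle).
"""

import numpy as np

import pcdct
from pcdct.metrics import circularity, segment_rod

geom = pcdct.FanBeamGeometry(sad=400.0, aid=200.0, n_views=360,
                             n_det=256, det_pitch=0.25)
phantom = pcdct.make_mae_phantom(0.2, n=210)
config = pcdct.RunConfig(phantom=phantom, geometry=geom, energy_step=5.0,
                         n0=1e7, noise=True, seed=2,
                         recon_n=210, recon_pixel_size=0.2)
result = pcdct.run_pipeline(config)

half = 210 / 2 - 0.5
centers = []
for ang in (90.0, 210.0, 330.0):
    col = 9.0 * np.cos(np.deg2rad(ang)) / 0.2 + half
    row = half - 9.0 * np.sin(np.deg2rad(ang)) / 0.2
    centers.append((int(round(row)), int(round(col))))

print(f"{'method':<12} {'mean rod circularity':>20}")
for method, img in result.images.items():
    vals = []
    for r0, c0 in centers:
        roi = (r0 - 20, r0 + 20, c0 - 20, c0 + 20)
        thr = img.values[roi[0]:roi[1], roi[2]:roi[3]].max() / 2
        vals.append(circularity(segment_rod(img, roi, thr), 0.2))
    print(f"{method:<12} {np.mean(vals):>20.4f}")
print()
print("Values near 1 mean the rods stay round; streak artifacts and "
      "sinogram inpainting erode the contour and lower the score.")
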