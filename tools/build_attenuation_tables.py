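"""Build the packaged linear-attenuation tables on the 1-150 keV / 1 keV grid.

Anchors are NIST-XCOM mass attenuation coefficients (cm^2/g, photon cross
sections with coherent scattering) on the standard XCOM energy grid, with
K-edge discontinuities represented by duplicated energies.  Between anchors
the curves are interpolated linearly in log(mu/rho) vs log(E), which is the
same convention the package uses at run time, so the shipped 1-keV tables
are smooth and self-consistent.

Run from the repository root:

    python tools/build_attenuation_tables.py
"""

from __future__ import annotations

import pathlib

import numpy as np

# (energy keV, mu/rho cm^2/g); duplicated energies mark absorption edges.
ANCHORS = {
    "water": [
        (1.0, 4078), (1.5, 1376), (2.0, 617.3), (3.0, 192.9), (4.0, 82.78),
        (5.0, 42.58), (6.0, 24.64), (8.0, 10.37), (10.0, 5.329),
        (15.0, 1.673), (20.0, 0.8096), (30.0, 0.3756), (40.0, 0.2683),
        (50.0, 0.2269), (60.0, 0.2059), (80.0, 0.1837), (100.0, 0.1707),
        (150.0, 0.1505),
    ],
    # ICRU-style soft tissue surrogate: water mass attenuation, density 1.06.
    "soft_tissue": None,  # filled from water below
    # Cortical-bone-like mixture; values below 15 keV are a smooth (edge-free)
    # log-log interpolation and only qualitative.
    "bone": [
        (1.0, 3780), (1.5, 1300), (2.0, 590), (3.0, 276), (4.0, 160),
        (5.0, 105), (6.0, 75), (8.0, 43.7), (10.0, 28.51), (15.0, 9.032),
        (20.0, 4.001), (30.0, 1.331), (40.0, 0.6655), (50.0, 0.4242),
        (60.0, 0.3148), (80.0, 0.2229), (100.0, 0.1855), (150.0, 0.1480),
    ],
    "pmma": [
        (1.0, 2794), (1.5, 925.0), (2.0, 425.7), (3.0, 131.6), (4.0, 55.9),
        (5.0, 28.56), (6.0, 16.43), (8.0, 6.941), (10.0, 3.357),
        (15.0, 1.101), (20.0, 0.5714), (30.0, 0.3032), (40.0, 0.2350),
        (50.0, 0.2074), (60.0, 0.1924), (80.0, 0.1751), (100.0, 0.1641),
        (150.0, 0.1456),
    ],
    "aluminum": [
        (1.0, 1185), (1.5, 402.2), (1.5596, 362.1), (1.55961, 3957),
        (2.0, 2263), (3.0, 788.0), (4.0, 360.5), (5.0, 193.4), (6.0, 115.3),
        (8.0, 50.33), (10.0, 26.23), (15.0, 7.955), (20.0, 3.441),
        (30.0, 1.128), (40.0, 0.5685), (50.0, 0.3681), (60.0, 0.2778),
        (80.0, 0.2018), (100.0, 0.1704), (150.0, 0.1378),
    ],
    "titanium": [
        (1.0, 5869), (1.5, 2096), (2.0, 986.0), (3.0, 332.3), (4.0, 151.7),
        (4.9664, 83.80), (4.96641, 687.8), (6.0, 432.3), (8.0, 202.3),
        (10.0, 110.7), (15.0, 35.87), (20.0, 15.85), (30.0, 4.972),
        (40.0, 2.214), (50.0, 1.213), (60.0, 0.7661), (80.0, 0.4052),
        (100.0, 0.2721), (150.0, 0.1649),
    ],
    "copper": [
        (1.0, 10570), (1.5, 4418), (2.0, 2154), (3.0, 748.8), (4.0, 347.3),
        (5.0, 189.9), (6.0, 118.9), (8.0, 52.55), (8.9789, 38.29),
        (8.97891, 278.4), (10.0, 215.9), (15.0, 74.05), (20.0, 33.79),
        (30.0, 10.92), (40.0, 4.862), (50.0, 2.613), (60.0, 1.593),
        (80.0, 0.7630), (100.0, 0.4584), (150.0, 0.2217),
    ],
    "air": [
        (1.0, 3606), (1.5, 1191), (2.0, 527.9), (3.0, 162.5), (4.0, 74.2),
        (5.0, 40.27), (6.0, 23.41), (8.0, 9.921), (10.0, 5.120),
        (15.0, 1.614), (20.0, 0.7779), (30.0, 0.3538), (40.0, 0.2485),
        (50.0, 0.2080), (60.0, 0.1875), (80.0, 0.1662), (100.0, 0.1541),
        (150.0, 0.1356),
    ],
}

DENSITY = {  # g/cm^3
    "water": 1.0,
    "soft_tissue": 1.06,
    "bone": 1.92,
    "pmma": 1.19,
    "aluminum": 2.699,
    "titanium": 4.506,
    "copper": 8.96,
    "air": 1.205e-3,
}

GRID = np.arange(1.0, 151.0)  # keV


def loglog_interp(grid, anchors):
    e = np.array([a[0] for a in anchors])
    m = np.array([a[1] for a in anchors])
    return np.exp(np.interp(np.log(grid), np.log(e), np.log(m)))


def main() -> None:
    out = pathlib.Path(__file__).resolve().parents[1] / "src" / "pcdct" / "data"
    out.mkdir(parents=True, exist_ok=True)
    anchors = dict(ANCHORS)
    anchors["soft_tissue"] = anchors["water"]
    for name, anch in anchors.items():
        rho = DENSITY[name]
        mu = loglog_interp(GRID, anch) * rho
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# material: {name}\n")
            fh.write(f"# density_g_cm3: {rho}\n")
            fh.write("energy_keV,mu_per_cm\n")
            for e, v in zip(GRID, mu):
                fh.write(f"{e:.0f},{v:.6e}\n")
        print(f"wrote {path} ({len(GRID)} rows)")


if __name__ == "__main__":
    main()
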