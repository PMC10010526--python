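import numpy as np
import pytest

import pcdct
from pcdct import decomp


@pytest.fixture(scope="session")
def basis():
    return pcdct.BasisPair(pcdct.get_material("pmma"),
                           pcdct.get_material("aluminum"))


@pytest.fixture(scope="session")
def spectrum140():
    """140 kV tube spectrum with the 2-mm added Al filtration, 1-keV grid."""
    s = pcdct.generate_spectrum(140.0, 1.0)
    return pcdct.apply_filtration(
        s, pcdct.get_material("aluminum"), 0.2).normalized()


@pytest.fixture(scope="session")
def detector():
    return pcdct.DetectorModel(20.0, 90.0)


@pytest.fixture(scope="session")
def design10(basis):
    return pcdct.make_calibration_design(10, 10, 50.0, 10.0, basis)


@pytest.fixture(scope="session")
def calib_nf(design10, spectrum140, detector):
    """Noise-free calibration measurements at the full blank count."""
    return decomp.simulate_calibration(design10, spectrum140, detector, 1e7)


@pytest.fixture(scope="session")
def poly_model(calib_nf):
    return decomp.fit_poly(calib_nf)


@pytest.fixture(scope="session")
def atable_model(calib_nf):
    return decomp.fit_atable(calib_nf)


@pytest.fixture(scope="session")
def geom_test():
    return pcdct.GEOMETRY_PRESETS["test"]


@pytest.fixture(scope="session")
def geom_small():
    """Very small geometry for fast unit tests."""
    return pcdct.FanBeamGeometry(sad=400.0, aid=200.0, n_views=90,
                                 n_det=96, det_pitch=2.0)
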