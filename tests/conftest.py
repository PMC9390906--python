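import numpy as np
import pytest

import filmdose as fd


@pytest.fixture(scope="session")
def co60_curve() -> fd.CalibrationCurve:
    """The measured EBT2/Co-60 cubic calibration curve (transcribed, no SDs)."""
    return fd.EBT2_CO60_CURVE


@pytest.fixture(scope="session")
def fitted_curve(co60_curve) -> fd.CalibrationCurve:
    """Same cubic but refit from noiseless points, so coefficient SDs exist."""
    nods = np.linspace(0.05, 0.60, 10)
    points = [
        fd.CalibrationPoint(nod=float(x), dose=float(np.polyval(co60_curve.coefficients, x)))
        for x in nods
    ]
    return fd.fit_calibration(points)


@pytest.fixture()
def scenario() -> fd.ResponseScenario:
    """Default synthetic scenario: quantised readout, sigma_OD 0.001, seed 0."""
    return fd.ResponseScenario(seed=0)
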